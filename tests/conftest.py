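import numpy as np
import pytest

from cardiomyosim import odes, protocols
from cardiomyosim.model import default_model


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def doc(model):
    return model.to_dict()


@pytest.fixture(scope="session")
def compiled(model):
    return model.compiled()


@pytest.fixture(scope="session")
def settings():
    return protocols.SolverSettings(method="BDF")


@pytest.fixture(scope="session")
def y0(model):
    return odes.initial_vector(model)


def random_states(model, n, seed=0):
    """Strictly positive random states: lognormal spread around the
    tabulated values (zeros replaced by small positives), membrane potential
    uniform in a physiological range."""
    rng = np.random.default_rng(seed)
    base = odes.initial_vector(model).copy()
    base[base <= 0] = 1e-4
    out = []
    for _ in range(n):
        y = base * rng.lognormal(0.0, 0.35, size=base.size)
        y[odes.IDX["DPSI"]] = rng.uniform(20.0, 200.0)
        # keep the intermembrane Mg-bound pools below the aliased totals so
        # the free-species assignments stay positive
        y[odes.IDX["MADP_i"]] = 0.5 * y[odes.IDX["ADP_c"]]
        y[odes.IDX["MATP_i"]] = 0.5 * y[odes.IDX["ATP_c"]]
        out.append(y)
    return out
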