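"""Metabolic control analysis by finite-difference perturbation.

The relative sensitivity of species i to the activity of enzyme/transporter j
is s_ij = (d[C_i]/dX_j)·(X_j/[C_i]), estimated with central differences: the
full protocol is re-simulated with X_j scaled by (1 ± delta) and the species
are compared at the evaluation timepoint.  "Activity" means a joint
multiplicative scaling of the reaction's maximal-rate constants (V_f and V_r
together for reversible forms, so the equilibrium constant is preserved).

Aggregated control strength is the L1 norm over species,
S_j = sum_i |s_ij|, ranked in descending order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import odes, protocols
from .model import ParameterOverride, apply_overrides

_log = logging.getLogger(__name__)

__all__ = ["ENZYME_ACTIVITIES", "SensitivityMatrix", "SensitivityReport",
           "relative_sensitivities", "aggregate"]

#: enzyme -> (pathway label, parameter paths scaled jointly as its activity)
ENZYME_ACTIVITIES = {
    "CK":      ("Energy Buffer",       ("ck.X",)),
    "AK":      ("Energy Buffer",       ("ak.X",)),
    "ATPase":  ("ATP Consumption",     ("atpase.X",)),
    "HK":      ("Glycolysis",          ("hk.Vf", "hk.Vr")),
    "PGI":     ("Glycolysis",          ("pgi.Vf", "pgi.Vr")),
    "PFK":     ("Glycolysis",          ("pfk.Vf",)),
    "FBPA":    ("Glycolysis",          ("fbpa.Vf",)),
    "TPI":     ("Glycolysis",          ("tpi.Vf",)),
    "GAPDH":   ("Glycolysis",          ("gapdh.Vf",)),
    "PGK":     ("Glycolysis",          ("pgk.Vf", "pgk.Vr")),
    "PGM":     ("Glycolysis",          ("pgm.Vf", "pgm.Vr")),
    "Enolase": ("Glycolysis",          ("enolase.Vf", "enolase.Vr")),
    "PK":      ("Glycolysis",          ("pk.Vf", "pk.Vr")),
    "G6PDH":   ("Pentose Phosphate",   ("g6pdh.Vf",)),
    "G3PDH":   ("Glycolysis",          ("g3pdh.Vf",)),
    "G16BPS":  ("Glycolysis",          ("g16bps.Vf", "g16bps.Vr")),
    "PGluM":   ("Glycogen",            ("pglum.Vf", "pglum.Vr")),
    "UDPGP":   ("Glycogen",            ("udpgp.X",)),
    "GSD":     ("Glycogen",            ("gsd.Vf",)),
    "GSI":     ("Glycogen",            ("gsi.Vf",)),
    "GP":      ("Glycogen",            ("gp.Vf", "gp.Vr")),
    "LDH":     ("Lactate",             ("ldh.Vf",)),
    "LHX":     ("Lactate",             ("lhx.Vf", "lhx.Vr")),
    "LA":      ("Lactate",             ("la.X",)),
    "MB":      ("Oxygen Buffer",       ("mb.ka", "mb.kd")),
    "MgBind":  ("Magnesium Binding",   ("mg_binding.X",)),
    "PiHt":    ("Phosphate Transport", ("pi1.X",)),
    "PiPassive": ("Phosphate Transport", ("pi2.p",)),
    "ANT":     ("ATP/ADP Transporter", ("ant.X",)),
    "DH":      ("TCA Cycle",           ("dh.X",)),
    "C1":      ("Electron Transport",  ("c1.X",)),
    "C3":      ("Electron Transport",  ("c3.X",)),
    "C4":      ("Electron Transport",  ("c4.X",)),
    "F1":      ("ATP Synthase",        ("f1.X",)),
    "Hle":     ("Proton Leak",         ("hle.X",)),
    "KH":      ("Potassium Transport", ("kh.X",)),
    "O2VE":    ("Oxygen Transport",    ("o2_ve.pA",)),
    "O2EC":    ("Oxygen Transport",    ("o2_ec.pA",)),
}

#: evaluation timepoints (s) on the standard 3000-s protocol
TIMEPOINTS = {"physiol": 1000.0, "ischemia": 2000.0, "reperfusion": 3000.0}


@dataclass
class SensitivityMatrix:
    """Relative sensitivities s_ij (species x enzyme), one timepoint."""

    timepoint: str
    delta: float
    species: list
    enzymes: list
    values: np.ndarray           # (n_species, n_enzymes)
    excluded: list = field(default_factory=list)


@dataclass
class SensitivityReport:
    """Aggregated per-enzyme control strengths with ranks."""

    timepoint: str
    enzymes: list                # sorted by rank
    pathways: list
    scores: np.ndarray           # S_j, same order
    ranks: np.ndarray            # 1-based

    def top(self, n=5):
        return list(zip(self.enzymes[:n], self.scores[:n]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"enzyme": self.enzymes, "pathway": self.pathways,
                             "S": self.scores, "rank": self.ranks})


def _state_at(result, t):
    out = np.empty(odes.N_ODE)
    for i in range(odes.N_ODE):
        out[i] = np.interp(t, result.time, result.states[:, i])
    return out


def perturbed_states(model, protocol=None, delta=0.01, settings=None,
                     enzymes=None, timepoints=None, progress=False):
    """Simulate the protocol once per (enzyme, sign) and collect the states
    at every timepoint.  Returns (baseline, {enzyme: (lo, hi)}) where each
    entry maps timepoint label -> state vector."""
    if not (0.0 < delta <= 0.1):
        raise ValueError(f"perturbation delta must be in (0, 0.1], got {delta}")
    protocol = protocol or protocols.standard_protocol(0.01)
    settings = settings or protocols.SolverSettings(method="BDF")
    timepoints = timepoints or TIMEPOINTS
    enzymes = list(enzymes or ENZYME_ACTIVITIES)

    def run(m):
        res = protocols.simulate(m, protocol, settings)
        return {label: _state_at(res, t) for label, t in timepoints.items()}

    baseline = run(model)
    perturbed = {}
    for name in enzymes:
        _, paths = ENZYME_ACTIVITIES[name]
        lo = run(apply_overrides(model, [ParameterOverride(p, 1.0 - delta, multiplicative=True) for p in paths]))
        hi = run(apply_overrides(model, [ParameterOverride(p, 1.0 + delta, multiplicative=True) for p in paths]))
        perturbed[name] = (lo, hi)
        if progress:
            _log.info("sensitivity: perturbed %s", name)
    return baseline, perturbed


def relative_sensitivities(model, protocol=None, timepoint="physiol",
                           delta=0.01, settings=None, enzymes=None,
                           _cache=None) -> SensitivityMatrix:
    """Central-difference relative sensitivities at one timepoint.

    ``_cache`` may carry the (baseline, perturbed) pair from
    :func:`perturbed_states` so several timepoints share one set of solves.
    """
    if _cache is None:
        _cache = perturbed_states(model, protocol, delta, settings, enzymes)
    baseline, perturbed = _cache
    if timepoint not in baseline:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    enzymes = list(perturbed)
    base = baseline[timepoint]
    species = list(odes.ODE_ORDER)
    excluded = [n for i, n in enumerate(species) if abs(base[i]) < 1e-12]
    if excluded:
        _log.warning("sensitivity: excluding species with ~zero baseline: %s", excluded)
    rows = [i for i, n in enumerate(species) if n not in excluded]
    values = np.zeros((len(rows), len(enzymes)))
    for j, name in enumerate(enzymes):
        lo, hi = perturbed[name]
        diff = hi[timepoint][rows] - lo[timepoint][rows]
        values[:, j] = diff / (2.0 * delta * base[rows])
    return SensitivityMatrix(timepoint=timepoint, delta=delta,
                             species=[species[i] for i in rows],
                             enzymes=enzymes, values=values, excluded=excluded)


def aggregate(matrix: SensitivityMatrix) -> SensitivityReport:
    """L1 aggregation over species; descending rank, ties lexicographic."""
    scores = np.abs(matrix.values).sum(axis=0)
    order = sorted(range(len(matrix.enzymes)),
                   key=lambda j: (-scores[j], matrix.enzymes[j]))
    enzymes = [matrix.enzymes[j] for j in order]
    return SensitivityReport(
        timepoint=matrix.timepoint,
        enzymes=enzymes,
        pathways=[ENZYME_ACTIVITIES[e][0] for e in enzymes],
        scores=scores[order],
        ranks=np.arange(1, len(order) + 1),
    )


def full_analysis(model, protocol=None, delta=0.01, settings=None):
    """Reports for all three canonical timepoints from one set of solves."""
    cache = perturbed_states(model, protocol, delta, settings)
    return {label: aggregate(relative_sensitivities(
        model, protocol, label, delta, settings, _cache=cache))
        for label in TIMEPOINTS}
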