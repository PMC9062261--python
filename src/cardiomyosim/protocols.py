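"""Oxygen schedules, time-course integration and steady-state search.

Ischemia/reperfusion experiments are piecewise-constant vessel-oxygen
schedules: oxygen is switched instantaneously at segment boundaries, so the
integrator is restarted at every discontinuity with state handoff (no
smoothing ramp).  The canonical experiment holds physiological oxygen for
1000 s, an ischemic fraction of it for 1000 s, and reperfuses for 1000 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import odes, rates
from .model import Model

#: Physiological vessel oxygen concentration (mM), the 100% reference.
O2_PHYSIOLOGICAL = 0.1326


class IntegrationError(RuntimeError):
    pass


class SteadyStateError(RuntimeError):
    pass


@dataclass(frozen=True)
class OxygenProtocol:
    """Contiguous (start, end, fraction-of-physiological) oxygen segments."""

    segments: tuple  # of (t0, t1, fraction)
    label: str = ""
    o2_physiological: float = O2_PHYSIOLOGICAL

    def __post_init__(self):
        segs = tuple((float(a), float(b), float(f)) for a, b, f in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        for t0, t1, f in segs:
            if not (0.0 < f <= 1.0):
                raise ValueError(f"oxygen fraction must be in (0, 1], got {f}")
            if not t1 > t0:
                raise ValueError(f"empty segment [{t0}, {t1}]")
        for (_a, prev_end, _fa), (start, _b, _fb) in zip(segs, segs[1:]):
            if abs(prev_end - start) > 1e-9:
                raise ValueError("segments must be contiguous and non-overlapping")

    @property
    def t_start(self):
        return self.segments[0][0]

    @property
    def t_end(self):
        return self.segments[-1][1]

    def fraction_at(self, t: float) -> float:
        for t0, t1, f in self.segments:
            if t0 <= t <= t1:
                if t == t1:  # boundary belongs to the following segment
                    for u0, _, g in self.segments:
                        if u0 == t:
                            return g
                return f
        raise ValueError(f"protocol undefined at t = {t}")

    def o2_at(self, t: float) -> float:
        return self.fraction_at(t) * self.o2_physiological

    def step_up_times(self):
        """Times at which oxygen increases (reperfusion onsets)."""
        out = []
        for (a0, a1, fa), (b0, b1, fb) in zip(self.segments, self.segments[1:]):
            if fb > fa:
                out.append(b0)
        return out

    def ischemia_onset(self):
        for (a0, a1, fa), (b0, b1, fb) in zip(self.segments, self.segments[1:]):
            if fb < fa:
                return b0
        return None


def constant_protocol(fraction=1.0, t_end=3000.0, label="constant") -> OxygenProtocol:
    return OxygenProtocol(((0.0, float(t_end), fraction),), label=label)


def standard_protocol(ischemic_fraction, t_isch_start=1000.0, t_rep=2000.0,
                      t_end=3000.0, label=None) -> OxygenProtocol:
    """Physiological / ischemia / full reperfusion, 1000 s each by default."""
    if not (0.0 < ischemic_fraction <= 1.0):
        raise ValueError(f"ischemic fraction must be in (0, 1], got {ischemic_fraction}")
    segs = ((0.0, t_isch_start, 1.0),
            (t_isch_start, t_rep, ischemic_fraction),
            (t_rep, t_end, 1.0))
    return OxygenProtocol(segs, label=label or f"ischemia {100 * ischemic_fraction:g}%")


def two_step_protocol(ischemic_fraction, step1_fraction, t_isch=1000.0,
                      t_step1=2000.0, t_step2=3000.0, t_end=4000.0,
                      label=None) -> OxygenProtocol:
    """Graded reperfusion: ischemia, an intermediate oxygen step, then 100%."""
    for f in (ischemic_fraction, step1_fraction):
        if not (0.0 < f <= 1.0):
            raise ValueError(f"oxygen fraction must be in (0, 1], got {f}")
    segs = ((0.0, t_isch, 1.0),
            (t_isch, t_step1, ischemic_fraction),
            (t_step1, t_step2, step1_fraction),
            (t_step2, t_end, 1.0))
    return OxygenProtocol(
        segs, label=label or
        f"ischemia {100 * ischemic_fraction:g}% / step {100 * step1_fraction:g}%")


@dataclass(frozen=True)
class SolverSettings:
    """Stiff-integration controls; defaults resolve the reperfusion spikes."""

    rtol: float = 1e-8
    atol: float = 1e-10          # mM
    atol_dpsi: float = 1e-6      # mV
    method: str = "LSODA"
    max_step: float = np.inf
    output_dt: float = 1.0       # s, regular reporting grid
    refine_dt: float = 0.05      # s, grid refinement after each O2 step-up
    refine_window: float = 30.0  # s
    negative_tolerance: float = 2e-3  # mM, largest tolerated undershoot

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0 or self.atol_dpsi <= 0:
            raise ValueError("tolerances must be positive")

    def atol_vector(self):
        v = np.full(odes.N_ODE, self.atol)
        v[odes.IDX["DPSI"]] = self.atol_dpsi
        return v


@dataclass
class SimulationResult:
    """Time grid, state and flux trajectories, protocol and diagnostics."""

    time: np.ndarray                 # (n,)
    states: np.ndarray               # (n, N_ODE) in odes.ODE_ORDER
    fluxes: np.ndarray               # (n, len(rates.FLUX_NAMES))
    protocol: OxygenProtocol
    settings: SolverSettings
    diagnostics: dict = field(default_factory=dict)

    def species(self, name: str) -> np.ndarray:
        return self.states[:, odes.IDX[name]]

    def flux(self, name: str) -> np.ndarray:
        return self.fluxes[:, rates.FLUX_NAMES.index(name)]

    def value_at(self, name: str, t: float) -> float:
        return float(np.interp(t, self.time, self.species(name)))

    def to_frame(self, include_fluxes=True):
        import pandas as pd

        data = {"time": self.time}
        data.update({n: self.states[:, i] for n, i in odes.IDX.items()})
        if include_fluxes:
            data.update({n: self.fluxes[:, j] for j, n in enumerate(rates.FLUX_NAMES)})
        return pd.DataFrame(data)


def _output_grid(protocol: OxygenProtocol, settings: SolverSettings):
    pts = [np.arange(protocol.t_start, protocol.t_end, settings.output_dt),
           [protocol.t_end]]
    for t_up in protocol.step_up_times():
        stop = min(t_up + settings.refine_window, protocol.t_end)
        pts.append(np.arange(t_up, stop, settings.refine_dt))
    grid = np.unique(np.concatenate([np.asarray(x, dtype=float) for x in pts]))
    return grid[(grid >= protocol.t_start) & (grid <= protocol.t_end)]


def _compile(model_or_params):
    if isinstance(model_or_params, Model):
        return model_or_params.compiled()
    return model_or_params


def simulate(model, protocol: OxygenProtocol, settings: SolverSettings = None,
             y0=None) -> SimulationResult:
    """Integrate the full ODE system over an oxygen protocol.

    Integration restarts at every segment boundary (instantaneous oxygen
    switches).  ``y0`` defaults to the registry initial values; pass a
    steady state from :func:`find_steady_state` for pre-equilibrated runs.
    """
    settings = settings or SolverSettings()
    p = _compile(model)
    y = np.array(initial_vector(model) if y0 is None else y0, dtype=float)
    grid = _output_grid(protocol, settings)

    times, ys = [], []
    n_steps = 0
    for k, (t0, t1, frac) in enumerate(protocol.segments):
        o2_v = frac * protocol.o2_physiological
        t_eval = grid[(grid >= t0) & (grid <= t1)]
        if t_eval.size == 0 or t_eval[0] > t0:
            t_eval = np.concatenate(([t0], t_eval))
        if t_eval[-1] < t1:
            t_eval = np.concatenate((t_eval, [t1]))
        sol = solve_ivp(
            odes.rhs, (t0, t1), y, method=settings.method, t_eval=t_eval,
            rtol=settings.rtol, atol=settings.atol_vector(),
            max_step=settings.max_step, args=(p, lambda t, o=o2_v: o),
        )
        if not sol.success:
            t_last = sol.t[-1] if sol.t.size else t0
            raise IntegrationError(
                f"integration failed in segment {k} ({protocol.label!r}) "
                f"at t = {t_last:.6g} s: {sol.message}")
        n_steps += sol.t.size
        # drop duplicated segment-boundary sample
        start = 1 if (times and sol.t[0] == times[-1][-1]) else 0
        times.append(sol.t[start:])
        ys.append(sol.y.T[start:])
        y = sol.y[:, -1].copy()

    time = np.concatenate(times)
    states = np.vstack(ys)
    _check_negatives(time, states, settings)

    fluxes = np.empty((time.size, len(rates.FLUX_NAMES)))
    for i, (t, row) in enumerate(zip(time, states)):
        S = odes.expand_state(row, p, o2_v=protocol.o2_at(float(t)))
        J = rates.all_fluxes(S, p, check=False)
        fluxes[i] = [J[n] for n in rates.FLUX_NAMES]
    return SimulationResult(time=time, states=states, fluxes=fluxes,
                            protocol=protocol, settings=settings,
                            diagnostics={"solver_steps": n_steps,
                                         "rtol": settings.rtol,
                                         "atol": settings.atol})


def _check_negatives(time, states, settings):
    worst = states.min(axis=0)
    bad = np.where(worst < -settings.negative_tolerance)[0]
    if bad.size:
        i = bad[np.argmin(worst[bad])]
        name = odes.ODE_ORDER[i]
        if name == "DPSI":
            return  # the membrane potential may legitimately change sign
        t_bad = time[int(np.argmin(states[:, i]))]
        raise IntegrationError(
            f"concentration of {name} became negative ({worst[i]:.3g} mM) "
            f"at t = {t_bad:.6g} s")


def initial_vector(model):
    if isinstance(model, Model):
        return odes.initial_vector(model)
    raise TypeError("simulate() without y0 requires a Model instance")


def find_steady_state(model, o2_fraction=1.0, settings: SolverSettings = None,
                      tol=2e-5, floor=1e-6, max_time=200000.0,
                      chunk=10000.0, y0=None):
    """Relax the model under constant oxygen until the dynamics settle.

    Integrates in chunks and accepts the state once
    ``max_i |dy_i/dt| / max(|y_i|, floor)`` drops below ``tol`` (1/s).
    Returns the settled ODE state vector (odes.ODE_ORDER layout).

    The default tolerance sits just above the residual drift of the lactic
    acid reservoir, which accumulates indefinitely by construction (its
    association reaction has no outflow); every other species is then
    stationary to much better than 0.1% over a 3000 s protocol.
    """
    settings = settings or SolverSettings()
    p = _compile(model)
    o2_v = o2_fraction * O2_PHYSIOLOGICAL
    y = np.array(odes.initial_vector(model) if y0 is None else y0, dtype=float)
    o2_fn = lambda t: o2_v  # noqa: E731

    t = 0.0
    residual = np.inf
    while t < max_time:
        sol = solve_ivp(odes.rhs, (t, t + chunk), y, method=settings.method,
                        rtol=settings.rtol, atol=settings.atol_vector(),
                        args=(p, o2_fn))
        if not sol.success:
            raise IntegrationError(
                f"steady-state relaxation failed at t = {sol.t[-1]:.6g} s: {sol.message}")
        y = sol.y[:, -1].copy()
        t += chunk
        dy = odes.rhs(t, y, p, o2_fn)
        residual = float(np.max(np.abs(dy) / np.maximum(np.abs(y), floor)))
        if residual < tol:
            return y
    raise SteadyStateError(
        f"no steady state within {max_time:.0f} s: residual {residual:.3g} 1/s > {tol:g}")
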