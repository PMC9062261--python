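"""Scalar injury-surrogate readouts extracted from a simulated protocol.

All times are in seconds relative to the relevant protocol event (ischemia
onset or reperfusion onset), linearly interpolated between output-grid
points.  "Preischemic" baselines are taken at the last sample before the
ischemia onset; the paper-style protocols hold a physiological pre-phase
long enough that this is the resting steady state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

_log = logging.getLogger(__name__)

__all__ = [
    "IRMetrics", "atp_depletion_time", "recovery_time", "dpsi_metrics",
    "ret_interval", "c3_spike_ratio", "ir_metrics",
]


@dataclass(frozen=True)
class IRMetrics:
    """Headline readouts of one ischemia/reperfusion experiment."""

    atp_depletion_time: float | None   # s after ischemia onset; None if kept
    atp_recovery_time: float | None    # s after reperfusion onset
    dpsi_ischemic_plateau: float       # mV at end of ischemia
    dpsi_spike_ratio: float            # max reperfusion dPsi / preischemic
    dpsi_spike_duration: float         # s above 1.1 x preischemic
    ret_interval: tuple | None         # (start, end) s of complex-I reversal
    c3_spike_ratio: float              # max complex-III rate / preischemic
    crp_recovery_time: float | None    # s after reperfusion onset
    atp_adp_settle_time: float | None  # s after reperfusion onset

    def to_dict(self):
        return asdict(self)


def _events(result):
    onset = result.protocol.ischemia_onset()
    if onset is None:
        raise ValueError("protocol has no ischemic segment")
    step_ups = result.protocol.step_up_times()
    reperfusion = step_ups[-1] if step_ups else None
    return onset, reperfusion


def _baseline_index(time, onset):
    idx = np.searchsorted(time, onset) - 1
    return max(idx, 0)


def _first_crossing(time, values, threshold, after):
    """First time after ``after`` where values drop below threshold."""
    mask = time >= after
    t, v = time[mask], values[mask]
    below = v < threshold
    if not below.any():
        return None
    k = int(np.argmax(below))
    if k == 0:
        return float(t[0])
    # linear interpolation between the bracketing grid points
    t0, t1, v0, v1 = t[k - 1], t[k], v[k - 1], v[k]
    if v1 == v0:
        return float(t1)
    return float(t0 + (threshold - v0) * (t1 - t0) / (v1 - v0))


def atp_depletion_time(result, threshold_frac=0.05):
    """Seconds from ischemia onset until cytosolic ATP falls below the
    threshold fraction of its preischemic value; None if it never does."""
    onset, reperfusion = _events(result)
    t, atp = result.time, result.species("ATP_c")
    pre = atp[_baseline_index(t, onset)]
    t_end = reperfusion if reperfusion is not None else t[-1]
    window = (t >= onset) & (t <= t_end)
    crossing = _first_crossing(t[window], atp[window], threshold_frac * pre, onset)
    return None if crossing is None else crossing - onset


def recovery_time(result, species, tol_frac=0.05, t_from=None):
    """Seconds after the final oxygen step-up for a species to enter and
    *remain* within ``tol_frac`` of its final value; 0 if already settled."""
    onset, reperfusion = _events(result)
    if reperfusion is None:
        raise ValueError("protocol has no reperfusion segment")
    t0 = reperfusion if t_from is None else t_from
    t = result.time
    x = result.species(species) if isinstance(species, str) else species
    final = x[-1]
    if final == 0:
        _log.warning("recovery_time: final value of %s is 0; returning None", species)
        return None
    mask = t >= t0
    dev = np.abs(x[mask] - final) > tol_frac * abs(final)
    if not dev.any():
        return 0.0
    last_bad = np.where(mask)[0][np.where(dev)[0][-1]]
    settled_at = t[min(last_bad + 1, len(t) - 1)]
    if settled_at > t[-1] - 0.02 * (t[-1] - t0):
        # still moving at the end of the run: "final" is not a plateau
        _log.warning("recovery_time: %s has not settled by the end of the run", species)
        return None
    return float(settled_at - t0)


def dpsi_metrics(result, spike_margin=1.1):
    """Late-ischemia plateau, reperfusion spike ratio and spike duration of
    the mitochondrial membrane potential."""
    onset, reperfusion = _events(result)
    t, dpsi = result.time, result.species("DPSI")
    pre = dpsi[_baseline_index(t, onset)]
    isch_end = reperfusion if reperfusion is not None else t[-1]
    plateau = float(dpsi[_baseline_index(t, isch_end)])  # last pre-reperfusion sample
    if reperfusion is None:
        return {"plateau": plateau, "spike_ratio": 1.0, "spike_duration": 0.0}
    rep = t >= reperfusion
    spike_ratio = float(dpsi[rep].max() / pre)
    above = dpsi[rep] > spike_margin * pre
    duration = float(np.trapezoid(above.astype(float), t[rep]))
    return {"plateau": plateau, "spike_ratio": spike_ratio,
            "spike_duration": duration}


def ret_interval(result):
    """Maximal contiguous post-reperfusion interval of reverse electron
    transport (negative complex-I rate); None if complex I never reverses."""
    onset, reperfusion = _events(result)
    if reperfusion is None:
        return None
    t, jc1 = result.time, result.flux("J_C1")
    rep = t >= reperfusion
    tr, jr = t[rep], jc1[rep]
    neg = jr < 0.0
    if not neg.any():
        return None
    # longest run of consecutive negative samples
    best, cur_start, best_span = None, None, -1.0
    for i, flag in enumerate(neg):
        if flag and cur_start is None:
            cur_start = i
        if (not flag or i == len(neg) - 1) and cur_start is not None:
            stop = i if flag else i - 1
            span = tr[stop] - tr[cur_start]
            if span > best_span:
                best, best_span = (float(tr[cur_start]), float(tr[stop])), span
            cur_start = None
    return best


def c3_spike_ratio(result, window=60.0):
    """Peak complex-III rate within ``window`` s of reperfusion onset divided
    by its preischemic value."""
    onset, reperfusion = _events(result)
    t, jc3 = result.time, result.flux("J_C3")
    pre = jc3[_baseline_index(t, onset)]
    if pre <= 0:
        raise ValueError(f"preischemic complex-III rate must be positive, got {pre!r}")
    if reperfusion is None:
        return 1.0
    mask = (t >= reperfusion) & (t <= reperfusion + window)
    return float(jc3[mask].max() / pre)


def ir_metrics(result, depletion_frac=0.05, tol_frac=0.05) -> IRMetrics:
    """All injury surrogates of one ischemia/reperfusion simulation."""
    dp = dpsi_metrics(result)
    t, atp, adp = result.time, result.species("ATP_c"), result.species("ADP_c")
    ratio = np.divide(atp, adp, out=np.full_like(atp, np.nan), where=adp > 0)
    return IRMetrics(
        atp_depletion_time=atp_depletion_time(result, depletion_frac),
        atp_recovery_time=recovery_time(result, "ATP_c", tol_frac),
        dpsi_ischemic_plateau=dp["plateau"],
        dpsi_spike_ratio=dp["spike_ratio"],
        dpsi_spike_duration=dp["spike_duration"],
        ret_interval=ret_interval(result),
        c3_spike_ratio=c3_spike_ratio(result),
        crp_recovery_time=recovery_time(result, "CRP_c", tol_frac),
        atp_adp_settle_time=recovery_time(result, ratio, tol_frac),
    )
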