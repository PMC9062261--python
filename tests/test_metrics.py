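"""Metric extraction on small synthetic trajectories with known answers."""

import numpy as np
import pytest

from cardiomyosim import metrics, odes, protocols, rates


def synthetic_result(time, label="synthetic", **series):
    """SimulationResult carrying hand-built traces; species/fluxes not
    supplied stay at benign constants."""
    time = np.asarray(time, dtype=float)
    states = np.ones((time.size, odes.N_ODE))
    for name, values in series.items():
        if name in odes.IDX:
            states[:, odes.IDX[name]] = values
    fluxes = np.full((time.size, len(rates.FLUX_NAMES)), 0.5)
    for name, values in series.items():
        if name in rates.FLUX_NAMES:
            fluxes[:, rates.FLUX_NAMES.index(name)] = values
    proto = protocols.OxygenProtocol(
        ((0.0, 100.0, 1.0), (100.0, 200.0, 0.01), (200.0, float(time[-1]), 1.0)),
        label=label)
    return protocols.SimulationResult(time=time, states=states, fluxes=fluxes,
                                      protocol=proto,
                                      settings=protocols.SolverSettings())


class TestDepletionTime:
    def test_exact_grid_crossing(self):
        t = np.arange(0.0, 301.0)
        atp = np.where(t < 153.0, 7.0, 0.1)  # drops below threshold at t=153
        res = synthetic_result(t, ATP_c=atp)
        assert metrics.atp_depletion_time(res) == pytest.approx(53.0, abs=1.0)

    def test_interpolated_crossing(self):
        t = np.array([0.0, 100.0, 150.0, 200.0, 300.0])
        atp = np.array([7.0, 7.0, 7.0, 0.0, 7.0])  # linear 7 -> 0 over 150..200
        res = synthetic_result(t, ATP_c=atp)
        # threshold 0.05*7 = 0.35 crossed at t = 150 + 50*(1-0.05) = 197.5
        got = metrics.atp_depletion_time(res)
        assert got == pytest.approx(97.5, abs=1e-9)

    def test_none_when_maintained(self):
        t = np.arange(0.0, 301.0)
        res = synthetic_result(t, ATP_c=np.full_like(t, 7.0))
        assert metrics.atp_depletion_time(res) is None

    def test_requires_an_ischemic_segment(self):
        t = np.arange(0.0, 301.0)
        res = synthetic_result(t)
        object.__setattr__(res.protocol, "segments", ((0.0, 301.0, 1.0),))
        with pytest.raises(ValueError, match="ischemic"):
            metrics.atp_depletion_time(res)


class TestRecoveryTime:
    def test_constant_trajectory_recovers_instantly(self):
        t = np.arange(0.0, 301.0)
        res = synthetic_result(t, ATP_c=np.full_like(t, 7.0))
        assert metrics.recovery_time(res, "ATP_c") == 0.0

    def test_ramp_settling(self):
        t = np.arange(0.0, 301.0)
        atp = np.where(t < 200.0, 1.0, 1.0 + (t - 200.0) * 0.06)
        atp = np.minimum(atp, 7.0)  # reaches 7.0 at t=300... clip at 7 by t=300
        res = synthetic_result(t, ATP_c=atp)
        # final 7.0; within 5% means >= 6.65, reached at t = 200 + 5.65/0.06
        got = metrics.recovery_time(res, "ATP_c")
        assert got == pytest.approx(5.65 / 0.06, abs=1.5)

    def test_trace_still_moving_at_the_end_returns_none(self):
        t = np.arange(0.0, 301.0)
        atp = np.where(t < 299.5, 1.0, 7.0)  # jumps right at the last sample
        res = synthetic_result(t, ATP_c=atp)
        assert metrics.recovery_time(res, "ATP_c") is None


class TestDpsiMetrics:
    def test_plateau_spike_and_duration(self):
        t = np.arange(0.0, 301.0)
        dpsi = np.full_like(t, 170.0)
        dpsi[(t >= 100) & (t < 200)] = 60.0       # ischemic plateau
        dpsi[(t >= 200) & (t < 250)] = 340.0      # 50 s spike at 2x
        res = synthetic_result(t, DPSI=dpsi)
        out = metrics.dpsi_metrics(res)
        assert out["plateau"] == pytest.approx(60.0, abs=1e-6)
        assert out["spike_ratio"] == pytest.approx(2.0, rel=1e-9)
        assert out["spike_duration"] == pytest.approx(50.0, abs=1.5)

    def test_no_overshoot_gives_unity_ratio(self):
        t = np.arange(0.0, 301.0)
        res = synthetic_result(t, DPSI=np.full_like(t, 170.0))
        out = metrics.dpsi_metrics(res)
        assert out["spike_ratio"] == pytest.approx(1.0)
        assert out["spike_duration"] == 0.0


class TestRetInterval:
    def test_none_when_complex1_stays_forward(self):
        t = np.arange(0.0, 301.0)
        res = synthetic_result(t, J_C1=np.full_like(t, 0.2))
        assert metrics.ret_interval(res) is None

    def test_finds_longest_negative_window(self):
        t = np.arange(0.0, 301.0)
        jc1 = np.full_like(t, 0.2)
        jc1[(t >= 205) & (t <= 215)] = -0.05
        jc1[(t >= 240) & (t <= 280)] = -0.02
        res = synthetic_result(t, J_C1=jc1)
        start, end = metrics.ret_interval(res)
        assert (start, end) == (240.0, 280.0)

    def test_pre_reperfusion_reversal_ignored(self):
        t = np.arange(0.0, 301.0)
        jc1 = np.full_like(t, 0.2)
        jc1[(t >= 120) & (t <= 180)] = -0.1  # during ischemia, not after
        res = synthetic_result(t, J_C1=jc1)
        assert metrics.ret_interval(res) is None


class TestC3Spike:
    def test_constant_rate_gives_unity(self):
        t = np.arange(0.0, 301.0)
        res = synthetic_result(t, J_C3=np.full_like(t, 0.3))
        assert metrics.c3_spike_ratio(res) == pytest.approx(1.0)

    def test_threefold_burst(self):
        t = np.arange(0.0, 301.0)
        jc3 = np.full_like(t, 0.3)
        jc3[(t >= 200) & (t <= 210)] = 0.9
        res = synthetic_result(t, J_C3=jc3)
        assert metrics.c3_spike_ratio(res) == pytest.approx(3.0)

    def test_burst_outside_window_ignored(self):
        t = np.arange(0.0, 401.0)
        jc3 = np.full_like(t, 0.3)
        jc3[t >= 290] = 0.9  # 90 s after reperfusion onset
        res = synthetic_result(t, J_C3=jc3)
        assert metrics.c3_spike_ratio(res, window=60.0) == pytest.approx(1.0)

    def test_nonpositive_baseline_rejected(self):
        t = np.arange(0.0, 301.0)
        res = synthetic_result(t, J_C3=np.zeros_like(t))
        with pytest.raises(ValueError, match="positive"):
            metrics.c3_spike_ratio(res)


class TestAggregateReport:
    def test_ir_metrics_bundles_all_readouts(self, model, settings):
        proto = protocols.OxygenProtocol(
            ((0.0, 150.0, 1.0), (150.0, 250.0, 0.01), (250.0, 400.0, 1.0)))
        res = protocols.simulate(model, proto, settings)
        out = metrics.ir_metrics(res)
        assert out.dpsi_spike_ratio > 0
        assert out.c3_spike_ratio > 0
        assert out.crp_recovery_time is not None
        doc = out.to_dict()
        assert set(doc) == {
            "atp_depletion_time", "atp_recovery_time", "dpsi_ischemic_plateau",
            "dpsi_spike_ratio", "dpsi_spike_duration", "ret_interval",
            "c3_spike_ratio", "crp_recovery_time", "atp_adp_settle_time"}
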