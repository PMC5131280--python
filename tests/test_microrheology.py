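"""MSD, power-law fit, and twisting-cytometry estimator checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asmkit import microrheology as mr
from asmkit import synthetic as sd
from asmkit.microrheology import MSDCurve, TwistRecord
from asmkit.tracking import Trajectory


def _traj(x, y, frame_rate=1.0):
    x = np.asarray(x, dtype=float)
    return Trajectory(0, np.arange(len(x)) / frame_rate, x,
                      np.asarray(y, dtype=float), frame_rate)


class TestComputeMsd:
    def test_stationary_bead_zero_msd(self):
        t = _traj([5.0] * 10, [-3.0] * 10)
        curve = mr.compute_msd(t, lag_grid=[1.0, 2.0, 5.0])
        assert np.all(curve.msd == 0.0)

    def test_hand_enumerated_oracle(self):
        # (0,0) -> (3,4) -> (6,8) at 1 s steps: each step is a 3-4-5
        # displacement, so MSD(1 s) = 25 and MSD(2 s) = 100 nm^2 exactly
        t = _traj([0.0, 3.0, 6.0], [0.0, 4.0, 8.0])
        curve = mr.compute_msd(t, lag_grid=[1.0, 2.0])
        assert curve.msd[0] == pytest.approx(25.0, abs=1e-12)
        assert curve.msd[1] == pytest.approx(100.0, abs=1e-12)
        assert list(curve.n_pairs) == [2, 1]

    def test_brownian_closed_form(self):
        params = sd.RemodelingSimParams(d_star=100.0, alpha=1.0,
                                        loc_noise_sd=0.0, frame_rate=12.0,
                                        duration=100.0, n_beads=500, seed=19)
        trajs = sd.simulate_remodeling_trajectories(params)
        ens = mr.ensemble_msd([mr.compute_msd(t, lag_grid=[10.0])
                               for t in trajs])
        assert ens.msd[0] == pytest.approx(1000.0, rel=0.05)

    def test_non_multiple_lag_rejected(self):
        t = _traj(np.arange(10.0), np.zeros(10), frame_rate=2.0)
        with pytest.raises(ValueError, match="multiple"):
            mr.compute_msd(t, lag_grid=[0.75])

    @given(dx=st.floats(-1e5, 1e5), dy=st.floats(-1e5, 1e5))
    @settings(max_examples=25, deadline=None)
    def test_translation_invariance_and_axis_swap(self, dx, dy):
        rng = np.random.default_rng(5)
        x = np.cumsum(rng.normal(0, 10, 50))
        y = np.cumsum(rng.normal(0, 10, 50))
        base = mr.compute_msd(_traj(x, y), lag_grid=[1.0, 3.0, 7.0])
        moved = mr.compute_msd(_traj(x + dx, y + dy), lag_grid=[1.0, 3.0, 7.0])
        swapped = mr.compute_msd(_traj(y, x), lag_grid=[1.0, 3.0, 7.0])
        np.testing.assert_allclose(moved.msd, base.msd, rtol=1e-9, atol=1e-6)
        np.testing.assert_allclose(swapped.msd, base.msd, rtol=1e-12)


class TestEnsembleMsd:
    def test_identical_curves_unchanged(self):
        c = MSDCurve(lags=[1.0, 2.0], msd=[10.0, 20.0], n_pairs=[5, 4])
        ens = mr.ensemble_msd([c, c, c])
        np.testing.assert_array_equal(ens.msd, c.msd)

    def test_two_bead_arithmetic_mean(self):
        a = MSDCurve(lags=[1.0], msd=[10.0], n_pairs=[5])
        b = MSDCurve(lags=[1.0], msd=[30.0], n_pairs=[5])
        assert mr.ensemble_msd([a, b]).msd[0] == 20.0

    def test_missing_lags_excluded_per_lag(self):
        a = MSDCurve(lags=[1.0, 2.0], msd=[10.0, 40.0], n_pairs=[5, 4])
        b = MSDCurve(lags=[1.0], msd=[30.0], n_pairs=[5])
        ens = mr.ensemble_msd([a, b])
        np.testing.assert_array_equal(ens.msd, [20.0, 40.0])
        np.testing.assert_array_equal(ens.n_pairs, [2, 1])

    def test_geometric_mean_summary_matches_log_t_interval(self):
        # well-level spread of per-bead MSD at one lag, summarized as
        # geometric mean with 95% CI, must match a direct t-interval on logs
        from asmkit import stats as stats_core
        rng = np.random.default_rng(21)
        per_bead = rng.lognormal(mean=np.log(500), sigma=0.8, size=40)
        gm, lo, hi = stats_core.geometric_mean_ci(per_bead)
        logs = np.log10(per_bead)
        from scipy import stats as sps
        t_crit = sps.t.ppf(0.975, len(logs) - 1)
        se = logs.std(ddof=1) / np.sqrt(len(logs))
        assert gm == pytest.approx(10 ** logs.mean())
        assert lo == pytest.approx(10 ** (logs.mean() - t_crit * se))
        assert hi == pytest.approx(10 ** (logs.mean() + t_crit * se))


class TestPowerLawFit:
    def test_exact_power_law_recovered_to_machine_precision(self):
        lags = np.linspace(10, 300, 30)
        curve = MSDCurve(lags=lags, msd=100.0 * lags ** 1.0,
                         n_pairs=np.full(30, 10))
        fit = mr.fit_power_law(curve)
        assert fit.alpha == pytest.approx(1.0, abs=1e-12)
        assert fit.d_star == pytest.approx(100.0, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    @given(d_star=st.floats(0.1, 1e4), alpha=st.floats(0.1, 1.95))
    @settings(max_examples=30, deadline=None)
    def test_exact_recovery_over_parameter_range(self, d_star, alpha):
        lags = np.logspace(1, np.log10(300), 16)
        curve = MSDCurve(lags=lags, msd=d_star * lags ** alpha,
                         n_pairs=np.full(16, 10))
        fit = mr.fit_power_law(curve)
        assert fit.alpha == pytest.approx(alpha, rel=1e-9, abs=1e-9)
        assert fit.d_star == pytest.approx(d_star, rel=1e-8)

    def test_default_remodeling_simulation_superdiffusive(self):
        trajs = sd.simulate_remodeling_trajectories(
            sd.RemodelingSimParams(n_beads=60, seed=13))
        fit = mr.fit_power_law(
            mr.ensemble_msd([mr.compute_msd(t) for t in trajs]))
        assert fit.alpha > 1.0

    def test_too_few_window_points_rejected(self):
        curve = MSDCurve(lags=[10.0, 20.0, 40.0], msd=[1, 2, 4],
                         n_pairs=[3, 2, 1])
        with pytest.raises(ValueError, match=">= 4"):
            mr.fit_power_law(curve)


def _noiseless_record(stiffness=2.0, torque=60.0, phase=0.0, drift=0.0):
    return sd.simulate_mtc_record(sd.MtcSimParams(
        stiffness=stiffness, torque_amplitude=torque, phase_lag=phase,
        drift_rate=drift, noise_sd=0.0))


class TestEstimateStiffness:
    def test_noiseless_ratio_exact(self):
        res = mr.estimate_stiffness(_noiseless_record())
        assert res.stiffness == pytest.approx(2.0, rel=1e-9)
        assert res.displacement_amplitude == pytest.approx(30.0, rel=1e-9)

    def test_phase_lag_recovered(self):
        res = mr.estimate_stiffness(_noiseless_record(phase=np.pi / 6))
        assert res.phase_lag == pytest.approx(np.pi / 6, abs=0.01)

    def test_noisy_drifting_record_within_2pct(self):
        rec = sd.simulate_mtc_record(sd.MtcSimParams(
            stiffness=1.5, noise_sd=2.0, drift_rate=1.0, seed=5))
        res = mr.estimate_stiffness(rec)
        assert res.stiffness == pytest.approx(1.5, rel=0.02)

    def test_invariant_to_offset_and_drift(self):
        rec = _noiseless_record(phase=0.2)
        res0 = mr.estimate_stiffness(rec)
        shifted = TwistRecord(rec.t, rec.specific_torque,
                              rec.displacement + 40.0 + 3.5 * rec.t,
                              rec.frequency)
        res1 = mr.estimate_stiffness(shifted)
        assert res1.stiffness == pytest.approx(res0.stiffness, rel=1e-9)
        assert res1.phase_lag == pytest.approx(res0.phase_lag, abs=1e-9)

    def test_low_amplitude_flagged(self):
        rec = sd.simulate_mtc_record(sd.MtcSimParams(
            stiffness=500.0, noise_sd=2.0, drift_rate=0.0, seed=1))
        res = mr.estimate_stiffness(rec)
        assert res.low_confidence

    def test_under_five_cycles_rejected(self):
        t = np.arange(0, 3.0, 0.01)
        with pytest.raises(ValueError, match="cycles"):
            TwistRecord(t, np.sin(2 * np.pi * t), np.sin(2 * np.pi * t), 1.0)
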