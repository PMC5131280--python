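"""Generator-level checks: known ground truth, closed forms, determinism."""

import numpy as np
import pytest

from asmkit import microrheology as mr
from asmkit import synthetic as sd


class TestRemodelingTrajectories:
    def test_brownian_limit_matches_4dt(self):
        # alpha = 1 reduces fBm to ordinary Brownian motion: MSD = 4 D tau
        # with d_star = 4D, within sampling error at short lags.
        params = sd.RemodelingSimParams(d_star=100.0, alpha=1.0,
                                        loc_noise_sd=0.0, frame_rate=12.0,
                                        duration=30.0, n_beads=500, seed=11)
        trajs = sd.simulate_remodeling_trajectories(params)
        ens = mr.ensemble_msd([mr.compute_msd(t) for t in trajs])
        sel = ens.lags <= params.duration / 10.0
        expected = params.d_star * ens.lags[sel]
        assert np.all(np.abs(ens.msd[sel] - expected) <= 0.05 * expected)

    def test_localization_noise_floor_dominates_smallest_lag(self):
        # closed-form static-error plateau: MSD -> 4 sigma^2 when motion
        # is negligible
        sigma = 50.0
        params = sd.RemodelingSimParams(d_star=0.001, alpha=1.0,
                                        loc_noise_sd=sigma, frame_rate=12.0,
                                        duration=60.0, n_beads=300, seed=2)
        trajs = sd.simulate_remodeling_trajectories(params)
        ens = mr.ensemble_msd([mr.compute_msd(t, lag_grid=[1 / 12.0])
                               for t in trajs])
        assert ens.msd[0] == pytest.approx(4.0 * sigma ** 2, rel=0.03)

    def test_ground_truth_recovered_by_loglog_fit(self):
        params = sd.RemodelingSimParams(d_star=20.0, alpha=1.6,
                                        loc_noise_sd=0.0, frame_rate=12.0,
                                        duration=300.0, n_beads=200, seed=7)
        trajs = sd.simulate_remodeling_trajectories(params)
        ens = mr.ensemble_msd([mr.compute_msd(t) for t in trajs])
        fit = mr.fit_power_law(ens, window=(10.0, 300.0))
        assert fit.alpha == pytest.approx(1.6, abs=0.1)
        assert fit.d_star == pytest.approx(20.0, rel=0.3)

    def test_substreams_reproducible_per_bead(self):
        base = sd.RemodelingSimParams(n_beads=5, duration=10.0, seed=42)
        small = sd.RemodelingSimParams(n_beads=2, duration=10.0, seed=42)
        t5 = sd.simulate_remodeling_trajectories(base)
        t2 = sd.simulate_remodeling_trajectories(small)
        for a, b in zip(t2, t5):
            np.testing.assert_array_equal(a.x, b.x)
            np.testing.assert_array_equal(a.y, b.y)

    @pytest.mark.parametrize("kwargs", [
        dict(alpha=2.0), dict(alpha=0.0), dict(d_star=-1.0), dict(d_star=0.0),
        dict(n_beads=0), dict(frame_rate=0.0),
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sd.RemodelingSimParams(**kwargs)


class TestRenderBeadStack:
    def _static_trajectory(self, x_px, y_px, n_frames=2, pixel_size=333.0):
        from asmkit.tracking import Trajectory
        return Trajectory(0, np.arange(n_frames) / 12.0,
                          np.full(n_frames, x_px * pixel_size),
                          np.full(n_frames, y_px * pixel_size), 12.0)

    def test_pixel_centered_spot_has_exact_centroid(self):
        traj = self._static_trajectory(16.0, 16.0)
        stack, truth = sd.render_bead_stack([traj], seed=None, shape=(33, 33),
                                            background_photons=0.0)
        img = stack[0]
        rr, cc = np.mgrid[0:33, 0:33]
        cx = (img * cc).sum() / img.sum()
        cy = (img * rr).sum() / img.sum()
        assert abs(cx - 16.0) < 1e-9 and abs(cy - 16.0) < 1e-9

    def test_subpixel_spot_centroid_within_hundredth_pixel(self):
        traj = self._static_trajectory(10.30, 10.70)
        stack, truth = sd.render_bead_stack([traj], seed=None, shape=(24, 24),
                                            background_photons=0.0)
        img = stack[0]
        rr, cc = np.mgrid[0:24, 0:24]
        cx = (img * cc).sum() / img.sum()
        cy = (img * rr).sum() / img.sum()
        assert abs(cx - 10.30) < 0.01 and abs(cy - 10.70) < 0.01

    def test_overlapping_spots_rejected(self):
        from asmkit.tracking import Trajectory
        t = np.arange(2) / 12.0
        a = Trajectory(0, t, np.full(2, 16 * 333.0), np.full(2, 16 * 333.0), 12.0)
        b = Trajectory(1, t, np.full(2, 17 * 333.0), np.full(2, 16 * 333.0), 12.0)
        with pytest.raises(ValueError, match="overlap"):
            sd.render_bead_stack([a, b], seed=None, shape=(33, 33))

    def test_margin_enforced(self):
        traj = self._static_trajectory(2.0, 2.0)
        with pytest.raises(ValueError, match="margin"):
            sd.render_bead_stack([traj], seed=None, shape=(33, 33))


class TestMtcRecord:
    def test_noiseless_amplitude_is_torque_over_stiffness(self):
        rec = sd.simulate_mtc_record(sd.MtcSimParams(
            stiffness=2.0, torque_amplitude=60.0, noise_sd=0.0,
            drift_rate=0.0, phase_lag=0.0))
        assert np.max(rec.displacement) == pytest.approx(30.0, rel=1e-6)

    def test_zero_phase_lag_synchronous_zero_crossings(self):
        rec = sd.simulate_mtc_record(sd.MtcSimParams(
            noise_sd=0.0, drift_rate=0.0, phase_lag=0.0))
        sign_changes = np.where(np.diff(np.sign(rec.specific_torque)) != 0)[0]
        for i in sign_changes:
            assert abs(rec.displacement[i]) <= abs(rec.displacement).max() * 0.05

    def test_seeded_record_bitwise_reproducible(self):
        p = sd.MtcSimParams(seed=9)
        a = sd.simulate_mtc_record(p)
        b = sd.simulate_mtc_record(p)
        np.testing.assert_array_equal(a.displacement, b.displacement)

    def test_underresolved_sampling_rejected(self):
        with pytest.raises(ValueError, match="sample_rate"):
            sd.MtcSimParams(frequency=10.0, sample_rate=50.0)


class TestDoseResponsePlate:
    def test_zero_dose_expectation_is_baseline(self):
        plate = sd.simulate_dose_response(sd.HillSimParams(cv=0.0, seed=0))
        zero = plate[plate["dose_mM"] == 0.0]
        ratios = zero["firefly"] / zero["renilla"]
        assert np.allclose(ratios, 1.0)

    def test_hill_midpoint_at_ec50(self):
        p = sd.HillSimParams(ec50=2.0, hill_n=1.0, cv=0.0, seed=0)
        plate = sd.simulate_dose_response(p)
        at_ec50 = plate[plate["dose_mM"] == 0.0].copy()
        mid = sd.hill_curve(2.0, p.baseline, p.span, p.ec50, p.hill_n)
        assert mid == pytest.approx(p.baseline + p.span / 2.0)
        assert len(at_ec50) == p.n_rep

    def test_empty_dose_list_rejected(self):
        with pytest.raises(ValueError):
            sd.HillSimParams(doses=())


class TestOrCounts:
    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_or_counts(10, 0.0, {"OR51E2": 5.0})

    def test_planted_or_expected_counts(self):
        counts, lengths = sd.simulate_or_counts(
            500, 1e7, {"OR51E2": 50.0}, n_samples=20, seed=1)
        mu = 50.0 * lengths["OR51E2"] / 1000.0 * 10.0
        observed = counts.loc["OR51E2"].mean()
        assert observed == pytest.approx(mu, rel=0.2)


class TestEditedAmplicons:
    REF = ("ATGGCTGACCGTTACGATCAGTTCGGCATCGATCGATTACCGGTAGCTAGCTAGGATCCG"
           "ATCGTAGCTAGCATCGATCGGTACCAGGTACCTTAGCAAGGCCTTGACCAGTTGGCCAAT"
           "ATCGGATCCAAGCTTGGGCCCACTAGTTCTAGAGCGGCCGCCACCGCGGTGGAGCTCCAG")

    def test_exact_counts_mode_reproduces_stated_mix(self):
        params = sd.EditSimParams(reference=self.REF, cut_site=90,
                                  n_colonies=33, p_deletion=31 / 33,
                                  p_insertion=2 / 33, seed=5)
        _, truth = sd.simulate_edited_amplicons(params, exact_counts=True)
        assert (truth["edit_type"] == "deletion").sum() == 31
        assert (truth["edit_type"] == "insertion").sum() == 2

    def test_truth_table_net_sizes_consistent(self):
        params = sd.EditSimParams(reference=self.REF, cut_site=90,
                                  n_colonies=20, seed=3)
        records, truth = sd.simulate_edited_amplicons(params)
        for (_, seq), (_, row) in zip(records, truth.iterrows()):
            assert len(seq) - len(self.REF) == row["net_size"]
            assert row["frameshift"] == (row["net_size"] != 0
                                         and abs(row["net_size"]) % 3 != 0)

    def test_cut_site_near_end_rejected(self):
        with pytest.raises(ValueError):
            sd.EditSimParams(reference=self.REF, cut_site=2)
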