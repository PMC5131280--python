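"""Localization and linking checks against rendered ground truth."""

import itertools

import numpy as np
import pytest

from asmkit import synthetic as sd
from asmkit import tracking as tk
from asmkit.tracking import Trajectory


def _render_static(x_px, y_px, *, peak=7e4, bg=100.0, seed=None, size=33):
    traj = Trajectory(0, np.arange(2) / 12.0,
                      np.full(2, x_px * 333.0), np.full(2, y_px * 333.0), 12.0)
    stack, truth = sd.render_bead_stack(
        [traj], psf_sigma=1.5, pixel_size=333.0, peak_photons=peak,
        background_photons=bg, seed=seed, shape=(size, size))
    return stack[0], truth[0, 0]


class TestLocateBeads:
    def test_pixel_centered_spot_localized_exactly(self):
        img, truth = _render_static(16.0, 16.0, bg=0.0)
        det, = tk.locate_beads(img)
        assert det.x_px == pytest.approx(16.0, abs=1e-9)
        assert det.y_px == pytest.approx(16.0, abs=1e-9)

    def test_subpixel_spot_matches_weighted_mean_oracle(self):
        img, truth = _render_static(10.30, 10.70, bg=0.0, size=24)
        det, = tk.locate_beads(img)
        # oracle: direct intensity-weighted mean over the whole array
        rr, cc = np.mgrid[0:img.shape[0], 0:img.shape[1]]
        ox = (img * cc).sum() / img.sum()
        oy = (img * rr).sum() / img.sum()
        assert det.x_px == pytest.approx(ox, abs=5e-3)
        assert det.y_px == pytest.approx(oy, abs=5e-3)
        assert det.x_px == pytest.approx(10.30, abs=0.01)
        assert det.y_px == pytest.approx(10.70, abs=0.01)

    def test_all_background_frame_yields_empty_list(self):
        assert tk.locate_beads(np.full((32, 32), 7.0)) == []
        assert tk.locate_beads(np.zeros((0, 0))) == []

    def test_translation_equivariance(self):
        img, _ = _render_static(12.3, 13.8, bg=50.0, seed=4, size=40)
        det, = tk.locate_beads(img)
        shifted = np.roll(np.roll(img, 5, axis=0), -3, axis=1)
        det2, = tk.locate_beads(shifted)
        assert det2.x_px - det.x_px == pytest.approx(-3.0, abs=1e-9)
        assert det2.y_px - det.y_px == pytest.approx(5.0, abs=1e-9)

    def test_rms_error_decreases_with_photon_budget(self):
        rng = np.random.default_rng(8)
        budgets = [7e2, 7e3, 7e4]
        rms = []
        for k, peak in enumerate(budgets):
            errs = []
            for i in range(40):
                x = 16 + rng.uniform(-0.5, 0.5)
                y = 16 + rng.uniform(-0.5, 0.5)
                img, _ = _render_static(x, y, peak=peak, bg=20.0,
                                        seed=1000 * k + i)
                det, = tk.locate_beads(img)
                errs.append((det.x_px - x) ** 2 + (det.y_px - y) ** 2)
            rms.append(np.sqrt(np.mean(errs)))
        assert rms[0] > rms[1] > rms[2]

    def test_high_snr_localization_below_5nm(self):
        # integrated spot signal >= 1e6 photons at 333 nm pixels: the
        # center-of-mass estimator must resolve positions to 5 nm RMS
        rng = np.random.default_rng(3)
        peak = 1e6 / (2 * np.pi * 1.5 ** 2)
        errs = []
        for i in range(100):
            x = 16 + rng.uniform(-0.5, 0.5)
            y = 16 + rng.uniform(-0.5, 0.5)
            img, _ = _render_static(x, y, peak=peak, bg=100.0, seed=i)
            det, = tk.locate_beads(img)
            errs.append((det.x_px - x) ** 2 + (det.y_px - y) ** 2)
        rms_nm = np.sqrt(np.mean(errs)) * 333.0
        assert rms_nm <= 5.0

    def test_saturated_roi_flagged(self):
        img, _ = _render_static(16.0, 16.0, bg=0.0)
        capped = np.minimum(img, 4095).astype(np.uint16)
        capped[16, 16] = np.iinfo(np.uint16).max
        det, = tk.locate_beads(capped)
        assert det.saturated


def _det(frame, x, y):
    return tk.SpotDetection(frame=frame, x_px=x, y_px=y, total_intensity=1.0,
                            roi=(int(y) - 2, int(y) + 2, int(x) - 2, int(x) + 2))


def _brute_force_assignment(prev, cur, max_step):
    """Oracle: globally optimal one-to-one assignment by enumeration."""
    best, best_cost = None, np.inf
    m = min(len(prev), len(cur))
    for perm in itertools.permutations(range(len(cur)), m):
        cost = 0.0
        ok = True
        for i, j in enumerate(perm):
            d = np.hypot(prev[i][0] - cur[j].x_px, prev[i][1] - cur[j].y_px)
            if d > max_step:
                ok = False
                break
            cost += d
        if ok and cost < best_cost:
            best, best_cost = perm, cost
    return best


class TestLinkTrajectories:
    def test_single_bead_full_length(self):
        dets = [[_det(f, 10.0, 10.0)] for f in range(20)]
        trajs = tk.link_trajectories(dets, max_step_nm=500, pixel_size_nm=333,
                                     frame_rate=12.0)
        assert len(trajs) == 1 and len(trajs[0]) == 20

    def test_two_stationary_beads_no_identity_swap(self):
        rng = np.random.default_rng(0)
        positions = [(10.0, 10.0), (30.0, 10.0)]  # 20 px apart
        dets = []
        for f in range(50):
            frame = [_det(f, x + rng.normal(0, 0.1), y + rng.normal(0, 0.1))
                     for x, y in positions]
            dets.append(frame)
        trajs = tk.link_trajectories(dets, max_step_nm=700, pixel_size_nm=333,
                                     frame_rate=12.0)
        assert len(trajs) == 2
        # each trajectory stays near its seed position (no swaps), and the
        # greedy linking agrees with the brute-force optimal assignment
        for t, (x0, _) in zip(sorted(trajs, key=lambda t: t.x[0]), positions):
            assert np.all(np.abs(t.x / 333.0 - x0) < 1.0)
        for f in range(1, 50):
            prev = [(d.x_px, d.y_px) for d in dets[f - 1]]
            perm = _brute_force_assignment(prev, dets[f], max_step=700 / 333)
            assert perm == (0, 1)

    def test_disappearing_bead_truncates_trajectory(self):
        dets = [[_det(f, 10.0, 10.0)] for f in range(8)] + [[] for _ in range(5)]
        trajs = tk.link_trajectories(dets, max_step_nm=500, pixel_size_nm=333,
                                     frame_rate=12.0)
        assert len(trajs) == 1 and len(trajs[0]) == 8

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            tk.link_trajectories([[_det(0, 1, 1)]], 500, 333, 12.0)


class TestGlobalDrift:
    def test_common_drift_removed(self):
        times = np.arange(30) / 12.0
        drift = 7.0 * times
        rng = np.random.default_rng(1)
        trajs = [Trajectory(i, times, drift + rng.normal(0, 1, 30) + 100 * i,
                            drift.copy(), 12.0) for i in range(4)]
        out = tk.subtract_global_drift(trajs)
        for t in out:
            assert np.std(np.diff(t.y)) == pytest.approx(0.0, abs=1e-9)
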