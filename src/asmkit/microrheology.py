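"""Passive and active bead microrheology.

Passive arm (spontaneous nanoscale tracer motions): time-averaged mean
square displacement of anchored-bead trajectories, bead-ensemble
averaging, and an unweighted log-log least-squares fit of the power law
MSD(tau) = D* (tau / 1 s)^alpha over a configurable lag window (default
10-300 s).  alpha = 1 marks thermal diffusion; alpha > 1 marks ATP-driven
cytoskeletal remodeling.

Active arm (magnetic twisting cytometry): a sinusoidal specific torque
drives the bead, and cell stiffness is the ratio of torque amplitude to
lateral displacement amplitude, in Pa/nm, extracted by least-squares
projection onto quadrature sinusoids at the drive frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tracking import Trajectory

__all__ = [
    "MSDCurve", "PowerLawFit", "TwistRecord", "StiffnessResult",
    "compute_msd", "ensemble_msd", "default_lag_grid",
    "MsdPowerLawModel", "fit_power_law",
    "TwistResponseModel", "estimate_stiffness",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class MSDCurve:
    """Mean square displacement versus lag time.

    ``n_pairs`` counts displacement pairs (per-bead curves) or
    contributing beads (ensemble curves); ``level`` records which.
    """

    lags: np.ndarray      # s, increasing
    msd: np.ndarray       # nm^2
    n_pairs: np.ndarray   # count per lag
    level: str = "bead"   # "bead" | "ensemble"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")
        if np.any(self.n_pairs < 1):
            raise ValueError("every lag needs at least one pair")

    def plot(self, ax=None, **kwargs):
        """Log-log MSD plot (thin matplotlib wrapper)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.loglog(self.lags, self.msd, marker="o", ls="-", **kwargs)
        ax.set_xlabel(r"lag $\tau$ (s)")
        ax.set_ylabel(r"MSD (nm$^2$)")
        return ax


@dataclass
class PowerLawFit:
    """Result of a log-log power-law fit to an MSD curve."""

    d_star: float            # nm^2 at the 1 s reference lag
    alpha: float
    window: tuple[float, float]  # s
    r2: float
    n_points: int
    se_alpha: float = float("nan")
    se_log10_d_star: float = float("nan")

    def __post_init__(self) -> None:
        if self.d_star <= 0:
            raise ValueError("d_star must be positive")
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")

    def predict(self, lags) -> np.ndarray:
        lags = np.asarray(lags, dtype=float)
        return self.d_star * lags ** self.alpha

    def summary(self) -> str:
        lines = [
            "MSD power-law fit: MSD(tau) = D* (tau/1 s)^alpha",
            f"  window      : {self.window[0]:g}-{self.window[1]:g} s "
            f"({self.n_points} points)",
            f"  D*          : {self.d_star:.4g} nm^2  "
            f"(SE log10 D* = {self.se_log10_d_star:.3g})",
            f"  alpha       : {self.alpha:.4f}  (SE = {self.se_alpha:.3g})",
            f"  R^2         : {self.r2:.5f}",
        ]
        return "\n".join(lines)


@dataclass
class TwistRecord:
    """Specific-torque and displacement waveforms of one twisting run."""

    t: np.ndarray               # s
    specific_torque: np.ndarray  # Pa
    displacement: np.ndarray     # nm
    frequency: float             # Hz, drive

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.specific_torque = np.asarray(self.specific_torque, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        dt = np.diff(self.t)
        if len(self.t) < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("record must be uniformly sampled")
        if (self.t[-1] - self.t[0]) * self.frequency < 5 - 1e-9:
            raise ValueError("record must span at least 5 full drive cycles")

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


@dataclass
class StiffnessResult:
    """Cell stiffness estimated from one twisting record."""

    stiffness: float               # Pa/nm
    phase_lag: float               # rad, displacement behind torque
    displacement_amplitude: float  # nm
    torque_amplitude: float        # Pa
    low_confidence: bool = False
    noise_floor: float = float("nan")  # residual sd, nm

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError("stiffness must be positive")
        if not 0.0 <= self.phase_lag <= np.pi:
            raise ValueError("phase_lag must lie in [0, pi]")

    def summary(self) -> str:
        flag = "  [LOW CONFIDENCE: amplitude < 3x noise floor]" if self.low_confidence else ""
        return "\n".join([
            "Magnetic twisting cytometry fit",
            f"  torque amplitude       : {self.torque_amplitude:.4g} Pa",
            f"  displacement amplitude : {self.displacement_amplitude:.4g} nm",
            f"  stiffness              : {self.stiffness:.4g} Pa/nm{flag}",
            f"  phase lag              : {self.phase_lag:.4f} rad",
        ])


# ---------------------------------------------------------------------------
# MSD

def default_lag_grid(frame_rate: float, n_frames: int,
                     points_per_decade: int = 16) -> np.ndarray:
    """Log-spaced down-selection of integer-frame lags, in seconds.

    ~16 points per decade from one frame interval up to the full record,
    so long lags do not dominate an unweighted log-log regression.
    """
    max_lag = n_frames - 1
    decades = np.log10(max_lag)
    n_pts = max(int(np.ceil(decades * points_per_decade)), 2)
    k = np.unique(np.round(np.logspace(0, np.log10(max_lag), n_pts)).astype(int))
    return k / frame_rate


def compute_msd(traj: Trajectory, lag_grid=None) -> MSDCurve:
    """Time-averaged MSD with overlapping pairs.

    MSD(tau) = mean_i |r(t_i + tau) - r(t_i)|^2 over all start frames i.
    Lags must be integer multiples of the frame interval; the default grid
    is the log-spaced selection of :func:`default_lag_grid`.
    """
    n = len(traj)
    dt = traj.dt
    if lag_grid is None:
        lag_grid = default_lag_grid(traj.frame_rate, n)
    lag_grid = np.asarray(lag_grid, dtype=float)
    steps = lag_grid / dt
    k = np.round(steps).astype(int)
    if np.any(np.abs(steps - k) > 1e-6 * np.maximum(1, k)):
        raise ValueError("lags must be integer multiples of the frame interval")
    if np.any(k < 1) or np.any(k > n - 1):
        raise ValueError("lags must lie in [frame interval, duration]")

    msd = np.empty(len(k))
    n_pairs = np.empty(len(k), dtype=int)
    for j, kk in enumerate(k):
        dx = traj.x[kk:] - traj.x[:-kk]
        dy = traj.y[kk:] - traj.y[:-kk]
        msd[j] = np.mean(dx * dx + dy * dy)
        n_pairs[j] = n - kk
    return MSDCurve(lags=k * dt, msd=msd, n_pairs=n_pairs, level="bead")


def ensemble_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Arithmetic mean of per-bead MSD at each lag (well-level curve).

    Beads lacking a given lag are excluded from that lag's mean;
    ``n_pairs`` counts contributing beads per lag.
    """
    if not curves:
        raise ValueError("no curves to average")
    all_lags = np.unique(np.concatenate([c.lags for c in curves]))
    sums = np.zeros(len(all_lags))
    counts = np.zeros(len(all_lags), dtype=int)
    for c in curves:
        idx = np.searchsorted(all_lags, c.lags)
        # guard against float mismatch between grids
        ok = np.isclose(all_lags[idx], c.lags, rtol=1e-9, atol=1e-12)
        sums[idx[ok]] += c.msd[ok]
        counts[idx[ok]] += 1
    keep = counts > 0
    return MSDCurve(lags=all_lags[keep], msd=sums[keep] / counts[keep],
                    n_pairs=counts[keep], level="ensemble")


# ---------------------------------------------------------------------------
# power-law fit

class MsdPowerLawModel:
    """Unweighted least squares of log10 MSD on log10 lag.

    The slope is the anomalous exponent alpha and the intercept (at the
    1 s reference lag) is log10 D*.  The default window keeps lags
    greater than 10 s and up to 300 s, where anchored-bead motion is
    dominated by cytoskeletal remodeling rather than localization noise.
    """

    def __init__(self, msd: MSDCurve, window: tuple[float, float] = (10.0, 300.0)):
        self.msd = msd
        self.window = (float(window[0]), float(window[1]))
        if self.window[0] >= self.window[1]:
            raise ValueError("window must be (lo, hi) with lo < hi")

    def fit(self) -> PowerLawFit:
        lo, hi = self.window
        sel = (self.msd.lags >= lo) & (self.msd.lags <= hi)
        lags = self.msd.lags[sel]
        msd = self.msd.msd[sel]
        if np.any(msd <= 0):
            warnings.warn("dropping non-positive MSD values inside the fit window")
            keep = msd > 0
            lags, msd = lags[keep], msd[keep]
        if len(lags) < 4:
            raise ValueError("need >= 4 positive MSD points inside the window")
        x = np.log10(lags)   # lag in units of the 1 s reference
        y = np.log10(msd)
        design = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        alpha, intercept = float(coef[0]), float(coef[1])
        resid = y - design @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        dof = len(x) - 2
        if dof > 0 and ss_res > 0:
            s2 = ss_res / dof
            cov = s2 * np.linalg.inv(design.T @ design)
            se_alpha = float(np.sqrt(cov[0, 0]))
            se_int = float(np.sqrt(cov[1, 1]))
        else:
            se_alpha = se_int = 0.0
        return PowerLawFit(d_star=10.0 ** intercept, alpha=alpha,
                           window=self.window, r2=r2, n_points=len(x),
                           se_alpha=se_alpha, se_log10_d_star=se_int)


def fit_power_law(msd: MSDCurve,
                  window: tuple[float, float] = (10.0, 300.0)) -> PowerLawFit:
    """Convenience wrapper: ``MsdPowerLawModel(msd, window).fit()``."""
    return MsdPowerLawModel(msd, window).fit()


# ---------------------------------------------------------------------------
# magnetic twisting cytometry

class TwistResponseModel:
    """Quadrature demodulation of a twisting record at the drive frequency.

    Displacement is linearly detrended, the first drive cycle (bead
    settling) is discarded, and in-phase/quadrature amplitudes of both
    channels are extracted by least squares against sin/cos at the drive
    frequency.  Stiffness = torque amplitude / displacement amplitude.
    """

    def __init__(self, record: TwistRecord, frequency: float | None = None,
                 discard_first_cycle: bool = True):
        self.record = record
        self.frequency = frequency if frequency is not None else record.frequency
        self.discard_first_cycle = discard_first_cycle
        if self.frequency <= 0:
            raise ValueError("drive frequency must be positive")

    @staticmethod
    def _quadrature(t: np.ndarray, y: np.ndarray, freq: float):
        """Return (amplitude, phase, resid_sd) for y ~ A sin(wt + phi) + c + b t."""
        omega = 2.0 * np.pi * freq
        design = np.column_stack([np.sin(omega * t), np.cos(omega * t),
                                  np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        a, b = coef[0], coef[1]
        amplitude = float(np.hypot(a, b))
        phase = float(np.arctan2(b, a))  # y ~ A sin(wt + phase)
        resid = y - design @ coef
        resid_sd = float(np.std(resid))
        return amplitude, phase, resid_sd

    def fit(self) -> StiffnessResult:
        rec = self.record
        t, torque, disp = rec.t, rec.specific_torque, rec.displacement
        if self.discard_first_cycle:
            keep = t - t[0] >= 1.0 / self.frequency
            t, torque, disp = t[keep], torque[keep], disp[keep]
        # linear detrend (drift and offset are nuisance; also in the design)
        slope, intercept = np.polyfit(t, disp, 1)
        disp = disp - (slope * t + intercept)

        amp_tq, ph_tq, _ = self._quadrature(t, torque, self.frequency)
        amp_d, ph_d, resid_sd = self._quadrature(t, disp, self.frequency)
        if amp_d <= 0:
            raise ValueError("displacement shows no response at the drive frequency")
        phase_lag = (ph_tq - ph_d) % (2.0 * np.pi)
        if phase_lag > np.pi:
            phase_lag = 2.0 * np.pi - phase_lag
        return StiffnessResult(
            stiffness=amp_tq / amp_d,
            phase_lag=phase_lag,
            displacement_amplitude=amp_d,
            torque_amplitude=amp_tq,
            low_confidence=bool(amp_d < 3.0 * resid_sd),
            noise_floor=resid_sd,
        )


def estimate_stiffness(rec: TwistRecord, frequency: float | None = None,
                       discard_first_cycle: bool = True) -> StiffnessResult:
    """Convenience wrapper: ``TwistResponseModel(rec, frequency).fit()``."""
    return TwistResponseModel(rec, frequency, discard_first_cycle).fit()
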