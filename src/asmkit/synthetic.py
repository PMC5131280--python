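"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the downstream estimators assume:

* spontaneous bead motion as 2-D fractional Brownian motion whose ensemble
  mean-square displacement follows MSD(tau) = D* (tau / 1 s)^alpha, plus
  static (white Gaussian) localization noise;
* image stacks of diffraction-limited Gaussian spots with Poisson photon
  noise, for exercising the centroid tracker against exact positions;
* sinusoidal torque/displacement records of a linearly viscoelastic cell
  under magnetic twisting, with drift and additive noise;
* Hill-type reporter dose-response plates with log-normal replicate noise;
* a count matrix with low-abundance odorant-receptor genes planted at
  target FPKM levels over a negative-binomial background transcriptome;
* Cas9-edited amplicon sequences with a truth table of indel calls.

All generators are deterministic given their seed; per-entity substreams
are keyed by (seed, entity id) so individual beads/colonies are
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, toeplitz

from .tracking import Trajectory

__all__ = [
    "RemodelingSimParams", "MtcSimParams", "HillSimParams", "EditSimParams",
    "simulate_remodeling_trajectories", "render_bead_stack",
    "simulate_mtc_record", "simulate_dose_response", "simulate_or_counts",
    "simulate_edited_amplicons", "hill_curve",
]

_DNA = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# parameter containers

@dataclass
class RemodelingSimParams:
    """Ground truth for spontaneous nanoscale bead motion.

    ``d_star`` is the MSD power-law prefactor in nm² at the reference lag
    of 1 s; ``alpha`` the anomalous exponent (1 = thermal diffusion,
    >1 = super-diffusive, motor-driven remodeling).  Defaults reproduce
    live-cell acquisition settings (12 frames/s for 300 s) and place the
    ensemble MSD in the 10²–10⁴ nm² range over 10–300 s lags typical of
    cytoskeleton-anchored beads on airway smooth muscle.
    """

    d_star: float = 5.0        # nm² at 1 s
    alpha: float = 1.35        # dimensionless, in (0, 2)
    loc_noise_sd: float = 5.0  # nm per axis, static localization error
    frame_rate: float = 12.0   # Hz
    duration: float = 300.0    # s
    n_beads: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_star <= 0:
            raise ValueError("d_star must be positive")
        if not 0.0 < self.alpha < 2.0:
            raise ValueError("alpha must lie in (0, 2)")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be positive")
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if self.loc_noise_sd < 0:
            raise ValueError("loc_noise_sd must be >= 0")


@dataclass
class MtcSimParams:
    """Ground truth for a magnetic-twisting record.

    A bead on a linearly viscoelastic cell driven by a sinusoidal specific
    torque responds at the drive frequency with amplitude
    torque_amplitude/stiffness and a phase lag, on top of slow drift and
    measurement noise.
    """

    stiffness: float = 1.5        # Pa/nm
    torque_amplitude: float = 60.0  # Pa (specific torque)
    frequency: float = 0.75       # Hz
    phase_lag: float = 0.3        # rad, in [0, pi/2)
    drift_rate: float = 1.0       # nm/s
    noise_sd: float = 2.0         # nm
    duration: float = 20.0        # s
    sample_rate: float = 100.0    # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError("stiffness must be positive")
        if self.torque_amplitude <= 0:
            raise ValueError("torque_amplitude must be positive")
        if not 0.0 <= self.phase_lag < np.pi / 2:
            raise ValueError("phase_lag must lie in [0, pi/2)")
        if self.sample_rate < 10 * self.frequency:
            raise ValueError("sample_rate must be >= 10x drive frequency "
                             "(waveform under-resolved)")


@dataclass
class HillSimParams:
    """Ground truth for a reporter-assay dose-response plate.

    The normalized firefly/renilla ratio follows
    baseline + span * d^n / (d^n + ec50^n) with multiplicative log-normal
    replicate noise of coefficient of variation ``cv``.  Default doses span
    the physiological short-chain fatty acid range with an EC50 of 2 mM.
    """

    baseline: float = 1.0
    span: float = 2.0
    ec50: float = 2.0       # mM
    hill_n: float = 1.0
    cv: float = 0.1
    doses: tuple[float, ...] = (0.0, 0.3, 1.0, 3.0, 10.0, 30.0)  # mM
    n_rep: int = 3
    seed: int = 0
    construct: str = "OR51E2"
    ligand: str = "acetate"

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be positive")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if len(self.doses) == 0:
            raise ValueError("doses must be non-empty")


@dataclass
class EditSimParams:
    """Ground truth for a cohort of Cas9-edited colony amplicons."""

    reference: str
    cut_site: int                  # 0-based position in reference
    n_colonies: int = 33
    p_deletion: float = 31 / 33
    p_insertion: float = 2 / 33
    size_range: tuple[int, int] = (1, 12)  # bp
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_deletion <= 1 or not 0 <= self.p_insertion <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.p_deletion + self.p_insertion > 1 + 1e-12:
            raise ValueError("p_deletion + p_insertion must be <= 1")
        if not 0 <= self.cut_site < len(self.reference):
            raise ValueError("cut_site must lie within the reference")
        margin = self.size_range[1] + 5
        if self.cut_site < margin or self.cut_site > len(self.reference) - margin:
            raise ValueError("cut_site too close to the sequence end for the "
                             "requested indel sizes")
        if self.size_range[0] < 1 or self.size_range[1] < self.size_range[0]:
            raise ValueError("invalid size_range")


# ---------------------------------------------------------------------------
# spontaneous bead motion (fractional Brownian motion)

def _fgn_cholesky_factor(n_steps: int, hurst: float) -> np.ndarray:
    """Lower Cholesky factor of the unit-variance fGn correlation matrix.

    Exact covariance of fractional Gaussian noise:
    rho(k) = 0.5 (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}).
    Exact factorization is affordable at acquisition scale (<= 3600 frames).
    """
    k = np.arange(n_steps, dtype=float)
    two_h = 2.0 * hurst
    rho = 0.5 * (np.abs(k + 1) ** two_h - 2 * np.abs(k) ** two_h
                 + np.abs(k - 1) ** two_h)
    return cholesky(toeplitz(rho), lower=True)


def simulate_remodeling_trajectories(
    params: RemodelingSimParams,
) -> list[Trajectory]:
    """Simulate anchored-bead trajectories with a power-law ensemble MSD.

    Each axis is fractional Brownian motion with Hurst exponent
    H = alpha/2, scaled so the expected 2-D MSD at lag tau equals
    d_star * (tau / 1 s)^alpha, plus independent Gaussian localization
    noise per frame (which adds the analytic 4*sigma^2 plateau to the
    observed MSD).  Bead b uses the random substream keyed by
    (seed, b), so any subset of beads is reproducible.
    """
    n_frames = int(round(params.frame_rate * params.duration))
    if n_frames < 2:
        raise ValueError("duration x frame_rate must give >= 2 frames")
    dt = 1.0 / params.frame_rate
    hurst = params.alpha / 2.0
    n_steps = n_frames - 1

    # per-axis increment sd over one frame: Var per axis = (d_star/2) dt^alpha
    step_sd = np.sqrt(params.d_star / 2.0) * dt ** hurst

    lower = _fgn_cholesky_factor(n_steps, hurst)

    # one standard-normal matrix per bead, drawn from its own substream,
    # colored jointly by a single GEMM
    z = np.empty((n_steps, 2 * params.n_beads))
    noise = np.empty((n_frames, 2 * params.n_beads))
    for b in range(params.n_beads):
        rng = np.random.default_rng([params.seed, b])
        z[:, 2 * b:2 * b + 2] = rng.standard_normal((n_steps, 2))
        noise[:, 2 * b:2 * b + 2] = rng.standard_normal((n_frames, 2))
    increments = step_sd * (lower @ z)
    positions = np.vstack([np.zeros((1, 2 * params.n_beads)),
                           np.cumsum(increments, axis=0)])
    positions += params.loc_noise_sd * noise

    times = np.arange(n_frames) * dt
    return [
        Trajectory(bead_id=b, times=times,
                   x=positions[:, 2 * b], y=positions[:, 2 * b + 1],
                   frame_rate=params.frame_rate)
        for b in range(params.n_beads)
    ]


# ---------------------------------------------------------------------------
# image rendering

def render_bead_stack(
    trajectories: list[Trajectory],
    psf_sigma: float = 1.5,          # px
    pixel_size: float = 333.0,       # nm/px
    peak_photons: float = 5e4,       # photons at spot center, per frame
    background_photons: float = 100.0,  # photons per pixel
    seed: int | None = 0,
    shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render trajectories as an image stack of Gaussian spots.

    Each frame holds one symmetric Gaussian spot per bead at its true
    sub-pixel position (integrated spot signal = peak_photons * 2 pi
    sigma^2), over a flat background, with Poisson photon noise applied
    when ``seed`` is not None.  Returns ``(stack, truth)`` where ``stack``
    has shape (n_frames, H, W) and ``truth[f, b] = (x_px, y_px)`` are the
    exact positions rendered.

    Trajectories must fit in the field of view with a margin of at least
    3 sigma; spots closer than 4 sigma are rejected (their centroids would
    be inseparable downstream).
    """
    if not trajectories:
        raise ValueError("no trajectories to render")
    n_frames = len(trajectories[0])
    if any(len(t) != n_frames for t in trajectories):
        raise ValueError("all trajectories must have equal length")

    xs = np.stack([t.x for t in trajectories], axis=1) / pixel_size  # px
    ys = np.stack([t.y for t in trajectories], axis=1) / pixel_size

    margin = 3.0 * psf_sigma
    if shape is None:
        # place content at margin + 2 sigma from the top-left corner
        off = margin + 2.0 * psf_sigma
        xs = xs - xs.min() + off
        ys = ys - ys.min() + off
        shape = (int(np.ceil(ys.max() + off)) + 1, int(np.ceil(xs.max() + off)) + 1)
    h, w = shape
    if (xs.min() < margin or ys.min() < margin
            or xs.max() > w - 1 - margin or ys.max() > h - 1 - margin):
        raise ValueError("trajectories must fit the field of view with a "
                         "margin >= 3 sigma")

    n_beads = xs.shape[1]
    for f in range(n_frames):
        for i in range(n_beads):
            for j in range(i + 1, n_beads):
                d = np.hypot(xs[f, i] - xs[f, j], ys[f, i] - ys[f, j])
                if d < 4.0 * psf_sigma:
                    raise ValueError(
                        f"spots {i} and {j} overlap in frame {f} "
                        f"({d:.2f} px < 4 sigma)")

    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    stack = np.empty((n_frames, h, w))
    rng = np.random.default_rng(seed) if seed is not None else None
    inv2s2 = 1.0 / (2.0 * psf_sigma ** 2)
    for f in range(n_frames):
        img = np.full((h, w), float(background_photons))
        for b in range(n_beads):
            img += peak_photons * np.exp(-((cc - xs[f, b]) ** 2
                                           + (rr - ys[f, b]) ** 2) * inv2s2)
        stack[f] = rng.poisson(img) if rng is not None else img

    truth = np.stack([xs, ys], axis=-1)  # (n_frames, n_beads, 2) in px
    return stack, truth


# ---------------------------------------------------------------------------
# magnetic twisting cytometry

def simulate_mtc_record(params: MtcSimParams):
    """Simulate a sinusoidal torque/displacement record.

    torque(t) = A sin(2 pi f t);
    displacement(t) = (A / stiffness) sin(2 pi f t - phase_lag)
                      + drift_rate * t + N(0, noise_sd^2).
    """
    from .microrheology import TwistRecord  # local import avoids a cycle

    n = int(round(params.sample_rate * params.duration))
    t = np.arange(n) / params.sample_rate
    omega = 2.0 * np.pi * params.frequency
    torque = params.torque_amplitude * np.sin(omega * t)
    disp = (params.torque_amplitude / params.stiffness
            * np.sin(omega * t - params.phase_lag)
            + params.drift_rate * t)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        disp = disp + rng.normal(0.0, params.noise_sd, size=n)
    return TwistRecord(t=t, specific_torque=torque, displacement=disp,
                       frequency=params.frequency)


# ---------------------------------------------------------------------------
# reporter-assay plates

def hill_curve(dose, baseline: float, span: float, ec50: float, hill_n: float):
    """Hill (variable-slope) response; defined to equal ``baseline`` at dose 0."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        dn = np.where(dose > 0, dose ** hill_n, 0.0)
    return baseline + span * dn / (dn + ec50 ** hill_n)


def simulate_dose_response(params: HillSimParams) -> pd.DataFrame:
    """Simulate a firefly/renilla plate table for one construct and ligand.

    The expected firefly/renilla ratio follows the Hill curve; replicate
    noise is multiplicative log-normal with coefficient of variation
    ``cv``, mean-corrected so the expectation stays on the curve.  Renilla
    luminescence is drawn around 1e5 a.u. with mild well-to-well scatter
    (transfection-efficiency variation), and firefly is ratio x renilla,
    so common per-well scalings cancel downstream.
    """
    rng = np.random.default_rng(params.seed)
    sigma = np.sqrt(np.log1p(params.cv ** 2))
    rows = []
    for dose in params.doses:
        mu = float(hill_curve(dose, params.baseline, params.span,
                              params.ec50, params.hill_n))
        for rep in range(params.n_rep):
            renilla = 1e5 * rng.lognormal(-0.02, 0.2)
            ratio = mu * rng.lognormal(-0.5 * sigma ** 2, sigma)
            rows.append({
                "construct": params.construct,
                "ligand": params.ligand,
                "dose_mM": dose,
                "firefly": ratio * renilla,
                "renilla": renilla,
                "rep": rep,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transcriptome counts with planted OR genes

def simulate_or_counts(
    n_genes: int,
    depth: float,
    or_fpkm: dict[str, float],
    n_samples: int = 6,
    seed: int = 0,
    length_range: tuple[int, int] = (500, 5000),
    dispersion: float = 0.3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a count matrix with OR genes planted at target FPKM levels.

    Background genes draw negative-binomial counts around log-normal mean
    expression scaled to the requested sequencing depth; OR genes are
    Poisson around the exact expected count implied by their target FPKM
    (count = fpkm * length_kb * depth / 1e6), keeping planted enrichment
    order intact in expectation.  Returns ``(counts, lengths_bp)`` with
    genes as rows and samples as columns.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not or_fpkm:
        raise ValueError("or_fpkm must name at least one OR gene")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:05d}" for i in range(n_genes)] + list(or_fpkm)
    lengths = pd.Series(rng.integers(length_range[0], length_range[1] + 1,
                                     size=len(genes)),
                        index=genes, name="length_bp").astype(int)

    # background: relative expression from a log-normal, scaled to depth
    rel = rng.lognormal(0.0, 1.5, size=n_genes)
    rel /= rel.sum()
    counts = np.empty((len(genes), n_samples), dtype=np.int64)
    base_mu = rel * depth
    for s in range(n_samples):
        mu = np.clip(base_mu, 1e-8, None)
        # NB via gamma-Poisson mixture
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        counts[:n_genes, s] = rng.poisson(lam)
    for i, (gene, fpkm) in enumerate(or_fpkm.items()):
        mu = fpkm * (lengths[gene] / 1000.0) * (depth / 1e6)
        counts[n_genes + i] = rng.poisson(mu, size=n_samples)
    df = pd.DataFrame(counts, index=genes,
                      columns=[f"sample{s + 1}" for s in range(n_samples)])
    return df, lengths


# ---------------------------------------------------------------------------
# Cas9-edited amplicons

def simulate_edited_amplicons(
    params: EditSimParams,
    exact_counts: bool = False,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate per-colony edited amplicons and their truth table.

    Each colony carries a single deletion or insertion starting within
    +/- 3 bp of the Cas9 cut site (or no edit), with size drawn uniformly
    from ``size_range``.  With ``exact_counts=True`` the cohort contains
    exactly round(p * n) colonies of each type (deterministic class
    sizes; only sizes and positions remain random), which reproduces a
    stated colony mix exactly.

    Returns ``(records, truth)`` where ``records`` is a list of
    (colony_id, sequence) pairs and ``truth`` has one row per colony with
    edit_type, net_size, frameshift and edit position.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_colonies
    if exact_counts:
        n_del = int(round(params.p_deletion * n))
        n_ins = int(round(params.p_insertion * n))
        if n_del + n_ins > n:
            raise ValueError("rounded class counts exceed n_colonies")
        types = (["deletion"] * n_del + ["insertion"] * n_ins
                 + ["none"] * (n - n_del - n_ins))
        types = list(rng.permutation(types))
    else:
        p_none = 1.0 - params.p_deletion - params.p_insertion
        types = list(rng.choice(["deletion", "insertion", "none"], size=n,
                                p=[params.p_deletion, params.p_insertion,
                                   max(p_none, 0.0)]))

    ref = params.reference.upper()
    records: list[tuple[str, str]] = []
    rows = []
    for i, etype in enumerate(types):
        sub = np.random.default_rng([params.seed, i])
        offset = int(sub.integers(-3, 4))
        pos = params.cut_site + offset
        if etype == "none":
            seq, net = ref, 0
        else:
            size = int(sub.integers(params.size_range[0],
                                    params.size_range[1] + 1))
            if etype == "deletion":
                seq = ref[:pos] + ref[pos + size:]
                net = -size
            else:
                ins = "".join(sub.choice(_DNA, size=size))
                seq = ref[:pos] + ins + ref[pos:]
                net = size
        cid = f"colony{i + 1:03d}"
        records.append((cid, seq))
        rows.append({
            "colony_id": cid,
            "edit_type": etype,
            "net_size": net,
            "frameshift": bool(net != 0 and abs(net) % 3 != 0),
            "position": pos if etype != "none" else -1,
        })
    return records, pd.DataFrame(rows)
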