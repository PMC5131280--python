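# Methods

This note records the models behind each estimator, the synthetic-data
conditions used to validate them, and the numerical and design choices a
maintainer would otherwise have to reverse-engineer.

## Spontaneous bead motion and its simulator

Anchored-bead motion on a living cell is modelled per axis as fractional
Brownian motion (fBm) with Hurst exponent H = α/2 and stationary
increments, so the ensemble two-dimensional MSD is exactly

    MSD(τ) = D* · (τ / 1 s)^α,   0 < α < 2,

with D* in nm² **at the reference lag t₀ = 1 s**. The reference lag is a
convention, not a physical scale: it makes D* the intercept of the MSD
power law on log-log axes, which is how the fit reports it. α = 1 is the
Brownian limit; α > 1 (super-diffusion) is the signature of motor-driven
cytoskeletal remodeling, and the acquisition this package models
consistently sits in that regime.

The generator draws fractional Gaussian noise by exact Cholesky
factorization of the increment autocovariance

    ρ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}),

which is exact at acquisition scale (12 frames/s × 300 s = 3600 frames;
one 3599² factorization, reused across beads). Spectral or wavelet fBm
approximations were rejected: at this size exactness is affordable and
removes a whole class of bias questions from the parameter-recovery
suite. Per-axis increments are scaled by √(D*/2)·Δt^H so the 2-D MSD
matches the law above. Bead b draws its normal variates from the
substream keyed (seed, b), making any subset of beads bitwise
reproducible.

Static localization error is additive white Gaussian noise per axis and
frame (sd `loc_noise_sd`, default 5 nm — the accuracy the
center-of-mass tracker achieves at high SNR). It adds the analytic
plateau 4σ² to the observed MSD, which the tests use as a closed-form
oracle.

Defaults (D* = 5 nm², α = 1.35, 100 beads) place the ensemble MSD in the
10²–10⁴ nm² band over 10–300 s lags, the range typical of cultured ASM
wells; neither value is measured from real data, and no claim about real
cells rests on them.

## MSD estimation and power-law fitting

`compute_msd` is the time-averaged estimator with overlapping pairs —
maximal pair usage for 300 s records; `ensemble_msd` takes the
arithmetic mean across beads per lag (a bead missing a lag is excluded
from that lag only). The default lag grid down-selects integer-frame lags
to ~16 points per decade so that an unweighted log-log regression is not
dominated by the dense long-lag end.

`fit_power_law` regresses log₁₀ MSD on log₁₀(τ/1 s) over a window of
10–300 s by ordinary least squares: slope = α, 10^intercept = D*.
Non-positive MSD values inside the window are dropped with a warning and
at least four surviving points are required. The window default reflects
where remodeling dominates over the localization-noise plateau in this
kind of data. Two analysis levels are supported, mirroring how such
experiments are reported: a well-level fit on the bead-averaged MSD, and
per-bead fits whose distribution is summarized as geometric mean ± 95% CI.

Parameter recovery is validated on the grid D* ∈ {1, 20, 400} nm² ×
α ∈ {1.0, 1.3, 1.6, 1.9} with 200 beads per condition at 12 Hz / 300 s,
recovering α within ±0.1 and D* within ±30%. The grid runs with
`loc_noise_sd = 0`: it isolates the MSD estimator and fit, whereas the
grid point (D* = 1 nm², α = 1.0) has MSD(10 s) = 10 nm², an order of
magnitude below the 4σ² = 100 nm² plateau of the default 5 nm noise — no
estimator can read a power law through a floor that high, and
localization error is characterized separately (see tracking below).

## Bead localization and linking

Localization is intensity-weighted center of mass: subtract the image
median (beads are sparse, ~50–100 per field, so the median is a robust,
parameter-free background), clip at zero, threshold at a quantile
(default 0.995), and take the weighted mean over the above-threshold
region's bounding box expanded by a pad (default twice the region size,
minimum 3 px). The pad matters: truncating the Gaussian skirt at the
threshold contour biases sub-pixel positions toward the ROI center by
tens of nm; with the expanded ROI the estimator is unbiased to < 0.01 px
on noiseless spots. Coordinates are 0-based pixel indices at pixel
centers, x rightward, y downward, converted to nm by the configured
pixel size. On rendered stacks with ≥ 10⁶ photons of integrated spot
signal per frame at 333 nm pixels the RMS error is well under 5 nm
(~0.7–0.8 nm), degrading monotonically as the photon budget shrinks.

Linking is greedy nearest neighbour with a maximum step (beads are
anchored; inter-bead spacing is orders of magnitude above frame-to-frame
motion), equidistant ties broken toward the lower detection index and
logged. There is no gap closing and no PSF-model fitting by design. A
global-drift subtraction utility exists but is off by default, matching
an acquisition protocol that applies none.

## Magnetic twisting cytometry

The record model is a linearly viscoelastic response at the drive
frequency: torque T(t) = A·sin(2πft), displacement
d(t) = (A/g)·sin(2πft − φ) + drift·t + noise. The estimator linearly
detrends the displacement, discards the first drive cycle (bead
settling), and projects both channels onto sin/cos at the drive
frequency by least squares (constant and linear terms included in the
design, so the result is exactly invariant to offset and drift).
Stiffness g = torque amplitude / displacement amplitude (Pa/nm); the
phase lag comes from the quadrature components. Records whose
displacement amplitude is below 3× the residual noise floor are flagged
low-confidence rather than rejected. The drive frequency defaults to
0.75 Hz in the configuration and is deliberately configurable — it is an
instrument setting, not a constant of the method. Noisy, drifting
synthetic records (2 nm noise, 1 nm/s drift) are recovered within 2%.

## Reporter assay

Wells are normalized in two steps: firefly/renilla per well (cancelling
per-well transfection efficiency exactly), then division by the mean
ratio of the same construct/ligand series' own 0 mM wells, so every
series starts at 1. The Hill model is fitted on the natural scale with
the 0 mM wells anchoring the baseline parameter (log(0) is undefined, so
zero dose cannot enter a log-dose design; the Hill form used equals
baseline at d = 0). Numerical choices:

- Hill slope bounded to (0.3, 4) — identifiability with ≤ 7 doses in
  triplicate;
- EC50 bounded to within one decade of the measured positive doses and
  span to 3× the observed dynamic range: values outside those bounds are
  not estimable from a plate and only trap the optimizer on a ridge;
- multistart over EC50 ∈ {lowest dose, geometric middle, highest dose},
  best residual sum of squares wins; non-convergence is reported, never
  silently defaulted;
- "no response" is decided by an extra-sum-of-squares F-test of the Hill
  model against a flat model at α = 0.05 (a span-SE criterion is
  unreliable because span and EC50 are strongly correlated when the top
  dose sits below the plateau).

The simulator's default design — doses 0, 0.3, 1, 3, 10, 30 mM in
triplicate, 10% log-normal replicate CV, EC50 2 mM — is a realistic
short-chain-fatty-acid reporter plate that brackets the EC50 and reaches
≥ 94% of plateau at the top dose. At these conditions the Fisher
information bounds the EC50 standard error at ≈ 21% for a single
triplicate-plate study with a free slope, so potency is treated the way
a lab would: as a study of three replicate plates fitted jointly, with
recovery judged on the estimator's typical (median) error across
replicate studies rather than a single noise draw.

## Expression quantification

FPKM = count / (length_kb · depth_millions), with depth defaulting to
column sums (an external depth below a column sum is accepted and
logged, since external totals may count fragments differently). OR
ranking sorts by descending **median** FPKM across samples — the max is
retained in the output but the median is robust to single-sample pileups
in low-abundance genes — with cross-sample support (samples with
strictly more than one read) and then gene id breaking ties. The count
simulator plants OR genes at exact expected counts implied by target
FPKMs over a negative-binomial background transcriptome, so planted
enrichment order is recoverable. Gene length is the supplied annotation
length; there is no isoform-aware effective-length model (alignment is
upstream of this package's scope).

qPCR: scaled abundance 2^−(Ct_target − Ct_ref) × 10⁴ and relative fold
change 2^−ΔΔCt; Ct values outside (0, 45) are rejected as
machine-implausible.

## CRISPR indel classification

Amplicons align globally to the reference with affine gaps (match +1,
mismatch −1, open −5, extend −1 — gap opening expensive relative to
extension so a single contiguous indel is preferred over scattered
gaps). Classification is by the **net** length change (inserted − deleted
bases) because genotyping reports one type per colony; compound edits
take the sign of the net change and are logged, and a balanced compound
(net 0) classifies as unedited with a flag. Frameshift ⇔ |net| mod 3 ≠ 0.
Among co-optimal alignments the one with lexicographically smallest
gap-start coordinates is chosen (leftmost-gap convention, as in variant
normalization), enumerating at most 64 co-optimal alignments — exhaustive
at amplicon scale; more than one co-optimal placement marks the call
ambiguous. Percentages are rounded to the nearest integer (31/33 → 94%,
2/33 → 6%). On simulated cohorts with indel sizes ≤ 20 bp, ≥ 99% of
colonies are recovered with exact type and net size.

The edit simulator places a single deletion or insertion starting within
±3 bp of the cut site, sizes uniform on a configurable range (default
1–12 bp); an exact-counts mode fixes the per-type colony counts at
round(p·n) so a stated cohort mix is reproduced deterministically.

## Proliferation

The per-sample EdU fraction is the pooled ratio Σ EdU⁺ / Σ DAPI⁺ across
the sample's four fields — the unbiased estimator when field densities
vary — with mean-of-field-ratios available as an option and per-field
ratios always reported. Growth curves (days 1, 4, 6) are summarized as
mean ± SE per condition/day; treatments are tested against the control
at day 6 (end of culture) by one-way ANOVA with Bonferroni-adjusted
pairwise t-tests. A simulated 40% day-6 suppression at n = 4 and 10% CV
is flagged in ≥ 90% of replicate simulations.

## Shared statistics

Stiffness and MSD metrics are approximately log-normal across cells, so
group comparisons run on log₁₀ values (the base is a convention; F and p
are base-invariant, base 10 fixes the reported means). ANOVA is the
explicit sums-of-squares decomposition (cross-checked against scipy in
tests). SNK uses studentized-range critical values at the ANOVA error
df, harmonic-mean group size for unequal n, and the step-down rule that
never tests a pair inside a non-significant span — which is what makes
its family-wise error equal α under a complete null (verified at ~0.05
by simulation). Bonferroni is min(1, p·m). Geometric mean ± 95% CI is a
t-interval on log₁₀ values, back-transformed; simulated coverage is
SE-consistent with 95%.

## What the synthetic data do and do not show

The generators reproduce the statistical structure the estimators assume
(power-law fBm with static localization noise, linear viscoelastic
response, Hill response with multiplicative noise, single clean indels
per colony, NB count backgrounds). They do not emulate bead-cytoskeleton
binding heterogeneity, bead internalization, cell-to-cell variability
within a well, optical aberrations or non-uniform backgrounds, plate
spatial effects, chromatogram artifacts, or mixed-clone colonies.
Passing the recovery suite therefore demonstrates correctness of the
estimators under their stated models, not robustness to every failure
mode of the corresponding wet-lab assays.

## Problem sizes

Default validation sizes were chosen as the smallest that make the
stochastic checks statistically meaningful: 200 beads per grid condition
(12 conditions), 200 frames for localization accuracy, 500 beads for the
Brownian closed form, 1000/2000 replicates for SNK and CI calibration,
100 colonies for indel recovery. The full suite runs in well under a
minute apart from the recovery grid (~20 s).
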