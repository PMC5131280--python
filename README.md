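# asmkit

Quantitative analyses for chemo-mechanical odorant-receptor signalling in
airway smooth muscle (ASM), built for bench scientists who measure
cytoskeletal mechanics with functionalized microbeads and back it up with
reporter assays, expression profiling, CRISPR genotyping, and
proliferation read-outs.

Short-chain fatty acids (acetate, propionate) activate the odorant
receptor OR51E2 (mouse ortholog Olfr78) on ASM cells and slow both
cytoskeletal remodeling and proliferation. Establishing that claim takes a
chain of quantitative steps, each of which this package implements as
tested, seeded, reproducible code:

- **Passive microrheology (SNTM).** Cytoskeleton-anchored beads are imaged
  at 12 frames/s for ~300 s; trajectories give the mean square displacement
  MSD(τ) (nm²), fitted over 10–300 s lags by unweighted log-log least
  squares to MSD(τ) = D\*·(τ/1 s)^α. α > 1 (super-diffusion) marks
  ATP-driven remodeling; D* is the motion's incremental step at the 1 s
  reference lag.
- **Bead tracking.** Sub-pixel localization by intensity-weighted center of
  mass after median-background subtraction, with greedy nearest-neighbour
  linking; high-SNR accuracy is at the few-nm level.
- **Active microrheology (MTC).** A sinusoidal specific torque T(t) twists
  the bead; cell stiffness g = torque amplitude / lateral displacement
  amplitude (Pa/nm) is demodulated at the drive frequency.
- **Reporter dose–response.** Firefly/renilla plates normalized to each
  series' own 0 mM wells, fitted with a variable-slope Hill model
  R(d) = baseline + span·dⁿ/(dⁿ + EC50ⁿ); per-dose significance via
  ANOVA + Student–Newman–Keuls.
- **OR expression.** FPKM from count matrices, OR ranking by descending
  median FPKM with cross-sample support (> 1 read), and qPCR abundance as
  2^−ΔCt × 10000 / fold change as 2^−ΔΔCt.
- **CRISPR genotyping.** Global affine alignment of colony amplicons to the
  reference, net-indel classification (deletion/insertion, frameshift when
  |net| mod 3 ≠ 0), cohort percentages.
- **Proliferation.** Pooled EdU⁺/DAPI⁺ fractions and day-1/4/6 growth
  curves with ANOVA + Bonferroni treatment-vs-control tests.
- **Shared statistics.** Log-scale ANOVA, Bonferroni, SNK step-down on the
  studentized range, geometric mean ± 95% CI.

Every analysis is paired with a synthetic-data generator whose ground
truth is known exactly (fractional Brownian motion with Hurst H = α/2 for
bead motion, Poisson-noise Gaussian spots for images, log-normal replicate
noise for plates, seeded Cas9 indel cohorts), so the full pipeline is
validated end to end by parameter recovery.

## Worked example

Simulate one well of remodeling trajectories (ground truth D* = 20 nm²,
α = 1.6, 5 nm localization noise, 100 beads at 12 Hz for 300 s), compute
the ensemble MSD, and fit the power law:

```python
from asmkit import synthetic as sd, microrheology as mr

params = sd.RemodelingSimParams(d_star=20.0, alpha=1.6, loc_noise_sd=5.0,
                                n_beads=100, seed=7)
trajs = sd.simulate_remodeling_trajectories(params)
ens = mr.ensemble_msd([mr.compute_msd(t) for t in trajs])
print(mr.fit_power_law(ens, window=(10, 300)).summary())
```

```
MSD power-law fit: MSD(tau) = D* (tau/1 s)^alpha
  window      : 10-300 s (24 points)
  D*          : 23.18 nm^2  (SE log10 D* = 0.00729)
  alpha       : 1.5626  (SE = 0.00405)
  R^2         : 0.99985
```

The fitted exponent (1.56) and prefactor (23 nm²) recover the simulated
truth within sampling error; α > 1 is the super-diffusive signature of
active cytoskeletal remodeling. The same objects drive the stiffness and
potency estimators:

```python
rec = sd.simulate_mtc_record(sd.MtcSimParams(stiffness=1.5, noise_sd=2.0,
                                             drift_rate=1.0, seed=5))
print(mr.estimate_stiffness(rec).summary())
```

```
Magnetic twisting cytometry fit
  torque amplitude       : 60 Pa
  displacement amplitude : 39.94 nm
  stiffness              : 1.502 Pa/nm
  phase lag              : 0.2991 rad
```

A potency study pools three triplicate plates (EC50 truth 2 mM, 10%
replicate CV):

```python
import pandas as pd
from asmkit import reporter as rp

plates = []
for k in range(3):
    plate = sd.simulate_dose_response(sd.HillSimParams(ec50=2.0, cv=0.1, seed=k))
    norm = rp.normalize_plate(plate)
    norm["rep"] += 10 * k
    plates.append(norm)
print(rp.fit_hill(pd.concat(plates, ignore_index=True))[0].summary())
```

```
Hill fit: OR51E2 / acetate
  EC50     : 2.541 mM  (95% CI 1.59-4.06)
  Hill n   : 0.84
  baseline : 0.9871
  span     : 2.239
  converged: True
```

A CLI mirrors the library (`asmkit simulate ... | track | sntm | mtc |
reporter | expression | crispr | proliferate | stats | run`); every
generator requires `--seed`, and `asmkit run --seed 5` executes the whole
synthetic pipeline into a workspace of provenance-stamped TSV tables.

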