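"""Pipeline orchestration over the synthetic generators and analyses.

Stages run in dependency order inside a workspace directory; every
output table carries a provenance header (tool version, config hash,
seed).  Re-running a stage with identical config and inputs reproduces
its outputs byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import crispr, expression, io, microrheology, proliferation, reporter, synthetic
from .io import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["STAGES", "run_pipeline"]


# ---------------------------------------------------------------------------
# stage implementations (workspace-relative paths)

def _stage_simulate(ws: Path, cfg: PipelineConfig) -> None:
    params = synthetic.RemodelingSimParams(
        frame_rate=cfg.frame_rate, duration=cfg.duration, seed=cfg.seed)
    trajs = synthetic.simulate_remodeling_trajectories(params)
    io.write_trajectories_csv(trajs, ws / "trajectories.csv", cfg, cfg.seed)

    rec = synthetic.simulate_mtc_record(synthetic.MtcSimParams(
        frequency=cfg.mtc_frequency, seed=cfg.seed))
    io.write_mtc_csv(rec, ws / "mtc.csv", cfg, cfg.seed)

    plate = synthetic.simulate_dose_response(synthetic.HillSimParams(seed=cfg.seed))
    io.write_table(plate, ws / "plate.csv", cfg, cfg.seed, sep=",")

    counts, lengths = synthetic.simulate_or_counts(
        n_genes=2000, depth=1e7,
        or_fpkm={"OR51E2": 5.0, "OR2W3": 1.0, "OR5P3": 0.3},
        seed=cfg.seed)
    table = counts.copy()
    table.insert(0, "length_bp", lengths)
    table.insert(0, "gene", table.index)
    io.write_table(table, ws / "counts.tsv", cfg, cfg.seed)

    rng = np.random.default_rng(cfg.seed)
    ref = "".join(rng.choice(list("ACGT"), size=240))
    records, truth = synthetic.simulate_edited_amplicons(
        synthetic.EditSimParams(reference=ref, cut_site=120, seed=cfg.seed),
        exact_counts=True)
    io.write_fasta([("reference", ref)], ws / "reference.fa")
    io.write_fasta(records, ws / "amplicons.fa")
    io.write_table(truth, ws / "amplicon_truth.tsv", cfg, cfg.seed)

    edu = pd.DataFrame({
        "sample": np.repeat([f"donor{i}" for i in range(1, 4)], 4),
        "field": list(range(1, 5)) * 3,
        "n_edu_positive": rng.integers(5, 40, size=12),
        "n_dapi": rng.integers(80, 160, size=12),
    })
    io.write_table(edu, ws / "edu.csv", cfg, cfg.seed, sep=",")

    rows = []
    for cond, factor in (("untreated", 1.0), ("acetate", 0.7), ("propionate", 0.6)):
        for day in (1, 4, 6):
            mean = 1e4 * (2.0 ** ((day - 1) / 2.0)) * (factor if day > 1 else 1.0)
            for rep in range(4):
                rows.append({"condition": cond, "day": day,
                             "count": float(rng.normal(mean, 0.1 * mean)),
                             "replicate": rep})
    io.write_table(pd.DataFrame(rows), ws / "growth.csv", cfg, cfg.seed, sep=",")


def _stage_sntm(ws: Path, cfg: PipelineConfig) -> None:
    trajs = io.read_trajectories_csv(ws / "trajectories.csv",
                                     frame_rate=cfg.frame_rate)
    curves = [microrheology.compute_msd(t) for t in trajs]
    ens = microrheology.ensemble_msd(curves)
    io.write_table(pd.DataFrame({"lag_s": ens.lags, "msd_nm2": ens.msd,
                                 "n_beads": ens.n_pairs}),
                   ws / "msd_ensemble.tsv", cfg, cfg.seed)
    fit = microrheology.fit_power_law(ens, window=cfg.msd_window)
    io.write_table(pd.DataFrame([{
        "level": "well", "d_star_nm2": fit.d_star, "alpha": fit.alpha,
        "r2": fit.r2, "n_points": fit.n_points,
        "window_lo_s": fit.window[0], "window_hi_s": fit.window[1],
    }]), ws / "sntm_fit.tsv", cfg, cfg.seed)

    rows = []
    for t, c in zip(trajs, curves):
        try:
            f = microrheology.fit_power_law(c, window=cfg.msd_window)
        except ValueError:
            continue
        rows.append({"bead_id": t.bead_id, "d_star_nm2": f.d_star,
                     "alpha": f.alpha, "r2": f.r2})
    io.write_table(pd.DataFrame(rows), ws / "sntm_fit_per_bead.tsv", cfg, cfg.seed)


def _stage_mtc(ws: Path, cfg: PipelineConfig) -> None:
    rec = io.read_mtc_csv(ws / "mtc.csv")
    res = microrheology.estimate_stiffness(rec)
    io.write_table(pd.DataFrame([{
        "stiffness_pa_per_nm": res.stiffness, "phase_lag_rad": res.phase_lag,
        "displacement_amplitude_nm": res.displacement_amplitude,
        "torque_amplitude_pa": res.torque_amplitude,
        "low_confidence": res.low_confidence,
    }]), ws / "stiffness.tsv", cfg, cfg.seed)


def _stage_reporter(ws: Path, cfg: PipelineConfig) -> None:
    plate = io.read_table(ws / "plate.csv", sep=",")
    norm = reporter.normalize_plate(plate)
    io.write_table(reporter.summarize_doses(norm), ws / "reporter_doses.tsv",
                   cfg, cfg.seed)
    fits = reporter.fit_hill(norm)
    io.write_table(pd.DataFrame([{
        "construct": f.construct, "ligand": f.ligand,
        "ec50_mM": f.ec50, "hill_n": f.hill_n, "baseline": f.baseline,
        "span": f.span, "responded": f.responded, "converged": f.converged,
    } for f in fits]), ws / "hill_fits.tsv", cfg, cfg.seed)
    io.write_table(reporter.dose_anova(norm), ws / "reporter_anova.tsv",
                   cfg, cfg.seed)


def _stage_expression(ws: Path, cfg: PipelineConfig) -> None:
    table = io.read_table(ws / "counts.tsv").set_index("gene")
    lengths = table.pop("length_bp")
    fpkm = expression.compute_fpkm(table, lengths)
    ors = [g for g in ("OR51E2", "OR2W3", "OR5P3") if g in fpkm.index]
    ranking = expression.rank_or_genes(fpkm, ors, table)
    io.write_table(ranking, ws / "or_ranking.tsv", cfg, cfg.seed)


def _stage_crispr(ws: Path, cfg: PipelineConfig) -> None:
    (_, ref), = io.read_fasta(ws / "reference.fa")
    amplicons = io.read_fasta(ws / "amplicons.fa")
    calls = crispr.call_indels(ref, amplicons, cut_site=120)
    io.write_table(crispr.calls_to_frame(calls), ws / "indel_calls.tsv",
                   cfg, cfg.seed)
    s = crispr.summarize_edits(calls)
    io.write_table(pd.DataFrame([{
        "n_total": s.n_total, "n_deletion": s.n_deletion,
        "n_insertion": s.n_insertion, "n_none": s.n_none,
        "pct_deletion": s.pct_deletion, "pct_insertion": s.pct_insertion,
        "n_frameshift": s.n_frameshift,
    }]), ws / "indel_summary.tsv", cfg, cfg.seed)


def _stage_proliferate(ws: Path, cfg: PipelineConfig) -> None:
    edu = io.read_table(ws / "edu.csv", sep=",")
    frac = proliferation.edu_fraction(edu)
    io.write_table(frac.drop(columns="field_fractions"),
                   ws / "edu_fractions.tsv", cfg, cfg.seed)
    growth = io.read_table(ws / "growth.csv", sep=",")
    summary, tests = proliferation.compare_growth(growth, control="untreated")
    io.write_table(summary, ws / "growth_summary.tsv", cfg, cfg.seed)
    io.write_table(tests, ws / "growth_tests.tsv", cfg, cfg.seed)


STAGES: dict[str, dict] = {
    "simulate": {"run": _stage_simulate, "inputs": [], "outputs": [
        "trajectories.csv", "mtc.csv", "plate.csv", "counts.tsv",
        "reference.fa", "amplicons.fa", "amplicon_truth.tsv",
        "edu.csv", "growth.csv"]},
    "sntm": {"run": _stage_sntm, "inputs": ["trajectories.csv"],
             "outputs": ["msd_ensemble.tsv", "sntm_fit.tsv",
                         "sntm_fit_per_bead.tsv"]},
    "mtc": {"run": _stage_mtc, "inputs": ["mtc.csv"], "outputs": ["stiffness.tsv"]},
    "reporter": {"run": _stage_reporter, "inputs": ["plate.csv"],
                 "outputs": ["reporter_doses.tsv", "hill_fits.tsv",
                             "reporter_anova.tsv"]},
    "expression": {"run": _stage_expression, "inputs": ["counts.tsv"],
                   "outputs": ["or_ranking.tsv"]},
    "crispr": {"run": _stage_crispr, "inputs": ["reference.fa", "amplicons.fa"],
               "outputs": ["indel_calls.tsv", "indel_summary.tsv"]},
    "proliferate": {"run": _stage_proliferate, "inputs": ["edu.csv", "growth.csv"],
                    "outputs": ["growth_summary.tsv", "growth_tests.tsv",
                                "edu_fractions.tsv"]},
}


def run_pipeline(config: PipelineConfig, stages: list[str]) -> Path:
    """Execute the requested stages in dependency order.

    Pre-flight: every stage's inputs must either exist in the workspace
    already or be produced by an earlier stage in the list; otherwise a
    named error is raised before anything runs.  Unknown stage names list
    the valid ones.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid stages: "
                         f"{sorted(STAGES)}")
    ws = Path(config.outdir)

    produced: set[str] = set()
    for s in stages:
        for inp in STAGES[s]["inputs"]:
            if inp not in produced and not (ws / inp).exists():
                raise FileNotFoundError(
                    f"stage {s!r} requires {inp!r}, which neither exists in "
                    f"{ws} nor is produced by an earlier stage")
        produced.update(STAGES[s]["outputs"])

    ws.mkdir(parents=True, exist_ok=True)
    for s in stages:
        logger.info("running stage %s (seed=%d, config=%s)", s, config.seed,
                    config.hash())
        STAGES[s]["run"](ws, config)
    return ws
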