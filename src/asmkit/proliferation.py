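"""Proliferation read-outs: EdU-positive fractions and growth curves.

EdU incorporation marks nuclei that synthesized DNA during the labelling
window; the proliferating fraction of a sample is EdU-positive nuclei
over DAPI-positive (total) nuclei, pooled across that sample's imaging
fields.  Live-cell growth curves (counts on days 1, 4 and 6) are
summarized as mean +/- SE per condition per day, with treatment-versus-
control tests (ANOVA + Bonferroni) on the final day.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import stats as stats_core

logger = logging.getLogger(__name__)

__all__ = ["edu_fraction", "compare_growth"]


def _check_fields(fields: pd.DataFrame) -> None:
    required = {"sample", "field", "n_edu_positive", "n_dapi"}
    missing = required - set(fields.columns)
    if missing:
        raise ValueError(f"field-count table missing columns: {sorted(missing)}")
    if (fields["n_edu_positive"] < 0).any() or (fields["n_dapi"] < 0).any():
        raise ValueError("nuclei counts must be non-negative")
    if (fields["n_edu_positive"] > fields["n_dapi"]).any():
        raise ValueError("EdU-positive count cannot exceed total nuclei")


def edu_fraction(fields: pd.DataFrame, method: str = "pooled") -> pd.DataFrame:
    """Proliferating-cell fraction per sample.

    ``pooled`` (default) divides summed EdU-positive nuclei by summed
    total nuclei across the sample's fields — the unbiased estimator when
    field densities vary; ``mean`` averages per-field ratios instead.
    Per-field ratios are reported alongside either way.
    """
    _check_fields(fields)
    if method not in ("pooled", "mean"):
        raise ValueError("method must be 'pooled' or 'mean'")
    rows = []
    for sample, sub in fields.groupby("sample", sort=False):
        total = sub["n_dapi"].sum()
        if total == 0:
            raise ValueError(f"sample {sample!r} has zero DAPI-positive nuclei")
        ratios = (sub["n_edu_positive"] / sub["n_dapi"].replace(0, np.nan)).dropna()
        pooled = sub["n_edu_positive"].sum() / total
        rows.append({
            "sample": sample,
            "fraction": pooled if method == "pooled" else float(ratios.mean()),
            "pooled_fraction": float(pooled),
            "mean_field_fraction": float(ratios.mean()),
            "n_fields": len(sub),
            "n_dapi_total": int(total),
            "field_fractions": list(np.round(ratios.to_numpy(), 6)),
        })
    return pd.DataFrame(rows)


def compare_growth(series: pd.DataFrame, control: str,
                   test_days: tuple[int, ...] = (6,),
                   alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize growth curves and test treatments against the control.

    ``series`` is long-format with columns condition, day, count,
    replicate.  Returns ``(summary, tests)``: mean +/- SE per condition
    per day, and per-condition ANOVA + Bonferroni decisions versus the
    control on ``test_days`` (day 6 by default, the end of the culture
    period).  Conditions missing a day are excluded from that day with a
    warning.
    """
    required = {"condition", "day", "count"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    if (series["count"] < 0).any():
        raise ValueError("cell counts must be non-negative")
    if control not in set(series["condition"]):
        raise ValueError(f"control condition {control!r} not in table")

    grouped = series.groupby(["condition", "day"])["count"]
    summary = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    summary["se"] = summary["sd"] / np.sqrt(summary["n"])
    summary = summary.drop(columns="sd")

    all_days = set(series["day"].unique())
    for cond, sub in series.groupby("condition"):
        lacking = all_days - set(sub["day"].unique())
        if lacking:
            logger.warning("condition %r missing day(s) %s; excluded there",
                           cond, sorted(lacking))

    rows = []
    for day in test_days:
        day_data = series[series["day"] == day]
        groups = {str(c): g["count"].to_numpy(dtype=float)
                  for c, g in day_data.groupby("condition")}
        if str(control) not in groups or len(groups) < 2:
            continue
        aov = stats_core.anova_oneway(groups)
        treatments = [c for c in groups if c != str(control)]
        raw_p = []
        for cond in treatments:
            from scipy import stats as sps
            t, p = sps.ttest_ind(groups[cond], groups[str(control)])
            raw_p.append(float(p))
        adj = stats_core.bonferroni(raw_p, m=len(treatments))
        for cond, p, ap in zip(treatments, raw_p, adj):
            rows.append({
                "day": day, "condition": cond, "control": control,
                "anova_f": aov.f_stat, "anova_p": aov.p_value,
                "raw_p": p, "adjusted_p": float(ap),
                "significant": bool(ap < alpha and aov.p_value < alpha),
                "method": "anova+bonferroni", "alpha": alpha,
            })
    return summary, pd.DataFrame(rows)
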