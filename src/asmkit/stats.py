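"""Shared statistical procedures.

Stiffness and MSD metrics are approximately log-normal across cells, so
group comparisons are run on log10-transformed values: one-way
fixed-effects ANOVA with Bonferroni adjustment, the Student-Newman-Keuls
(SNK) step-down multiple-range procedure, and geometric means with 95%
confidence intervals (t-interval on logs, back-transformed).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps


@lru_cache(maxsize=4096)
def _q_crit(alpha: float, r: int, df: int) -> float:
    """Studentized-range critical value (cached; the ppf is expensive)."""
    return float(sps.studentized_range.ppf(1 - alpha, r, df))

__all__ = ["AnovaResult", "log_anova", "anova_oneway", "bonferroni", "snk",
           "geometric_mean_ci", "groups_from_table"]


@dataclass
class AnovaResult:
    """One-way fixed-effects ANOVA summary (optionally on log10 values)."""

    f_stat: float
    p_value: float
    group_means: dict[str, float]   # on the analysis scale
    df_between: int
    df_error: int
    mse: float                      # error mean square, analysis scale
    group_sizes: dict[str, int]
    log_scale: bool

    def summary(self) -> str:
        scale = "log10" if self.log_scale else "raw"
        lines = [f"One-way ANOVA ({scale} scale)",
                 f"  F({self.df_between}, {self.df_error}) = {self.f_stat:.4f}, "
                 f"p = {self.p_value:.4g}"]
        for g, m in self.group_means.items():
            lines.append(f"  {g}: mean = {m:.4g} (n = {self.group_sizes[g]})")
        return "\n".join(lines)


def groups_from_table(table: pd.DataFrame, group_col: str = "group",
                      value_col: str = "value") -> dict[str, np.ndarray]:
    """Split a long-format (group, value) table into an ordered dict of arrays."""
    return {str(g): np.asarray(sub[value_col], dtype=float)
            for g, sub in table.groupby(group_col, sort=False)}


def _validate_groups(groups: dict[str, np.ndarray], log_scale: bool) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    out = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
        if log_scale and np.any(v <= 0):
            raise ValueError(f"group {name!r} contains non-positive values; "
                             "log-scale metrics must be positive")
        out[name] = np.log10(v) if log_scale else v
    return out


def anova_oneway(groups: dict[str, np.ndarray], log_scale: bool = False) -> AnovaResult:
    """One-way fixed-effects ANOVA by explicit sums-of-squares decomposition."""
    g = _validate_groups(groups, log_scale)
    all_vals = np.concatenate(list(g.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in g.values())
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in g.values())
    df_b = len(g) - 1
    df_e = len(all_vals) - len(g)
    ms_b = ss_between / df_b
    ms_e = ss_within / df_e
    if ms_e == 0.0:
        f = 0.0 if ss_between == 0.0 else np.inf
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        f = ms_b / ms_e
        p = float(sps.f.sf(f, df_b, df_e))
    return AnovaResult(
        f_stat=float(f), p_value=p,
        group_means={k: float(v.mean()) for k, v in g.items()},
        df_between=df_b, df_error=df_e, mse=float(ms_e),
        group_sizes={k: len(v) for k, v in g.items()},
        log_scale=log_scale,
    )


def log_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """One-way ANOVA on log10 values (stiffness/MSD convention)."""
    return anova_oneway(groups, log_scale=True)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * m)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be >= the number of p-values")
    return np.minimum(1.0, p * m)


def snk(groups: dict[str, np.ndarray], alpha: float = 0.05,
        log_scale: bool = False) -> pd.DataFrame:
    """Student-Newman-Keuls multiple-range procedure.

    Group means are ranked; the studentized range statistic is compared
    with its critical value for each span r, stepping down from the full
    range (r = k) to adjacent pairs (r = 2).  A pair inside a span already
    declared non-significant is not tested (coherence), so under a
    complete null the family-wise error rate equals alpha.

    Returns one row per ordered pair with the observed q, the critical
    value for its span, and the decision.
    """
    g = _validate_groups(groups, log_scale)
    names = sorted(g, key=lambda k: g[k].mean())
    means = np.array([g[n].mean() for n in names])
    k = len(names)
    aov = anova_oneway({n: (10.0 ** g[n] if log_scale else g[n]) for n in names},
                       log_scale=log_scale)
    df_e, mse = aov.df_error, aov.mse
    sizes = np.array([len(g[n]) for n in names], dtype=float)
    n_h = len(sizes) / np.sum(1.0 / sizes)  # harmonic mean for unequal n
    se = np.sqrt(mse / n_h)

    significant = {}

    def test_span(i: int, j: int) -> None:
        """Test the span of sorted means [i, j]; recurse only if significant."""
        r = j - i + 1
        if r < 2:
            return
        if se == 0.0:
            sig = means[j] > means[i]
            q_obs = np.inf if sig else 0.0
            q_crit = np.nan
        else:
            q_obs = (means[j] - means[i]) / se
            q_crit = _q_crit(alpha, r, df_e)
            sig = q_obs > q_crit
        significant[(i, j)] = (q_obs, q_crit, sig, True)
        if sig:
            test_span(i, j - 1)
            test_span(i + 1, j)

    test_span(0, k - 1)

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            if (i, j) in significant:
                q_obs, q_crit, sig, tested = significant[(i, j)]
            else:
                # inside a non-significant span: not tested, declared NS
                q_obs = (means[j] - means[i]) / se if se > 0 else 0.0
                q_crit, sig, tested = np.nan, False, False
            rows.append({
                "group_lo": names[i], "group_hi": names[j],
                "diff": float(means[j] - means[i]),
                "span": j - i + 1,
                "q": float(q_obs), "q_crit": q_crit,
                "significant": bool(sig), "tested": tested,
                "method": "snk", "alpha": alpha,
            })
    return pd.DataFrame(rows)


def geometric_mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Geometric mean with a back-transformed t-interval on log10 values."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need n >= 2")
    if np.any(v <= 0):
        raise ValueError("values must be positive")
    logs = np.log10(v)
    m = logs.mean()
    se = logs.std(ddof=1) / np.sqrt(len(v))
    tq = sps.t.ppf(0.5 + level / 2.0, len(v) - 1)
    return 10.0 ** m, 10.0 ** (m - tq * se), 10.0 ** (m + tq * se)
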