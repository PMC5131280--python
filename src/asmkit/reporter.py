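"""Luciferase reporter-assay normalization and Hill dose-response fitting.

Firefly luminescence (cAMP-response-element driven) is first expressed
relative to the constitutively active renilla co-transfection control,
then each construct/ligand series is normalized to the mean ratio of its
own 0 mM wells, so an inactive construct sits at 1 and fold-activation is
read directly.  Agonist potency is estimated with a variable-slope Hill
model; per-dose significance versus the 0 mM control uses one-way ANOVA
followed by the Student-Newman-Keuls procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import f as sps_f

from . import stats as stats_core
from .synthetic import hill_curve

__all__ = ["normalize_plate", "summarize_doses", "HillModel", "HillResults",
           "fit_hill", "dose_anova"]

REQUIRED_COLUMNS = ("construct", "ligand", "dose_mM", "firefly", "renilla")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    if (table["renilla"] <= 0).any():
        raise ValueError("renilla luminescence must be positive")
    if (table["dose_mM"] < 0).any():
        raise ValueError("doses must be non-negative")


def normalize_plate(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize a firefly/renilla plate to each series' own 0 mM control.

    Adds ``ratio`` (firefly/renilla) and ``response`` (ratio divided by
    the mean 0 mM ratio of the same construct/ligand series).  Raises if
    any series lacks a 0 mM condition, naming the offender.
    """
    _check_table(table)
    out = table.copy()
    out["ratio"] = out["firefly"] / out["renilla"]
    responses = np.empty(len(out))
    for (construct, ligand), sub in out.groupby(["construct", "ligand"], sort=False):
        zero = sub.loc[sub["dose_mM"] == 0.0, "ratio"]
        if zero.empty:
            raise ValueError(f"construct {construct!r} / ligand {ligand!r} "
                             "has no 0 mM control wells")
        responses[out.index.get_indexer(sub.index)] = sub["ratio"] / zero.mean()
    out["response"] = responses
    return out


def summarize_doses(normalized: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE of the normalized response per construct/ligand/dose."""
    grouped = normalized.groupby(["construct", "ligand", "dose_mM"])["response"]
    summary = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    summary["se"] = summary["sd"] / np.sqrt(summary["n"])
    return summary.drop(columns="sd")


@dataclass
class HillResults:
    """Fitted Hill curve for one construct/ligand series."""

    construct: str
    ligand: str
    ec50: float | None      # mM; None when no response
    hill_n: float | None
    baseline: float
    span: float
    converged: bool
    responded: bool
    ec50_ci: tuple[float, float] | None
    rss: float = float("nan")

    def predict(self, dose) -> np.ndarray:
        if not self.responded:
            return np.full_like(np.asarray(dose, dtype=float), self.baseline)
        return hill_curve(dose, self.baseline, self.span, self.ec50, self.hill_n)

    def summary(self) -> str:
        head = f"Hill fit: {self.construct} / {self.ligand}"
        if not self.responded:
            return head + "\n  no response (span indistinguishable from 0); EC50 undefined"
        lo, hi = self.ec50_ci if self.ec50_ci else (float("nan"),) * 2
        return "\n".join([
            head,
            f"  EC50     : {self.ec50:.4g} mM  (95% CI {lo:.4g}-{hi:.4g})",
            f"  Hill n   : {self.hill_n:.3g}",
            f"  baseline : {self.baseline:.4g}",
            f"  span     : {self.span:.4g}",
            f"  converged: {self.converged}",
        ])


class HillModel:
    """Variable-slope Hill model for one normalized dose-response series.

    The 0 mM wells anchor the baseline parameter (log(0) is undefined, so
    zero dose cannot enter a log-dose design; the Hill form used here is
    defined to equal ``baseline`` at dose 0, so those wells are fitted
    directly).  The Hill slope is bounded to (0.3, 4) for identifiability
    with few doses; EC50 is multistarted over the observed dose range.
    """

    HILL_N_BOUNDS = (0.3, 4.0)

    def __init__(self, dose: np.ndarray, response: np.ndarray,
                 construct: str = "", ligand: str = ""):
        self.dose = np.asarray(dose, dtype=float)
        self.response = np.asarray(response, dtype=float)
        self.construct = construct
        self.ligand = ligand
        if len(np.unique(self.dose)) < 4 or 0.0 not in self.dose:
            raise ValueError("need >= 4 distinct doses including 0 mM")

    def fit(self) -> HillResults:
        dose, resp = self.dose, self.response
        pos = np.unique(dose[dose > 0])
        baseline0 = float(resp[dose == 0].mean())
        top = float(np.mean(resp[dose == dose.max()]))
        span0 = max(top - baseline0, 1e-6)
        geo_mid = float(np.sqrt(pos.min() * pos.max()))
        # identifiability bounds: an EC50 more than a decade outside the
        # measured doses, or a span far beyond the observed dynamic range,
        # cannot be estimated from the plate and only traps the optimizer
        obs_range = float(resp.max() - resp.min())
        lb = [-np.inf, 0.0, pos.min() / 10.0, self.HILL_N_BOUNDS[0]]
        ub = [np.inf, max(3.0 * obs_range, 1e-6), pos.max() * 10.0,
              self.HILL_N_BOUNDS[1]]

        best = None
        converged = False
        for ec50_0 in (float(pos.min()), geo_mid, float(pos.max())):
            try:
                popt, pcov = curve_fit(
                    hill_curve, dose, resp,
                    p0=[baseline0, span0, ec50_0, 1.0],
                    bounds=(lb, ub), maxfev=20000)
            except RuntimeError:
                continue
            rss = float(np.sum((resp - hill_curve(dose, *popt)) ** 2))
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
                converged = True

        if not converged:
            warnings.warn(f"Hill fit did not converge for "
                          f"{self.construct}/{self.ligand}")
            return HillResults(self.construct, self.ligand, None, None,
                               baseline0, 0.0, converged=False,
                               responded=False, ec50_ci=None)

        popt, pcov, rss = best
        baseline, span, ec50, hill_n = (float(v) for v in popt)

        # no-response check: extra-sum-of-squares F-test of the Hill model
        # (4 params) against a flat model (1 param).  A span SE alone is a
        # poor test because span and EC50 are strongly correlated when the
        # top dose sits below the plateau.
        rss_flat = float(np.sum((resp - resp.mean()) ** 2))
        dof = len(resp) - 4
        if rss_flat <= 0.0:
            responded = False  # perfectly flat data
        elif dof <= 0 or rss == 0.0:
            responded = rss < rss_flat  # noiseless: any improvement is real
        else:
            f_stat = ((rss_flat - rss) / 3.0) / (rss / dof)
            responded = float(sps_f.sf(f_stat, 3, dof)) < 0.05
        if not responded or span <= 0.0:
            return HillResults(self.construct, self.ligand, None, None,
                               baseline, span, converged=True,
                               responded=False, ec50_ci=None, rss=rss)

        se_ec50 = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
        if np.isfinite(se_ec50) and ec50 > 0:
            # normal interval on log EC50 (multiplicative errors)
            rel = se_ec50 / ec50
            ci = (ec50 * np.exp(-1.96 * rel), ec50 * np.exp(1.96 * rel))
        else:
            ci = None
        return HillResults(self.construct, self.ligand, ec50, hill_n,
                           baseline, span, converged=True, responded=True,
                           ec50_ci=ci, rss=rss)


def fit_hill(normalized: pd.DataFrame) -> list[HillResults]:
    """Fit a Hill curve per construct/ligand series of a normalized plate."""
    results = []
    for (construct, ligand), sub in normalized.groupby(["construct", "ligand"],
                                                       sort=False):
        model = HillModel(sub["dose_mM"].to_numpy(), sub["response"].to_numpy(),
                          construct=str(construct), ligand=str(ligand))
        results.append(model.fit())
    return results


def dose_anova(normalized: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-dose significance versus the 0 mM control (ANOVA + SNK).

    For each construct/ligand series, the doses form the groups of a
    one-way ANOVA; the SNK step-down procedure then decides which doses
    differ from the 0 mM control at the requested alpha.
    """
    rows = []
    for (construct, ligand), sub in normalized.groupby(["construct", "ligand"],
                                                       sort=False):
        groups = {f"{d:g}": sub.loc[sub["dose_mM"] == d, "response"].to_numpy()
                  for d in np.sort(sub["dose_mM"].unique())}
        aov = stats_core.anova_oneway(groups)
        pairs = stats_core.snk(groups, alpha=alpha)
        control = "0"
        for d in groups:
            if d == control:
                continue
            row = pairs[((pairs["group_lo"] == control) & (pairs["group_hi"] == d))
                        | ((pairs["group_lo"] == d) & (pairs["group_hi"] == control))]
            sig = bool(row["significant"].any())
            rows.append({
                "construct": construct, "ligand": ligand, "dose_mM": float(d),
                "anova_f": aov.f_stat, "anova_p": aov.p_value,
                "significant_vs_control": sig and aov.p_value < alpha,
                "method": "anova+snk", "alpha": alpha,
            })
    return pd.DataFrame(rows)
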