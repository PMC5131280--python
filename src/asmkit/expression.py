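"""Odorant-receptor expression quantification.

RNA-Seq side: FPKM (fragments per kilobase of transcript per million
mapped fragments) from a count matrix with annotated gene lengths, and
ranking of a supplied OR gene set by descending median FPKM with
cross-sample support (number of samples with more than one read) as the
tie-breaker.  qPCR side: scaled relative abundance 2^-(dCt) x 10000
against a reference gene (GAPDH), and relative fold change 2^-(ddCt)
against a calibrator sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["compute_fpkm", "rank_or_genes", "fpkm_quantile_summary",
           "delta_ct", "ddct_rfc"]


def compute_fpkm(counts: pd.DataFrame, lengths_bp: pd.Series,
                 depth: pd.Series | None = None) -> pd.DataFrame:
    """FPKM per gene per sample.

    fpkm[g, s] = count[g, s] / (length_kb[g] * depth_millions[s]).
    ``depth`` defaults to per-sample column sums; a supplied depth that is
    smaller than a column sum is accepted but logged (external totals may
    count multi-mapped fragments differently).
    """
    lengths_bp = lengths_bp.reindex(counts.index)
    if lengths_bp.isna().any():
        missing = list(lengths_bp.index[lengths_bp.isna()])[:5]
        raise ValueError(f"genes missing a length annotation, e.g. {missing}")
    if (lengths_bp <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if depth is None:
        depth = counts.sum(axis=0)
    else:
        depth = depth.reindex(counts.columns)
        low = depth < counts.sum(axis=0)
        if low.any():
            logger.warning("supplied depth below column sum for samples %s",
                           list(depth.index[low]))
    if (depth <= 0).any():
        raise ValueError("sample depth must be positive")
    length_kb = lengths_bp.to_numpy(dtype=float)[:, None] / 1000.0
    depth_m = depth.to_numpy(dtype=float)[None, :] / 1e6
    return pd.DataFrame(counts.to_numpy(dtype=float) / (length_kb * depth_m),
                        index=counts.index, columns=counts.columns)


def rank_or_genes(fpkm: pd.DataFrame, or_genes, counts: pd.DataFrame) -> pd.DataFrame:
    """Rank OR genes by descending median FPKM across samples.

    Cross-sample support is the number of samples with strictly more than
    one read for the gene.  Ties in median FPKM break by support
    (descending), then gene id (lexicographic).  OR ids absent from the
    matrix are logged and skipped, not fatal.  Pseudogenes are expected to
    be excluded from ``or_genes`` by the caller.
    """
    or_genes = list(or_genes)
    if not or_genes:
        raise ValueError("or_genes must be non-empty")
    present = [g for g in or_genes if g in fpkm.index]
    absent = sorted(set(or_genes) - set(present))
    if absent:
        logger.warning("OR genes absent from the matrix: %s", absent)
    if not present:
        raise ValueError("none of the OR genes are present in the matrix")
    sub = fpkm.loc[present]
    support = (counts.loc[present] > 1).sum(axis=1)
    table = pd.DataFrame({
        "gene": present,
        "median_fpkm": sub.median(axis=1).to_numpy(),
        "mean_fpkm": sub.mean(axis=1).to_numpy(),
        "max_fpkm": sub.max(axis=1).to_numpy(),
        "support": support.to_numpy(),
    })
    table = table.sort_values(["median_fpkm", "support", "gene"],
                              ascending=[False, False, True],
                              kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def fpkm_quantile_summary(fpkm: pd.DataFrame,
                          groups: pd.Series | dict) -> pd.DataFrame:
    """Min/q1/median/q3/max FPKM per gene per tissue group (quantile strips)."""
    groups = pd.Series(groups)
    rows = []
    for tissue, cols in groups.groupby(groups):
        block = fpkm[list(cols.index)]
        q = block.quantile([0.0, 0.25, 0.5, 0.75, 1.0], axis=1).T
        q.columns = ["min", "q1", "median", "q3", "max"]
        q.insert(0, "tissue", tissue)
        q.insert(0, "gene", q.index)
        q["n_samples"] = len(cols)
        rows.append(q.reset_index(drop=True))
    return pd.concat(rows, ignore_index=True)


def _check_ct(ct, name: str) -> np.ndarray:
    arr = np.asarray(ct, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError(f"missing {name} Ct value")
    if np.any((arr <= 0) | (arr >= 45)):
        raise ValueError(f"{name} Ct values must lie in (0, 45)")
    return arr


def delta_ct(ct_target, ct_reference, scale: float = 10000.0):
    """Scaled relative abundance: 2^-(Ct_target - Ct_reference) x scale."""
    t = _check_ct(ct_target, "target")
    r = _check_ct(ct_reference, "reference")
    out = np.power(2.0, -(t - r)) * scale
    return float(out) if out.ndim == 0 else out


def ddct_rfc(ct_target, ct_reference, ct_target_cal, ct_reference_cal):
    """Relative fold change 2^-(ddCt) versus a calibrator sample."""
    dct = _check_ct(ct_target, "target") - _check_ct(ct_reference, "reference")
    dct_cal = (_check_ct(ct_target_cal, "calibrator target")
               - _check_ct(ct_reference_cal, "calibrator reference"))
    out = np.power(2.0, -(dct - dct_cal))
    return float(out) if out.ndim == 0 else out
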