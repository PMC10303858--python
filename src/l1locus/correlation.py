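"""Expression correlation between L1 loci and their host genes, plus simple
per-sample metric correlations (e.g. intronic read load vs total full-length
L1 expression)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def l1_host_correlation(
    norm_l1: pd.DataFrame,
    norm_genes: pd.DataFrame,
    context_calls: pd.DataFrame,
    expressed_l1_ids=None,
    method: str = "pearson",
) -> tuple[pd.DataFrame, float]:
    """Correlation across samples of each genic L1 with its host gene.

    Pairs come from context calls (host_gene set); L1s can be restricted to an
    expressed set.  Pairs where either vector has zero variance are flagged
    and excluded from the summary.  Returns (pair table, fraction with r < 0).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    shared = [s for s in norm_l1.columns if s in norm_genes.columns]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    rows = []
    for row in context_calls.itertuples(index=False):
        if row.host_gene is None or pd.isna(row.host_gene):
            continue
        if expressed_l1_ids is not None and row.l1_id not in expressed_l1_ids:
            continue
        if row.l1_id not in norm_l1.index or row.host_gene not in norm_genes.index:
            continue
        x = norm_l1.loc[row.l1_id, shared].to_numpy(dtype=float)
        y = norm_genes.loc[row.host_gene, shared].to_numpy(dtype=float)
        degenerate = np.ptp(x) == 0 or np.ptp(y) == 0
        if degenerate:
            r = np.nan
        elif method == "pearson":
            r = float(stats.pearsonr(x, y).statistic)
        else:
            r = float(stats.spearmanr(x, y).statistic)
        rows.append(
            {
                "l1_id": row.l1_id,
                "gene_id": row.host_gene,
                "r": r,
                "n": len(shared),
                "method": method,
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(
        rows, columns=["l1_id", "gene_id", "r", "n", "method", "degenerate"]
    )
    valid = table.loc[~table["degenerate"], "r"]
    negative_fraction = float((valid < 0).mean()) if len(valid) else np.nan
    return table, negative_fraction


def metric_correlation(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p between two per-sample metrics."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-d vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
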