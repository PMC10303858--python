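"""Resampling-based gene-set enrichment.

The observed overlap of a target gene set with an annotation set is compared
with the overlaps of ``n`` size-matched random gene sets drawn uniformly
without replacement from the expressed-gene universe; the enrichment score is
z = (observed − null mean) / null sd.  An exact hypergeometric p-value is
reported alongside as a cross-check (the null overlap count of a uniform draw
is exactly hypergeometric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as ivl
from .formats_io import GeneModel, L1Locus


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    observed: int
    null_mean: float
    null_sd: float
    z: float | None  # None when the null is degenerate (sd = 0)
    n_resamples: int
    seed: int | None = None
    hypergeom_p: float | None = None

    @property
    def defined(self) -> bool:
        return self.z is not None


def _as_result(name, observed, null_counts, n, seed, p) -> EnrichmentResult:
    null_mean = float(np.mean(null_counts))
    null_sd = float(np.std(null_counts, ddof=0))
    z = (observed - null_mean) / null_sd if null_sd > 0 else None
    return EnrichmentResult(
        set_name=name,
        observed=int(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        n_resamples=n,
        seed=seed,
        hypergeom_p=p,
    )


def resampling_enrichment(
    target,
    annotation,
    universe,
    n: int = 1000,
    seed: int | None = None,
    set_name: str = "annotation",
) -> EnrichmentResult:
    """Enrichment of ``target`` in ``annotation`` against size-matched draws
    from ``universe``.  ``target`` must be a subset of ``universe``."""
    target = set(target)
    annotation = set(annotation)
    universe_list = sorted(set(universe))
    if not target <= set(universe_list):
        raise ValueError("target must be a subset of the universe")
    if len(target) > len(universe_list):
        raise ValueError("target larger than universe")
    rng = np.random.default_rng(seed)
    observed = len(target & annotation)

    in_annot = np.array([g in annotation for g in universe_list])
    k = len(target)
    draws = np.empty(n, dtype=np.int64)
    for i in range(n):
        idx = rng.choice(len(universe_list), size=k, replace=False)
        draws[i] = int(in_annot[idx].sum())

    n_annot_in_universe = int(in_annot.sum())
    p = float(
        stats.hypergeom.sf(observed - 1, len(universe_list), n_annot_in_universe, k)
    )
    return _as_result(set_name, observed, draws, n, seed, p)


def genomic_l1_enrichment(
    l1s: list[L1Locus],
    gene_sets: dict[str, set],
    genes: list[GeneModel],
    universe,
    n: int = 1000,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Are L1 loci enriched within the genes of each set?

    Observed = number of L1s overlapping (>= 1 bp) any gene of the set; the
    null swaps in ``n`` equally sized random gene sets from the universe.
    """
    universe_list = sorted(set(universe))
    gene_by_id = {g.gene_id: g for g in genes}
    missing = [g for g in universe_list if g not in gene_by_id]
    if missing:
        raise ValueError(f"no interval for universe genes: {missing[:5]}")
    l1_ivs = [x.interval for x in l1s]

    def overlap_count(gene_ids) -> int:
        bodies = [gene_by_id[g].body for g in gene_ids]
        return int(sum(ivl.overlaps_any(l1_ivs, bodies)))

    out = []
    rng = np.random.default_rng(seed)
    for name, gene_set in gene_sets.items():
        gene_set = set(gene_set)
        if len(gene_set) > len(universe_list):
            raise ValueError(f"set {name!r} larger than universe")
        observed = overlap_count([g for g in gene_set if g in gene_by_id])
        draws = np.empty(n, dtype=np.int64)
        for i in range(n):
            idx = rng.choice(len(universe_list), size=len(gene_set), replace=False)
            draws[i] = overlap_count([universe_list[j] for j in idx])
        out.append(_as_result(name, observed, draws, n, seed, None))
    return out


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "observed": r.observed,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "z": np.nan if r.z is None else r.z,
                "n_resamples": r.n_resamples,
                "seed": r.seed,
                "hypergeom_p": np.nan if r.hypergeom_p is None else r.hypergeom_p,
            }
            for r in results
        ]
    )
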