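"""Shared read-pair fragments between two genomic loci — the exonization
statistic.

For a locus pair (A, B): take the read ids with at least one mate mapping
fully within A (proper pairs, mapq >= 30); all mates belonging to those ids
are the 'total fragments' (two per id); ids with at least one mate overlapping
B by >= 1 bp are 'shared'.  The statistic is 100 · shared ids / total
fragments, so a pair split perfectly across A and B scores 50%.  High values
mean many read pairs span both loci within the same mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as ivl
from .formats_io import GenomicInterval

MIN_MAPQ_DEFAULT = 30


@dataclass(frozen=True)
class SharingResult:
    locus_a: str
    locus_b: str
    n_total_fragments: int
    n_shared_ids: int

    @property
    def pct(self) -> float | None:
        """Percentage shared; None when no qualifying read maps in A."""
        if self.n_total_fragments == 0:
            return None
        return 100.0 * self.n_shared_ids / self.n_total_fragments


def _qualify(fragments: pd.DataFrame, min_mapq: int) -> pd.DataFrame:
    return fragments[(fragments["mapq"] >= min_mapq) & fragments["proper_pair"]]


def _mate_in(row, mate: int, iv: GenomicInterval, contained: bool) -> bool:
    chrom = getattr(row, f"chrom{mate}")
    s = getattr(row, f"start{mate}")
    e = getattr(row, f"end{mate}")
    if chrom != iv.chrom:
        return False
    if contained:
        return s >= iv.start and e <= iv.end
    return max(s, iv.start) < min(e, iv.end)


def shared_fragment_pct(
    a: GenomicInterval,
    b: GenomicInterval,
    fragments: pd.DataFrame,
    min_mapq: int = MIN_MAPQ_DEFAULT,
    dedup: bool = False,
) -> SharingResult:
    """The sharing statistic for one locus pair.

    Extraction from A requires full containment of a mate ("mapping within
    the boundaries"); intersection with B is any-overlap.  ``dedup`` drops
    exact duplicate records (same id and coordinates) first.
    """
    frags = _qualify(fragments, min_mapq)
    if dedup:
        frags = frags.drop_duplicates(
            subset=["read_id", "chrom1", "start1", "end1", "chrom2", "start2", "end2"]
        )
    ids_in_a = set()
    for row in frags.itertuples(index=False):
        if _mate_in(row, 1, a, contained=True) or _mate_in(row, 2, a, contained=True):
            ids_in_a.add(row.read_id)
    total = frags[frags["read_id"].isin(ids_in_a)]
    n_total_fragments = 2 * total["read_id"].nunique()
    shared = {
        row.read_id
        for row in total.itertuples(index=False)
        if _mate_in(row, 1, b, contained=False) or _mate_in(row, 2, b, contained=False)
    }
    return SharingResult(
        locus_a=a.id, locus_b=b.id,
        n_total_fragments=int(n_total_fragments), n_shared_ids=len(shared),
    )


def sharing_for_pairs(
    pairs: list[tuple[GenomicInterval, GenomicInterval]],
    fragments: pd.DataFrame,
    min_mapq: int = MIN_MAPQ_DEFAULT,
) -> list[SharingResult]:
    return [shared_fragment_pct(a, b, fragments, min_mapq) for a, b in pairs]


def _with_closest(queries, features) -> list[tuple[GenomicInterval, GenomicInterval]]:
    by_id = {f.id: f for f in features}
    out = []
    for q in queries:
        hit = ivl.closest(q, [f for f in features if f.id != q.id])
        if hit.found:
            out.append((q, by_id[hit.feature_id]))
    return out


def sharing_distributions(
    exons: list[GenomicInterval],
    upregulated_l1s: list[GenomicInterval],
    expressed_gene_bodies: list[GenomicInterval],
    fragments: pd.DataFrame,
    n_random: int = 1000,
    segment_length: int = 6000,
    seed: int | None = None,
    min_mapq: int = MIN_MAPQ_DEFAULT,
) -> dict[str, list[SharingResult]]:
    """The three control pairings of the exonization analysis.

    (a) ``exon_exon``: ``n_random`` expressed exons (sampled with replacement
    when fewer exist) paired with their closest exon; (b) ``l1_exon``:
    upregulated L1s with their closest exon; (c) ``random_exon``: ``n_random``
    fixed-length segments inside expressed gene bodies with their closest
    exon.  Returns the per-pairing SharingResult lists.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[SharingResult]] = {}

    if n_random > 0 and exons:
        idx = rng.integers(0, len(exons), size=min(n_random, len(exons)))
        sample_exons = [exons[int(i)] for i in idx]
        out["exon_exon"] = [
            shared_fragment_pct(a, b, fragments, min_mapq)
            for a, b in _with_closest(sample_exons, exons)
        ]
    else:
        out["exon_exon"] = []

    out["l1_exon"] = [
        shared_fragment_pct(a, b, fragments, min_mapq)
        for a, b in _with_closest(upregulated_l1s, exons)
    ]

    if n_random > 0 and expressed_gene_bodies:
        segments = ivl.random_intronic_segments(
            expressed_gene_bodies, n_random, segment_length, rng
        )
        out["random_exon"] = [
            shared_fragment_pct(seg, by, fragments, min_mapq)
            for seg, by in _with_closest(segments, exons)
        ]
    else:
        out["random_exon"] = []
    return out


def summarize_distributions(dists: dict[str, list[SharingResult]]) -> pd.DataFrame:
    rows = []
    for name, results in dists.items():
        pcts = [r.pct for r in results if r.pct is not None]
        rows.append(
            {
                "pairing": name,
                "n_pairs": len(results),
                "n_defined": len(pcts),
                "median_pct": float(np.median(pcts)) if pcts else np.nan,
                "mean_pct": float(np.mean(pcts)) if pcts else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["pairing", "n_pairs", "n_defined", "median_pct", "mean_pct"])


def rank_sum_compare(a: list[SharingResult], b: list[SharingResult]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on the defined pct values of two pairings."""
    xa = [r.pct for r in a if r.pct is not None]
    xb = [r.pct for r in b if r.pct is not None]
    if not xa or not xb:
        return np.nan, np.nan
    if np.ptp(xa + xb) == 0:  # all identical -> no evidence of difference
        return np.nan, 1.0
    stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
    return float(stat), float(p)
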