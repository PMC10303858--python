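"""Interval arithmetic with bedtools-like semantics.

All operations are strand-blind and work on 0-based half-open intervals.
Two intervals overlap iff ``max(starts) < min(ends)`` (at least 1 bp shared);
containment follows the ``-F 1`` rule (100% of the query inside the region
set) where stated.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import GenomicInterval


def _by_chrom(intervals) -> dict[str, list[GenomicInterval]]:
    d: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        d[iv.chrom].append(iv)
    for chrom in d:
        d[chrom].sort(key=lambda x: (x.start, x.end, x.id))
    return d


def merge(intervals) -> list[GenomicInterval]:
    """Union of an interval set as sorted, non-overlapping intervals."""
    out = []
    for chrom in sorted(_by_chrom(intervals)):
        cur_s = cur_e = None
        for iv in _by_chrom(intervals)[chrom]:
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def intersect_any(a, b) -> list[tuple[GenomicInterval, bool, list[str]]]:
    """For each interval of ``a``: does it overlap ``b``, and which b ids.

    Overlap requires >= 1 shared bp.  Returns ``(a_interval, flag, b_ids)``
    in the input order of ``a``; ``b_ids`` are sorted by (start, end, id).
    """
    b_chrom = _by_chrom(b)
    starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in b_chrom.items()}
    out = []
    for iv in a:
        hits: list[str] = []
        ivs = b_chrom.get(iv.chrom, [])
        if ivs:
            # candidates cannot start at/after iv.end
            hi = int(np.searchsorted(starts[iv.chrom], iv.end, side="left"))
            hits = [bv.id for bv in ivs[:hi] if bv.end > iv.start]
        out.append((iv, bool(hits), hits))
    return out


def overlaps_any(a, b) -> list[bool]:
    return [flag for _, flag, _ in intersect_any(a, b)]


def subtract(a, b) -> list[GenomicInterval]:
    """Exact per-chromosome set difference a \\ b, sorted and merged."""
    a_merged = merge(a)
    b_chrom = _by_chrom(merge(b))
    out = []
    for iv in a_merged:
        cursor = iv.start
        for bv in b_chrom.get(iv.chrom, []):
            if bv.end <= cursor or bv.start >= iv.end:
                continue
            if bv.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, bv.start))
            cursor = max(cursor, bv.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return out


@dataclass(frozen=True)
class ClosestHit:
    feature_id: str
    distance: int  # signed genomic gap: negative upstream of query, 0 on overlap
    found: bool = True


NO_NEIGHBOR = ClosestHit(feature_id="", distance=0, found=False)


def closest(query: GenomicInterval, features) -> ClosestHit:
    """Nearest feature by genomic gap; overlap -> distance 0.

    Ties are broken by smaller feature start, then lexicographic id.  With no
    feature on the query's chromosome, returns a result with ``found=False``.
    """
    best = None
    for f in features:
        if f.chrom != query.chrom:
            continue
        if max(query.start, f.start) < min(query.end, f.end):
            gap, signed = 0, 0
        elif f.start >= query.end:
            gap = f.start - query.end + 1
            signed = gap
        else:
            gap = query.start - f.end + 1
            signed = -gap
        key = (gap, f.start, f.id)
        if best is None or key < best[0]:
            best = (key, f, signed)
    if best is None:
        return NO_NEIGHBOR
    return ClosestHit(feature_id=best[1].id, distance=best[2])


def _contained(chrom: str, blocks, merged_by_chrom) -> bool:
    """All blocks fully inside the merged region set."""
    regions = merged_by_chrom.get(chrom)
    if not regions:
        return False
    starts = np.array([r.start for r in regions])
    for s, e in blocks:
        i = int(np.searchsorted(starts, s, side="right")) - 1
        if i < 0 or regions[i].end < e:
            return False
    return True


def _mate_blocks(row, mate: int, split_blocks: bool):
    s = getattr(row, f"start{mate}")
    e = getattr(row, f"end{mate}")
    if split_blocks:
        raw = getattr(row, f"blocks{mate}", None)
        if isinstance(raw, str) and raw:
            return [tuple(map(int, b.split("-"))) for b in raw.split(",")]
    return [(s, e)]


def count_contained_fragments(
    fragments: pd.DataFrame, regions, split_blocks: bool = False
) -> int:
    """Count mates falling 100% inside the region set (bedtools ``-F 1``).

    A mate counts only when its whole span — or, with ``split_blocks``, each
    of its spliced blocks (optional ``blocks1``/``blocks2`` columns holding
    ``"start-end,start-end"`` strings) — lies inside the merged regions.
    """
    merged_by_chrom = _by_chrom(merge(regions))
    n = 0
    for row in fragments.itertuples(index=False):
        for mate in (1, 2):
            chrom = getattr(row, f"chrom{mate}")
            if _contained(chrom, _mate_blocks(row, mate, split_blocks), merged_by_chrom):
                n += 1
    return n


def random_intronic_segments(
    introns, n: int, length: int, rng: np.random.Generator
) -> list[GenomicInterval]:
    """``n`` fixed-length segments placed uniformly over all eligible positions
    inside the given introns (introns shorter than ``length`` are skipped)."""
    eligible = [iv for iv in merge(introns) if iv.length >= length]
    if not eligible:
        raise ValueError(f"no intron of length >= {length}")
    weights = np.array([iv.length - length + 1 for iv in eligible], dtype=float)
    probs = weights / weights.sum()
    picks = rng.choice(len(eligible), size=n, p=probs)
    out = []
    for k, i in enumerate(picks):
        iv = eligible[int(i)]
        off = int(rng.integers(0, iv.length - length + 1))
        out.append(
            GenomicInterval(iv.chrom, iv.start + off, iv.start + off + length, ".", f"rand_{k}")
        )
    return out
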