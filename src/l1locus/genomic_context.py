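"""Genomic context of L1 loci and their relationship to host-gene expression.

Classifies each L1 as exonic / intronic / intergenic (exon contact wins over
intron contact when an element touches both), pairs DE L1s with DE genes they
overlap, collects anticorrelated host genes (negative gene z under an
upregulated intronic L1), and counts overlaps against named reference interval
sets (e.g. full-length-L1 catalogues).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals as ivl
from .formats_io import GeneModel, GenomicInterval, L1Locus
from .per_sample_de import Z_THRESHOLD_DEFAULT

EXONIC, INTRONIC, INTERGENIC = "exonic", "intronic", "intergenic"


def _overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _host_gene(l1: GenomicInterval, genes: list[GeneModel]) -> str | None:
    """Overlapping gene with maximal overlap; ties -> smaller start, then id."""
    best = None
    for g in genes:
        bp = _overlap_bp(l1, g.body)
        if bp <= 0:
            continue
        key = (-bp, g.body.start, g.gene_id)
        if best is None or key < best[0]:
            best = (key, g.gene_id)
    return None if best is None else best[1]


def classify_context(
    l1s: list[L1Locus], genes: list[GeneModel], exon_precedence: bool = True
) -> pd.DataFrame:
    """One context call per L1: columns l1_id, context, host_gene.

    Exonic if >= 1 bp overlap with any exon; else intronic if >= 1 bp overlap
    with any intron; else intergenic.  With ``exon_precedence=False`` the
    larger of exon/intron overlap decides instead.
    """
    exons = [ex for g in genes for ex in g.exons]
    intron_list = [iv for g in genes for iv in g.introns()]
    rows = []
    for locus in l1s:
        iv = locus.interval
        exon_bp = sum(_overlap_bp(iv, e) for e in exons)
        intron_bp = sum(_overlap_bp(iv, i) for i in intron_list)
        if exon_bp and (exon_precedence or exon_bp >= intron_bp):
            context = EXONIC
        elif intron_bp:
            context = INTRONIC
        else:
            context = INTERGENIC
        host = _host_gene(iv, genes) if context != INTERGENIC else None
        rows.append({"l1_id": locus.id, "context": context, "host_gene": host})
    return pd.DataFrame(rows, columns=["l1_id", "context", "host_gene"])


def _z_lookup(zt: pd.DataFrame, sample: str) -> pd.Series:
    sub = zt[zt["sample"] == sample]
    return pd.Series(sub["z"].to_numpy(), index=sub["feature"])


def de_overlap_pairs(
    zt_l1: pd.DataFrame,
    zt_genes: pd.DataFrame,
    l1s: list[L1Locus],
    genes: list[GeneModel],
    sample: str,
    z_threshold: float = Z_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Pairs (upregulated L1, DE gene) whose intervals overlap in one sample.

    Emitted when L1 z > threshold, |gene z| > threshold and the L1 overlaps
    the gene body by >= 1 bp; gene_direction follows the sign of the gene z.
    """
    zl = _z_lookup(zt_l1, sample)
    zg = _z_lookup(zt_genes, sample)
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for locus in l1s:
        z_l1 = zl.get(locus.id, np.nan)
        if not (z_l1 > z_threshold):
            continue
        for gid, z_gene in zg.items():
            if not (abs(z_gene) > z_threshold):
                continue
            g = gene_by_id[gid]
            if _overlap_bp(locus.interval, g.body) > 0:
                rows.append(
                    {
                        "l1_chrom": locus.interval.chrom,
                        "l1_start": locus.interval.start,
                        "l1_end": locus.interval.end,
                        "l1_id": locus.id,
                        "gene_name": g.gene_name,
                        "l1_z": float(z_l1),
                        "gene_z": float(z_gene),
                        "gene_direction": "Upregulated" if z_gene > 0 else "Downregulated",
                        "sample": sample,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "l1_chrom",
            "l1_start",
            "l1_end",
            "l1_id",
            "gene_name",
            "l1_z",
            "gene_z",
            "gene_direction",
            "sample",
        ],
    )


def anticorrelated_genes(
    zt_l1: pd.DataFrame,
    zt_genes: pd.DataFrame,
    l1s: list[L1Locus],
    genes: list[GeneModel],
    sample: str,
    z_threshold: float = Z_THRESHOLD_DEFAULT,
    context_calls: pd.DataFrame | None = None,
) -> set[str]:
    """Genes with negative z hosting an intronic L1 with z > threshold.

    The L1 cutoff is on the L1 z only; the gene needs z < 0, no threshold.
    """
    if context_calls is None:
        context_calls = classify_context(l1s, genes)
    zl = _z_lookup(zt_l1, sample)
    zg = _z_lookup(zt_genes, sample)
    intronic = context_calls[context_calls["context"] == INTRONIC]
    out = set()
    for row in intronic.itertuples(index=False):
        if row.host_gene is None:
            continue
        if zl.get(row.l1_id, np.nan) > z_threshold and zg.get(row.host_gene, np.nan) < 0:
            out.add(row.host_gene)
    return out


def reference_set_overlap(
    expressed_l1s: list[L1Locus], reference_sets: dict[str, list[GenomicInterval]]
) -> pd.DataFrame:
    """Count expressed L1s overlapping (>= 1 bp) each named reference set.

    One L1 may match several sets.  Returns columns set, n_matched, n_total,
    fraction_matched.
    """
    l1_ivs = [x.interval for x in expressed_l1s]
    rows = []
    for name, ref in reference_sets.items():
        flags = ivl.overlaps_any(l1_ivs, ref)
        n = int(sum(flags))
        rows.append(
            {
                "set": name,
                "n_matched": n,
                "n_total": len(l1_ivs),
                "fraction_matched": n / len(l1_ivs) if l1_ivs else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["set", "n_matched", "n_total", "fraction_matched"])


def fraction_in_expressed_genes(
    l1_subsets: dict[str, list[L1Locus]], expressed_genes: list[GeneModel]
) -> pd.DataFrame:
    """Percentage of each L1 subset overlapping (>= 1 bp) an expressed gene body."""
    bodies = [g.body for g in expressed_genes]
    rows = []
    for name, subset in l1_subsets.items():
        flags = ivl.overlaps_any([x.interval for x in subset], bodies)
        pct = 100.0 * sum(flags) / len(subset) if subset else np.nan
        rows.append({"subset": name, "n": len(subset), "pct_in_expressed_genes": pct})
    return pd.DataFrame(rows, columns=["subset", "n", "pct_in_expressed_genes"])
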