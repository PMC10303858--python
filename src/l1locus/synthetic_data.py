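"""Seeded generators for annotation, count matrices, fragment tables and
signal tracks with the statistical structure the pipeline assumes.

The default configuration mirrors the cohort the method was designed for:
9 control and 9 case brain samples, 3 of the cases carrying a strong
(8-fold) upregulation of a subset of intronic full-length L1 loci, with a
handful of host genes coupled negatively to their resident L1.  Counts are
negative binomial with mean μ and variance μ + αμ² (the standard bulk
RNA-seq noise model), per-feature baseline means and per-sample library size
factors.  Every generator is a pure function of its config, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import (
    GeneModel,
    GenomicInterval,
    L1Locus,
    fragment_table,
)
from . import genomic_context

# subfamily -> typical consensus divergence (mismatches per thousand);
# younger subfamilies diverge less
SUBFAMILY_MILLIDIV = {
    "L1HS": 5.0,
    "L1PA2": 8.0,
    "L1PA3": 12.0,
    "L1PA4": 15.0,
    "L1PA5": 20.0,
    "L1PA6": 30.0,
    "L1PA7": 45.0,
    "L1PA8": 60.0,
    "L1PA10": 90.0,
    "L1PA13": 120.0,
    "L1PA16": 150.0,
    "L1MA4": 220.0,
    "L1ME1": 300.0,
}
YOUNG_SUBFAMILIES = ["L1HS", "L1PA2", "L1PA3", "L1PA4", "L1PA5", "L1PA6", "L1PA7", "L1PA8"]
OLD_SUBFAMILIES = ["L1PA10", "L1PA13", "L1PA16", "L1MA4", "L1ME1"]

GENE_LABELS = ("SFARI", "neuron_marker", "brain_high")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chrom: str = "chr1"
    genome_length: int | None = None  # None = sized to fit the features
    n_genes: int = 300
    n_l1: int = 100
    fl_fraction: float = 0.6
    l1_context_props: tuple[float, float, float] = (0.65, 0.10, 0.25)  # intronic, exonic, intergenic
    n_controls: int = 9
    n_cases: int = 9
    affected_cases: tuple[int, ...] = (0, 1, 2)
    l1_up_fraction: float = 0.4
    l1_fold: float = 8.0
    gene_de_count: int = 50
    gene_fold: float = 8.0
    anticorr_pairs: int = 5
    anticorr_factor: float = 2.0
    nb_dispersion: float = 0.05
    base_mean_range: tuple[float, float] = (100.0, 2000.0)
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    min_expressed_mean: float = 200.0  # injected effects target loci expressed at this level

    def __post_init__(self) -> None:
        for name in ("fl_fraction", "l1_up_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.l1_context_props) - 1.0) > 1e-9:
            raise ValueError("l1_context_props must sum to 1")
        if self.n_genes < 1 or self.n_l1 < 1:
            raise ValueError("n_genes and n_l1 must be >= 1")
        if not set(self.affected_cases) <= set(range(self.n_cases)):
            raise ValueError("affected_cases must be a subset of case indices")
        for name in ("l1_fold", "gene_fold", "anticorr_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.base_mean_range
        if not (0 < lo <= hi):
            raise ValueError("base_mean_range must be positive")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must exclude 0 and be positive")


class GenomeSizeError(ValueError):
    """Requested genome too small to place the configured features."""


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def simulate_annotation(config: SimulationConfig) -> tuple[list[GeneModel], list[L1Locus]]:
    """Non-overlapping gene models (>= 2 exons each) and L1 loci stratified
    intronic/exonic/intergenic, with subfamily-dependent MilliDiv."""
    rng = np.random.default_rng([config.seed, 0])
    genes: list[GeneModel] = []
    cursor = int(rng.integers(10_000, 20_000))
    for i in range(config.n_genes):
        n_exons = int(rng.integers(2, 6))
        exon_lens = rng.integers(150, 1500, size=n_exons)
        intron_lens = rng.integers(8_000, 16_000, size=n_exons - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene_{i:04d}"
        exons = []
        pos = cursor
        for k in range(n_exons):
            exons.append(GenomicInterval(config.chrom, pos, pos + int(exon_lens[k]), strand))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        labels = frozenset(lab for lab in GENE_LABELS if rng.random() < 0.12)
        genes.append(
            GeneModel(
                gene_id=gid,
                gene_name=gid.upper(),
                body=GenomicInterval(config.chrom, cursor, pos, strand, gid),
                exons=exons,
                biotype="protein_coding",
                labels=labels,
            )
        )
        cursor = pos + int(rng.integers(9_000, 22_000))  # intergenic gap
    required = cursor + 20_000
    if config.genome_length is not None and config.genome_length < required:
        raise GenomeSizeError(
            f"genome_length {config.genome_length} too small: placing {config.n_genes} "
            f"genes needs >= {required} bp"
        )
    genome_length = config.genome_length or required

    # context strata, exact counts
    n_int = int(round(config.l1_context_props[0] * config.n_l1))
    n_ex = int(round(config.l1_context_props[1] * config.n_l1))
    n_inter = config.n_l1 - n_int - n_ex
    contexts = ["intronic"] * n_int + ["exonic"] * n_ex + ["intergenic"] * n_inter
    rng.shuffle(contexts)

    n_fl = int(round(config.fl_fraction * config.n_l1))
    is_fl = np.zeros(config.n_l1, dtype=bool)
    is_fl[rng.choice(config.n_l1, size=n_fl, replace=False)] = True

    introns = [iv for g in genes for iv in g.introns()]
    all_exons = [ex for g in genes for ex in g.exons]
    gaps = []
    prev_end = 0
    for g in genes:
        if g.body.start - prev_end > 0:
            gaps.append((prev_end, g.body.start))
        prev_end = g.body.end
    if genome_length - prev_end > 0:
        gaps.append((prev_end, genome_length))

    l1s: list[L1Locus] = []
    for i in range(config.n_l1):
        length = int(rng.integers(5_500, 6_500)) if is_fl[i] else int(rng.integers(600, 3_000))
        ctx = contexts[i]
        if ctx == "intronic":
            fitting = [iv for iv in introns if iv.length >= length + 2]
            if not fitting:
                raise GenomeSizeError(f"no intron can host an L1 of {length} bp")
            host = fitting[int(rng.integers(0, len(fitting)))]
            start = host.start + 1 + int(rng.integers(0, host.length - length - 1))
        elif ctx == "exonic":
            ex = all_exons[int(rng.integers(0, len(all_exons)))]
            start = ex.start + int(rng.integers(0, max(1, ex.length - 1)))
        else:
            fitting = [(s, e) for s, e in gaps if e - s >= length + 2]
            if not fitting:
                raise GenomeSizeError(f"no intergenic gap can host an L1 of {length} bp")
            s, e = fitting[int(rng.integers(0, len(fitting)))]
            start = s + 1 + int(rng.integers(0, e - s - length - 1))
        end = min(start + length, genome_length)
        subfam = (
            YOUNG_SUBFAMILIES[int(rng.integers(0, len(YOUNG_SUBFAMILIES)))]
            if is_fl[i]
            else (YOUNG_SUBFAMILIES + OLD_SUBFAMILIES)[
                int(rng.integers(0, len(YOUNG_SUBFAMILIES) + len(OLD_SUBFAMILIES)))
            ]
        )
        base = SUBFAMILY_MILLIDIV[subfam]
        milli_div = float(max(0.0, rng.normal(base, 0.2 * base)))
        strand = "+" if rng.random() < 0.5 else "-"
        l1s.append(
            L1Locus(
                GenomicInterval(config.chrom, start, end, strand, f"l1_{i:04d}"),
                subfamily=subfam,
                milli_div=milli_div,
            )
        )
    return genes, l1s


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Counts with mean mu and variance mu + alpha*mu**2."""
    if alpha == 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    ids = [f"ctrl_{i + 1:02d}" for i in range(config.n_controls)] + [
        f"case_{i + 1:02d}" for i in range(config.n_cases)
    ]
    groups = ["control"] * config.n_controls + ["case"] * config.n_cases
    return pd.DataFrame({"sample_id": ids, "group": groups, "dataset": "sim"})


def simulate_counts(
    config: SimulationConfig, genes: list[GeneModel], l1s: list[L1Locus]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(gene counts, L1 counts, sample sheet, ground truth).

    Affected case samples carry ``l1_fold`` upregulation of a subset of
    expressed intronic full-length L1s, ``gene_de_count`` dysregulated genes,
    and a negative coupling (mean divided by ``anticorr_factor``) on the host
    genes of ``anticorr_pairs`` of the upregulated L1s.  The truth table
    records every injected effect.
    """
    rng = np.random.default_rng([config.seed, 1])
    sheet = sample_sheet(config)
    n_samples = len(sheet)
    affected_cols = [config.n_controls + i for i in config.affected_cases]

    sf = rng.uniform(*config.size_factor_range, size=n_samples)

    gene_ids = [g.gene_id for g in genes]
    l1_ids = [x.id for x in l1s]
    gene_base = rng.uniform(*config.base_mean_range, size=len(genes))
    # younger (lower-MilliDiv) copies are transcribed at higher baseline
    age_weight = np.exp(-np.array([x.milli_div for x in l1s]) / 100.0)
    l1_base = rng.uniform(*config.base_mean_range, size=len(l1s)) * age_weight

    context = genomic_context.classify_context(l1s, genes)
    is_intronic_fl = (
        (context["context"] == "intronic").to_numpy()
        & np.array([x.length > 5000 for x in l1s])
    )
    expressed_enough = l1_base >= config.min_expressed_mean
    candidates = np.flatnonzero(is_intronic_fl & expressed_enough)
    n_up = int(round(config.l1_up_fraction * len(candidates)))
    up_idx = rng.choice(candidates, size=n_up, replace=False) if n_up else np.array([], int)

    host_of = dict(zip(context["l1_id"], context["host_gene"]))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # anticorrelated host genes: hosts of upregulated L1s, expressed baseline
    anticorr: list[tuple[str, str]] = []  # (l1_id, gene_id)
    for i in rng.permutation(up_idx):
        host = host_of.get(l1_ids[int(i)])
        if host and gene_base[gene_pos[host]] >= config.min_expressed_mean:
            if all(host != g for _, g in anticorr):
                anticorr.append((l1_ids[int(i)], host))
        if len(anticorr) >= config.anticorr_pairs:
            break

    anticorr_gene_idx = {gene_pos[g] for _, g in anticorr}
    de_candidates = np.array(
        [
            i
            for i in range(len(genes))
            if gene_base[i] >= config.min_expressed_mean and i not in anticorr_gene_idx
        ]
    )
    n_de = min(config.gene_de_count, len(de_candidates))
    de_idx = rng.choice(de_candidates, size=n_de, replace=False) if n_de else np.array([], int)
    de_dir = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)

    mu_genes = np.outer(gene_base, sf)
    mu_l1 = np.outer(l1_base, sf)
    for col in affected_cols:
        mu_l1[up_idx, col] *= config.l1_fold
        for k, gi in enumerate(de_idx):
            mu_genes[gi, col] *= config.gene_fold if de_dir[k] > 0 else 1.0 / config.gene_fold
        for _, gname in anticorr:
            mu_genes[gene_pos[gname], col] /= config.anticorr_factor

    counts_genes = pd.DataFrame(
        _nb_draw(rng, mu_genes, config.nb_dispersion),
        index=pd.Index(gene_ids, name="feature"),
        columns=sheet["sample_id"],
    )
    counts_l1 = pd.DataFrame(
        _nb_draw(rng, mu_l1, config.nb_dispersion),
        index=pd.Index(l1_ids, name="feature"),
        columns=sheet["sample_id"],
    )

    affected_names = ",".join(sheet["sample_id"].iloc[affected_cols])
    truth_rows = [
        {
            "feature": l1_ids[int(i)],
            "kind": "l1",
            "effect": "up",
            "fold": config.l1_fold,
            "samples": affected_names,
            "partner": "",
        }
        for i in up_idx
    ]
    truth_rows += [
        {
            "feature": gene_ids[int(gi)],
            "kind": "gene",
            "effect": "up" if de_dir[k] > 0 else "down",
            "fold": config.gene_fold,
            "samples": affected_names,
            "partner": "",
        }
        for k, gi in enumerate(de_idx)
    ]
    truth_rows += [
        {
            "feature": g,
            "kind": "gene",
            "effect": "anticorr_host",
            "fold": config.anticorr_factor,
            "samples": affected_names,
            "partner": l1_id,
        }
        for l1_id, g in anticorr
    ]
    truth = pd.DataFrame(
        truth_rows, columns=["feature", "kind", "effect", "fold", "samples", "partner"]
    )
    return counts_genes, counts_l1, sheet, truth


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------


def simulate_fragments(
    locus_a: GenomicInterval,
    locus_b: GenomicInterval,
    n_pairs: int,
    co_spliced_fraction: float = 0.0,
    mapq_params: dict | None = None,
    read_len: int = 100,
    seed: int | None = None,
    read_id_prefix: str = "frag",
) -> pd.DataFrame:
    """Paired-end fragments anchored in ``locus_a``.

    A ``co_spliced_fraction`` of the pairs has mate 1 inside A and mate 2
    inside B (a co-splicing event); the rest have both mates inside A.
    ``mapq_params`` keys: min (default 30), max (60), low_fraction (pairs
    drawn with mapq below min), improper_fraction (flagged not proper).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not 0.0 <= co_spliced_fraction <= 1.0:
        raise ValueError("co_spliced_fraction must be in [0, 1]")
    if locus_a.length < read_len or locus_b.length < read_len:
        raise ValueError("loci shorter than the read length")
    params = {"min": 30, "max": 60, "low_fraction": 0.0, "improper_fraction": 0.0}
    params.update(mapq_params or {})
    rng = np.random.default_rng(seed)
    n_split = int(round(co_spliced_fraction * n_pairs))
    records = []
    for i in range(n_pairs):
        split = i < n_split
        s1 = locus_a.start + int(rng.integers(0, locus_a.length - read_len + 1))
        if split:
            target = locus_b
        else:
            target = locus_a
        s2 = target.start + int(rng.integers(0, target.length - read_len + 1))
        low = rng.random() < params["low_fraction"]
        mapq = (
            int(rng.integers(0, params["min"]))
            if low
            else int(rng.integers(params["min"], params["max"] + 1))
        )
        records.append(
            {
                "chrom1": locus_a.chrom,
                "start1": s1,
                "end1": s1 + read_len,
                "chrom2": target.chrom,
                "start2": s2,
                "end2": s2 + read_len,
                "read_id": f"{read_id_prefix}_{i:06d}",
                "mapq": mapq,
                "strand1": "+",
                "strand2": "-",
                "proper_pair": rng.random() >= params["improper_fraction"],
            }
        )
    return fragment_table(records)


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------


def simulate_signal_track(
    regions,
    genome_length: int,
    enrich_level: float,
    background_level: float,
    noise: float = 0.0,
    seed: int | None = None,
    bin_size: int = 200,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Contiguous bedGraph over [0, genome_length): value ≈ ``enrich_level``
    inside the regions and ``background_level`` elsewhere, with Gaussian noise
    of the given sd added per run.  Run boundaries align with region edges, so
    at noise=0 the levels are exact."""
    if enrich_level < 0 or background_level < 0:
        raise ValueError("levels must be >= 0")
    for iv in regions:
        if iv.chrom != chrom or iv.start < 0 or iv.end > genome_length:
            raise ValueError(f"region {iv.chrom}:{iv.start}-{iv.end} outside genome bounds")
    rng = np.random.default_rng(seed)
    edges = sorted({0, genome_length} | {iv.start for iv in regions} | {iv.end for iv in regions})
    region_sorted = sorted((iv.start, iv.end) for iv in regions)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        inside = any(s <= a and b <= e for s, e in region_sorted)
        level = enrich_level if inside else background_level
        pos = a
        while pos < b:
            nxt = min(pos + bin_size, b)
            value = level + (noise * rng.normal() if noise > 0 else 0.0)
            rows.append((chrom, pos, nxt, float(value)))
            pos = nxt
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
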