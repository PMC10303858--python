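"""End-to-end orchestration: simulate (or load) inputs, normalize, filter,
score, classify, and summarize, writing every stage table under one output
directory along with a manifest and a human-readable report."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import correlation as corr
from . import enrichment_resampling as enr
from . import formats_io as fio
from . import fragment_sharing as fsh
from . import genomic_context as ctx
from . import intervals as ivl
from . import normalize_filter as nf
from . import per_sample_de as de
from . import signal_profiles as sp
from . import synthetic_data as sim

log = logging.getLogger("l1locus")

L1_SUBFAMILY_WHITELIST = ("L1HS", "L1PA*")


@dataclass
class PipelineConfig:
    out_dir: str = "l1locus_run"
    seed: int = 0
    # stage thresholds
    min_mean_l1: float = 200.0
    min_mean_genes: float = 200.0
    min_length: int = 5000
    z_threshold: float = 3.0
    min_mapq: int = 30
    n_resamples: int = 1000
    n_sharing_pairs: int = 30
    fragments_per_locus: int = 40
    flank: int = 5000
    body_bins: int = 60
    flank_bin_size: int = 50
    log_level: str = "INFO"
    # either a simulation config (self-generated run) or paths to inputs
    simulation: sim.SimulationConfig | None = field(default_factory=sim.SimulationConfig)
    counts_l1_path: str | None = None
    counts_genes_path: str | None = None
    l1_bed_path: str | None = None
    genes_gtf_path: str | None = None
    samples_path: str | None = None

    def validate(self) -> None:
        if self.z_threshold <= 0 or self.min_mapq < 0 or self.n_resamples < 1:
            raise ValueError("thresholds out of range")
        if self.simulation is None:
            for name in ("counts_l1_path", "counts_genes_path", "l1_bed_path",
                         "genes_gtf_path", "samples_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"no simulation config and no {name}")
                if not Path(p).exists():
                    raise ValueError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_cfg = raw.pop("simulation", "default")
        cfg = cls(**raw)
        if sim_cfg is None:
            cfg.simulation = None
        elif sim_cfg == "default":
            pass
        else:
            sim_cfg.setdefault("affected_cases", (0, 1, 2))
            if isinstance(sim_cfg["affected_cases"], list):
                sim_cfg["affected_cases"] = tuple(sim_cfg["affected_cases"])
            cfg.simulation = sim.SimulationConfig(**sim_cfg)
        return cfg


def _setup_logging(out: Path, level: str) -> None:
    log.setLevel(level.upper())
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(out / "run.log", mode="w")):
        h.setFormatter(fmt)
        log.addHandler(h)


def _load_or_simulate(config: PipelineConfig, out: Path):
    if config.simulation is not None:
        scfg = config.simulation
        log.info("simulating inputs (seed=%d)", scfg.seed)
        genes, l1s = sim.simulate_annotation(scfg)
        counts_genes, counts_l1, samples, truth = sim.simulate_counts(scfg, genes, l1s)
        fio.write_gtf_genes(genes, out / "genes.gtf")
        fio.write_bed(l1s, out / "l1.bed")
        fio.write_counts_tsv(counts_genes, out / "counts_genes.tsv")
        fio.write_counts_tsv(counts_l1, out / "counts_l1.tsv")
        fio.write_sample_sheet(samples, out / "samples.tsv")
        fio.write_tsv(truth, out / "truth.tsv")
        return genes, l1s, counts_genes, counts_l1, samples, truth
    genes = fio.read_gtf_genes(config.genes_gtf_path)
    l1s = fio.read_bed(config.l1_bed_path)
    counts_genes = fio.read_counts_tsv(config.counts_genes_path)
    counts_l1 = fio.read_counts_tsv(config.counts_l1_path)
    samples = fio.read_sample_sheet(config.samples_path)
    return genes, l1s, counts_genes, counts_l1, samples, None


def run_end_to_end(config: PipelineConfig) -> dict:
    """Execute every stage in dependency order; returns a summary dict.

    All outputs land in ``config.out_dir``; rerunning with the same config
    and seed reproduces them byte for byte.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.log_level)
    rng_seed = config.seed
    summary: dict = {"seed": rng_seed}

    genes, l1s, counts_genes, counts_l1, samples, truth = _load_or_simulate(config, out)

    # --- normalization -----------------------------------------------------
    sf_genes = nf.estimate_size_factors(counts_genes)
    sf_l1 = nf.estimate_size_factors(pd.concat([counts_l1, counts_genes]))
    norm_genes = nf.normalize(counts_genes, sf_genes)
    norm_l1 = nf.normalize(counts_l1, sf_l1)
    fio.write_tsv(sf_genes.rename("size_factor").to_frame(), out / "size_factors.tsv", index=True)
    fio.write_counts_tsv(norm_genes.round(4), out / "normalized_genes.tsv")
    fio.write_counts_tsv(norm_l1.round(4), out / "normalized_l1.tsv")

    # --- expressed-feature filters -----------------------------------------
    lengths = pd.Series({x.id: x.length for x in l1s})
    subfams = pd.Series({x.id: x.subfamily for x in l1s})
    expressed_l1 = nf.select_expressed(
        counts_l1, min_mean=config.min_mean_l1, min_length=config.min_length,
        subfamilies=L1_SUBFAMILY_WHITELIST, lengths=lengths, feature_subfamilies=subfams,
    )
    expressed_genes = nf.select_expressed(counts_genes, min_mean=config.min_mean_genes)
    summary["n_expressed_l1"] = len(expressed_l1)
    summary["n_expressed_genes"] = len(expressed_genes)
    log.info("expressed: %d L1 loci, %d genes", len(expressed_l1), len(expressed_genes))

    millidiv = nf.millidiv_summary(l1s, expressed_l1)
    fio.write_tsv(millidiv, out / "millidiv_summary.tsv")

    # --- per-sample z-scores ------------------------------------------------
    zt_l1 = de.per_sample_z(norm_l1, samples, expressed_l1, z_threshold=config.z_threshold)
    zt_genes = de.per_sample_z(norm_genes, samples, expressed_genes,
                               z_threshold=config.z_threshold)
    fio.write_tsv(zt_l1.round(4), out / "zscores_l1.tsv")
    fio.write_tsv(zt_genes.round(4), out / "zscores_genes.tsv")
    net = de.net_upregulated(zt_l1, config.z_threshold)
    fio.write_tsv(net, out / "net_upregulation.tsv")
    de_counts = de.de_gene_counts(zt_genes, config.z_threshold)
    fio.write_tsv(de_counts.to_frame(), out / "de_gene_counts.tsv", index=True)
    summary["max_net_upregulation"] = int(net["net"].max())
    summary["expected_null_de_per_sample"] = de.expected_false_positive_count(
        len(expressed_genes), (samples["group"] == "control").sum(), config.z_threshold
    )

    # --- genomic context and overlap pairs ----------------------------------
    expressed_l1_loci = [x for x in l1s if x.id in set(expressed_l1.feature_ids)]
    context = ctx.classify_context(expressed_l1_loci, genes)
    fio.write_tsv(context, out / "context_calls.tsv")
    case_ids = samples.loc[samples["group"] != "control", "sample_id"]
    pair_frames = [
        ctx.de_overlap_pairs(zt_l1, zt_genes, expressed_l1_loci, genes, s, config.z_threshold)
        for s in case_ids
    ]
    nonempty = [f for f in pair_frames if len(f)]
    pairs = pd.concat(nonempty, ignore_index=True) if nonempty else pair_frames[0]
    fio.write_tsv(pairs, out / "overlap_pairs.tsv")
    summary["n_overlap_pairs"] = len(pairs)

    anti: set[str] = set()
    anti_rows = []
    for s in case_ids:
        found = ctx.anticorrelated_genes(
            zt_l1, zt_genes, expressed_l1_loci, genes, s, config.z_threshold, context
        )
        anti |= found
        anti_rows += [{"sample": s, "gene_id": g} for g in sorted(found)]
    fio.write_tsv(pd.DataFrame(anti_rows, columns=["sample", "gene_id"]),
                  out / "anticorrelated_genes.tsv")
    summary["n_anticorrelated_genes"] = len(anti)

    # --- resampling enrichment ----------------------------------------------
    universe = set(expressed_genes.feature_ids)
    gene_by_id = {g.gene_id: g for g in genes}
    label_sets = {
        lab: {g.gene_id for g in genes if lab in g.labels and g.gene_id in universe}
        for lab in sim.GENE_LABELS
    }
    results = []
    if anti:
        for name, genes_of in label_sets.items():
            results.append(
                enr.resampling_enrichment(anti & universe, genes_of, universe,
                                          n=config.n_resamples, seed=rng_seed, set_name=name)
            )
    fio.write_tsv(enr.results_table(results), out / "enrichment.tsv")

    # --- exonization: shared fragments ---------------------------------------
    exon_ivs = [
        fio.GenomicInterval(e.chrom, e.start, e.end, e.strand, f"{g.gene_id}_ex{k}")
        for g in genes if g.gene_id in universe
        for k, e in enumerate(g.exons)
    ]
    up_l1_ids = set(zt_l1.loc[zt_l1["status"] == "up", "feature"])
    up_l1_ivs = [x.interval for x in expressed_l1_loci if x.id in up_l1_ids]
    frag_rng = np.random.default_rng([rng_seed, 7])
    frames = []
    for k, ex in enumerate(exon_ivs[: config.n_sharing_pairs]):
        hit = ivl.closest(ex, [e for e in exon_ivs if e.id != ex.id])
        if not hit.found:
            continue
        partner = next(e for e in exon_ivs if e.id == hit.feature_id)
        frames.append(sim.simulate_fragments(
            ex, partner, config.fragments_per_locus, co_spliced_fraction=0.5,
            seed=int(frag_rng.integers(2**31)), read_id_prefix=f"ex{k}",
        ))
    for k, iv in enumerate(up_l1_ivs):
        frames.append(sim.simulate_fragments(
            iv, iv, config.fragments_per_locus, co_spliced_fraction=0.0,
            seed=int(frag_rng.integers(2**31)), read_id_prefix=f"l1{k}",
        ))
    fragments = (
        pd.concat(frames, ignore_index=True) if frames else fio.fragment_table([])
    )
    fio.write_bedpe(fragments, out / "fragments.bedpe")
    gene_bodies = [gene_by_id[g].body for g in sorted(universe)]
    dists = fsh.sharing_distributions(
        exon_ivs, up_l1_ivs, gene_bodies, fragments,
        n_random=config.n_sharing_pairs, seed=rng_seed, min_mapq=config.min_mapq,
    )
    sharing_summary = fsh.summarize_distributions(dists)
    fio.write_tsv(sharing_summary, out / "sharing_summary.tsv")

    # --- signal profiles ------------------------------------------------------
    if config.simulation is not None and up_l1_ivs:
        genome_length = max(g.body.end for g in genes) + 50_000
        track = sim.simulate_signal_track(
            up_l1_ivs, genome_length, enrich_level=5.0, background_level=1.0,
            noise=0.2, seed=rng_seed, chrom=config.simulation.chrom,
        )
        fio.write_bedgraph(track, out / "signal.bedgraph")
        pm = sp.profile_matrix(track, up_l1_ivs, config.flank, config.body_bins,
                               config.flank_bin_size)
        introns = [iv for g in genes for iv in g.introns()]
        rand = ivl.random_intronic_segments(
            introns, min(100, len(up_l1_ivs) * 10), 6000,
            np.random.default_rng([rng_seed, 11]),
        )
        pm_rand = sp.profile_matrix(track, rand, config.flank, config.body_bins,
                                    config.flank_bin_size)
        prof = pd.DataFrame({
            "bin": range(pm.values.shape[1]),
            "upregulated_l1": sp.mean_profile(pm),
            "random_intronic": sp.mean_profile(pm_rand),
        })
        fio.write_tsv(prof.round(4), out / "mean_profile.tsv")
        summary["profile_body_vs_flank"] = float(
            sp.mean_profile(pm)[pm.n_flank_bins: -pm.n_flank_bins].mean()
            / max(sp.mean_profile(pm)[: pm.n_flank_bins].mean(), 1e-9)
        )

    # --- correlations ----------------------------------------------------------
    corr_table, neg_frac = corr.l1_host_correlation(
        norm_l1, norm_genes, context, expressed_l1_ids=set(expressed_l1.feature_ids)
    )
    fio.write_tsv(corr_table.round(4), out / "correlations.tsv")
    summary["l1_host_negative_fraction"] = neg_frac
    fl_ids = [x.id for x in expressed_l1_loci]
    total_fl = norm_l1.loc[[i for i in fl_ids if i in norm_l1.index]].sum(axis=0)
    de_per_sample = de_counts.reindex(total_fl.index).fillna(0)
    if np.ptp(total_fl.to_numpy()) > 0 and np.ptp(de_per_sample.to_numpy()) > 0:
        r, p = corr.metric_correlation(total_fl.to_numpy(), de_per_sample.to_numpy())
        summary["fl_l1_vs_de_genes_r"] = r
        summary["fl_l1_vs_de_genes_p"] = p

    # --- report and manifest ----------------------------------------------------
    if truth is not None:
        injected = set(truth.loc[truth["effect"] == "up", "feature"]) & set(
            zt_l1["feature"]
        )
        affected = set(truth["samples"].iloc[0].split(",")) if len(truth) else set()
        top = set(net.sort_values("net", ascending=False)["sample"].head(len(affected)))
        summary["affected_samples"] = sorted(affected)
        summary["top_net_samples"] = sorted(top)
        summary["affected_recovered"] = affected == top
        if injected and affected:
            up_calls = zt_l1[(zt_l1["status"] == "up") & zt_l1["sample"].isin(affected)]
            hits = sum(
                1 for f in injected
                for s in affected
                if ((up_calls["feature"] == f) & (up_calls["sample"] == s)).any()
            )
            summary["l1_sensitivity"] = hits / (len(injected) * len(affected))

    manifest = {
        "package": "l1locus",
        "version": __version__,
        "seed": rng_seed,
        "config": {k: v for k, v in asdict(config).items() if k != "simulation"},
        "simulation": asdict(config.simulation) if config.simulation else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    _write_report(out, summary, net, sharing_summary)
    log.info("pipeline complete: %s", out)
    return summary


def _write_report(out: Path, summary: dict, net: pd.DataFrame, sharing: pd.DataFrame) -> None:
    lines = ["# l1locus run report", ""]
    for k, v in summary.items():
        lines.append(f"- **{k}**: {v}")
    lines += ["", "## Net L1 upregulation per sample", "", net.to_string(index=False), ""]
    if len(sharing):
        lines += ["## Fragment sharing", "", sharing.to_string(index=False), ""]
    (out / "report.md").write_text("\n".join(lines) + "\n")
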