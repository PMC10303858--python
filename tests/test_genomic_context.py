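"""Context classification, DE-overlap pairs, anticorrelated genes, reference
overlaps."""

import numpy as np
import pandas as pd
import pytest

from l1locus import genomic_context as ctx
from l1locus import normalize_filter as nf
from l1locus import per_sample_de as de
from l1locus import synthetic_data as sim
from l1locus.formats_io import GeneModel, GenomicInterval as GI, L1Locus


def gene(gid, start, end, exon_spans, chrom="chr1"):
    return GeneModel(
        gene_id=gid, gene_name=gid.upper(),
        body=GI(chrom, start, end, "+", gid),
        exons=[GI(chrom, s, e, "+") for s, e in exon_spans],
    )


def l1(lid, start, end, chrom="chr1"):
    return L1Locus(GI(chrom, start, end, ".", lid), "L1HS", 5.0)


GENES = [gene("g1", 0, 50_000, [(0, 1000), (49_000, 50_000)])]


class TestClassifyContext:
    def test_l1_inside_intron(self):
        calls = ctx.classify_context([l1("a", 10_000, 16_000)], GENES)
        assert calls.iloc[0]["context"] == "intronic"
        assert calls.iloc[0]["host_gene"] == "g1"

    def test_exon_precedence_over_intron(self):
        # touches the first exon by 1 bp, the intron by ~5 kb
        calls = ctx.classify_context([l1("a", 999, 6_000)], GENES)
        assert calls.iloc[0]["context"] == "exonic"

    def test_outside_all_genes_is_intergenic_without_host(self):
        calls = ctx.classify_context([l1("a", 100_000, 106_000)], GENES)
        assert calls.iloc[0]["context"] == "intergenic"
        assert calls.iloc[0]["host_gene"] is None

    def test_partition_is_exhaustive_and_exclusive(self, small_simulation):
        _, genes, l1s, *_ = small_simulation
        calls = ctx.classify_context(l1s, genes)
        assert len(calls) == len(l1s)
        assert set(calls["context"]) <= {"exonic", "intronic", "intergenic"}
        assert calls["context"].value_counts().sum() == len(l1s)
        genic = calls["context"] != "intergenic"
        assert calls.loc[genic, "host_gene"].notna().all()
        assert calls.loc[~genic, "host_gene"].isna().all()


def zt(entries, kind="feature"):
    rows = [
        {"feature": f, "sample": s, "z": z, "log2fc": 0.0,
         "status": "up" if z > 3 else ("down" if z < -3 else "ns")}
        for f, s, z in entries
    ]
    return pd.DataFrame(rows)


class TestDeOverlapPairs:
    def test_pair_emitted_with_direction(self):
        zl = zt([("a", "s1", 4.0)])
        zg = zt([("g1", "s1", -4.0)])
        pairs = ctx.de_overlap_pairs(zl, zg, [l1("a", 10_000, 16_000)], GENES, "s1")
        assert len(pairs) == 1
        assert pairs.iloc[0]["gene_direction"] == "Downregulated"

    def test_non_de_gene_is_not_paired(self):
        zl = zt([("a", "s1", 4.0)])
        zg = zt([("g1", "s1", -1.0)])
        assert ctx.de_overlap_pairs(zl, zg, [l1("a", 10_000, 16_000)], GENES, "s1").empty

    def test_agrees_with_brute_force_double_loop(self, small_simulation):
        cfg, genes, l1s, counts_genes, counts_l1, sheet, _ = small_simulation
        norm_g = nf.normalize(counts_genes, nf.estimate_size_factors(counts_genes))
        norm_l = nf.normalize(counts_l1, nf.estimate_size_factors(counts_genes))
        zt_g = de.per_sample_z(norm_g, sheet)
        zt_l = de.per_sample_z(norm_l, sheet)
        sample = "case_01"
        pairs = ctx.de_overlap_pairs(zt_l, zt_g, l1s, genes, sample)
        zl = zt_l[zt_l["sample"] == sample].set_index("feature")["z"]
        zg = zt_g[zt_g["sample"] == sample].set_index("feature")["z"]
        expected = {
            (x.id, g.gene_id)
            for x in l1s
            for g in genes
            if zl.get(x.id, np.nan) > 3
            and abs(zg.get(g.gene_id, np.nan)) > 3
            and x.interval.chrom == g.body.chrom
            and max(x.interval.start, g.body.start) < min(x.interval.end, g.body.end)
        }
        got = set(zip(pairs["l1_id"], pairs["gene_name"].str.lower()))
        assert got == {(a, b.lower()) for a, b in expected}


class TestAnticorrelatedGenes:
    CASES = [
        (4.0, -0.5, True),   # upregulated intronic L1, negative gene z
        (2.5, -0.5, False),  # L1 below threshold
        (4.0, 0.2, False),   # gene z positive
    ]

    @pytest.mark.parametrize("l1_z,gene_z,included", CASES)
    def test_definition(self, l1_z, gene_z, included):
        zl = zt([("a", "s1", l1_z)])
        zg = zt([("g1", "s1", gene_z)])
        out = ctx.anticorrelated_genes(zl, zg, [l1("a", 10_000, 16_000)], GENES, "s1")
        assert ("g1" in out) is included

    def test_recovers_imposed_anticorrelation(self):
        # l1_fold >= 4 and coupling >= 2: the anticorrelated hosts written to
        # the truth table should be recovered in most seeds
        hits, total = 0, 0
        for seed in range(20):
            cfg = sim.SimulationConfig(seed=seed, l1_fold=4.0, anticorr_factor=2.0,
                                       anticorr_pairs=5)
            genes, l1s = sim.simulate_annotation(cfg)
            cg, cl, sheet, truth = sim.simulate_counts(cfg, genes, l1s)
            sf = nf.estimate_size_factors(cg)
            zt_g = de.per_sample_z(nf.normalize(cg, sf), sheet)
            zt_l = de.per_sample_z(nf.normalize(cl, sf), sheet)
            calls = ctx.classify_context(l1s, genes)
            affected = truth["samples"].iloc[0].split(",")
            found = set()
            for s in affected:
                found |= ctx.anticorrelated_genes(zt_l, zt_g, l1s, genes, s,
                                                  context_calls=calls)
            expected = set(truth.loc[truth["effect"] == "anticorr_host", "feature"])
            hits += len(found & expected)
            total += len(expected)
        assert total > 0
        assert hits / total >= 0.8


class TestReferenceOverlap:
    def test_identical_and_disjoint_records(self):
        loci = [l1("a", 1000, 7000)]
        out = ctx.reference_set_overlap(
            loci,
            {"match": [GI("chr1", 1000, 7000)], "miss": [GI("chr1", 50_000, 56_000)]},
        )
        out = out.set_index("set")
        assert out.loc["match", "n_matched"] == 1
        assert out.loc["miss", "n_matched"] == 0

    def test_constructed_fraction(self, rng):
        loci = [l1(f"x{i}", 10_000 * i + 1000, 10_000 * i + 7000) for i in range(10)]
        ref = [x.interval for x in loci[:9]]  # covers 90%
        out = ctx.reference_set_overlap(loci, {"ref": ref})
        assert out.iloc[0]["fraction_matched"] == pytest.approx(0.9)


class TestFractionInExpressedGenes:
    def test_boundary_fractions(self):
        inside = [l1("a", 10_000, 16_000)]
        outside = [l1("b", 100_000, 106_000)]
        out = ctx.fraction_in_expressed_genes(
            {"all_in": inside, "none_in": outside, "three_of_four": inside * 3 + outside},
            GENES,
        ).set_index("subset")
        assert out.loc["all_in", "pct_in_expressed_genes"] == 100.0
        assert out.loc["none_in", "pct_in_expressed_genes"] == 0.0
        assert out.loc["three_of_four", "pct_in_expressed_genes"] == 75.0
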