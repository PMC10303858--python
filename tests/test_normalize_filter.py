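"""Median-of-ratios normalization and the expression / retained-intron filters."""

import numpy as np
import pandas as pd
import pytest

from l1locus import normalize_filter as nf
from l1locus.formats_io import GenomicInterval, L1Locus


def matrix(rows, samples=None):
    rows = np.asarray(rows)
    return pd.DataFrame(
        rows,
        index=[f"f{i}" for i in range(rows.shape[0])],
        columns=samples or [f"s{j}" for j in range(rows.shape[1])],
    )


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        sf = nf.estimate_size_factors(matrix([[10, 10], [7, 7], [300, 300]]))
        assert np.allclose(sf, [1.0, 1.0])

    def test_doubled_library_splits_geometrically(self):
        raw = matrix([[10, 20], [50, 100], [7, 14]])
        sf = nf.estimate_size_factors(raw)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_rows_with_zeros_are_excluded_from_reference(self):
        sf = nf.estimate_size_factors(matrix([[0, 5], [10, 10]]))
        assert np.allclose(sf, [1.0, 1.0])

    def test_all_rows_with_zeros_is_an_error(self):
        with pytest.raises(ValueError, match="pre-filter"):
            nf.estimate_size_factors(matrix([[0, 5], [10, 0]]))

    def test_scale_equivariance(self, rng):
        # scaling one sample by c scales its factor by c (after geometric
        # renormalization all factors shift by a common constant k)
        raw = matrix(rng.integers(1, 1000, size=(50, 4)))
        sf = nf.estimate_size_factors(raw)
        scaled = raw.copy()
        scaled["s1"] *= 5
        sf2 = nf.estimate_size_factors(scaled)
        ratio = (sf2 / sf).to_numpy()
        assert np.allclose(ratio[1] / ratio[0], 5.0)
        assert np.allclose(ratio[[0, 2, 3]], ratio[0])


class TestNormalize:
    def test_unit_factors_leave_matrix_unchanged(self):
        raw = matrix([[10, 20], [5, 8]])
        sf = pd.Series([1.0, 1.0], index=raw.columns)
        pd.testing.assert_frame_equal(nf.normalize(raw, sf), raw.astype(float))

    def test_factor_two_halves_a_column(self):
        raw = matrix([[10, 20], [6, 8]])
        sf = pd.Series([1.0, 2.0], index=raw.columns)
        out = nf.normalize(raw, sf)
        assert np.allclose(out["s1"], [10, 4])

    def test_round_trip_raw_equals_normalized_times_factor(self, rng):
        raw = matrix(rng.integers(1, 500, size=(20, 5)))
        sf = nf.estimate_size_factors(raw)
        assert np.allclose(nf.normalize(raw, sf) * sf.to_numpy(), raw)

    def test_constant_feature_becomes_flat_after_normalization(self, rng):
        # a feature tracking library size exactly loses all sample variation
        sf_true = np.array([0.5, 1.0, 2.0, 4.0])
        base = rng.integers(100, 1000, size=(100, 1)).astype(float)
        raw = matrix(np.round(base * sf_true))
        out = nf.normalize(raw, nf.estimate_size_factors(raw))
        cv = out.std(axis=1) / out.mean(axis=1)
        assert (cv < 0.02).all()

    def test_missing_sample_in_factors_is_an_error(self):
        raw = matrix([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="missing"):
            nf.normalize(raw, pd.Series([1.0], index=["s0"]))


class TestSelectExpressed:
    def test_mean_threshold_is_inclusive(self):
        raw = matrix([[199, 200], [200, 200]])  # means 199.5 and 200
        out = nf.select_expressed(raw, min_mean=200)
        assert out.feature_ids == ("f1",)

    def test_length_filter_is_strictly_greater(self):
        raw = matrix([[500, 500], [500, 500]])
        lengths = pd.Series({"f0": 5000, "f1": 5001})
        out = nf.select_expressed(raw, min_mean=200, min_length=5000, lengths=lengths)
        assert out.feature_ids == ("f1",)

    def test_subfamily_whitelist_with_wildcard(self):
        raw = matrix([[500, 500], [500, 500], [500, 500]])
        subf = pd.Series({"f0": "L1HS", "f1": "L1PA7", "f2": "L1ME1"})
        out = nf.select_expressed(
            raw, min_mean=1, subfamilies=("L1HS", "L1PA*"), feature_subfamilies=subf
        )
        assert out.feature_ids == ("f0", "f1")

    def test_length_filter_without_lengths_is_an_error(self):
        with pytest.raises(ValueError, match="lengths"):
            nf.select_expressed(matrix([[1, 1]]), min_length=5000)


class TestMillidivSummary:
    @staticmethod
    def locus(i, subfam, md):
        return L1Locus(
            GenomicInterval("chr1", 1000 * i, 1000 * i + 900, ".", f"l{i}"), subfam, md
        )

    def test_single_locus_mean(self):
        loci = [self.locus(0, "L1HS", 12.5)]
        expressed = nf.ExpressedSet(("l0",), 200)
        out = nf.millidiv_summary(loci, expressed)
        assert out.loc[0, "mean_millidiv_all"] == 12.5
        assert out.loc[0, "mean_millidiv_expressed"] == 12.5

    def test_two_loci_average_and_strata(self):
        loci = [self.locus(0, "L1PA3", 10.0), self.locus(1, "L1PA3", 20.0)]
        out = nf.millidiv_summary(loci, nf.ExpressedSet(("l0",), 200))
        assert out.loc[0, "mean_millidiv_all"] == 15.0
        assert out.loc[0, "mean_millidiv_expressed"] == 10.0  # expressed subset younger

    def test_expressed_subset_with_lower_values_has_lower_mean(self):
        # simulator couples low MilliDiv to high baseline expression, so the
        # expressed stratum is younger overall than the full annotation
        from l1locus import synthetic_data as sim

        cfg = sim.SimulationConfig(seed=13, n_genes=80, n_l1=200)
        genes, l1s = sim.simulate_annotation(cfg)
        _, counts_l1, _, _ = sim.simulate_counts(cfg, genes, l1s)
        expressed = nf.select_expressed(counts_l1, min_mean=200)
        out = nf.millidiv_summary(l1s, expressed)
        assert 0 < len(expressed) < len(l1s)
        overall_all = (out["mean_millidiv_all"] * out["n_all"]).sum() / out["n_all"].sum()
        with_expr = out[out["n_expressed"] > 0]
        overall_expr = (
            with_expr["mean_millidiv_expressed"] * with_expr["n_expressed"]
        ).sum() / with_expr["n_expressed"].sum()
        assert overall_expr < overall_all


class TestRetainedIntronFilter:
    @staticmethod
    def record(ratio=0.1, depth=3.0, warn="-", overlap=False):
        return {
            "chrom": "chr1", "start": 0, "end": 100, "name": "i",
            "IRratio": ratio, "IntronDepth": depth, "Warnings": warn,
            "overlaps_known_feature": overlap,
        }

    def test_inclusive_boundaries_retained(self):
        df = pd.DataFrame([self.record()])
        assert len(nf.filter_retained_introns(df)) == 1

    @pytest.mark.parametrize(
        "rec",
        [
            {"ratio": 0.09},
            {"depth": 2.9},
            {"warn": "LowCover"},
            {"overlap": True},
        ],
    )
    def test_each_condition_excludes(self, rec):
        df = pd.DataFrame([self.record(**{k: v for k, v in rec.items()})])
        assert len(nf.filter_retained_introns(df)) == 0
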