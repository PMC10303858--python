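"""Scale-regions profile matrices vs a per-base brute-force binning oracle."""

import numpy as np
import pandas as pd
import pytest

from l1locus import signal_profiles as sp
from l1locus import synthetic_data as sim
from l1locus.formats_io import GenomicInterval as GI


def track_from_values(values, chrom="chr1", start=0):
    """One run per base — the most granular possible track."""
    rows = [(chrom, start + i, start + i + 1, float(v)) for i, v in enumerate(values)]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def brute_profile_row(values, genome_start, region, flank, body_bins, flank_bin_size):
    """Per-base oracle: distribute each base's signal across fractional bins."""
    nf = flank // flank_bin_size
    edges = np.concatenate([
        np.linspace(region.start - flank, region.start, nf + 1)[:-1],
        np.linspace(region.start, region.end, body_bins + 1)[:-1],
        np.linspace(region.end, region.end + flank, nf + 1),
    ])
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    for i, v in enumerate(values):
        base_s, base_e = genome_start + i, genome_start + i + 1
        for k in range(n_bins):
            ov = max(0.0, min(base_e, edges[k + 1]) - max(base_s, edges[k]))
            sums[k] += v * ov
    widths = np.diff(edges)
    row = sums / widths
    return row[::-1] if region.strand == "-" else row


class TestProfileMatrix:
    def test_constant_track_gives_constant_matrix(self):
        track = pd.DataFrame([("chr1", 0, 100_000, 2.5)],
                             columns=["chrom", "start", "end", "value"])
        regions = [GI("chr1", 20_000, 26_000, "+", "a"),
                   GI("chr1", 50_000, 53_333, "-", "b")]  # heterogeneous lengths
        pm = sp.profile_matrix(track, regions, flank=5000, body_bins=60, flank_bin_size=50)
        assert np.allclose(pm.values, 2.5)
        # mass conservation: the mean profile is flat despite length differences
        assert np.allclose(sp.mean_profile(pm), 2.5)

    def test_minus_strand_reverses_orientation(self):
        # signal only in the genomic left flank of a minus-strand region
        # -> appears in the downstream (right) bins of the profile
        track = pd.DataFrame([("chr1", 9_000, 10_000, 4.0)],
                             columns=["chrom", "start", "end", "value"])
        region = GI("chr1", 10_000, 16_000, "-", "r")
        pm = sp.profile_matrix(track, [region], flank=1000, body_bins=10, flank_bin_size=100)
        nf = pm.n_flank_bins
        assert pm.values[0, :nf].sum() == 0.0
        assert pm.values[0, -nf:].sum() > 0.0

    def test_single_impulse_matches_per_base_oracle(self, rng):
        values = np.zeros(400)
        values[137] = 7.0
        track = track_from_values(values, start=1000)
        region = GI("chr1", 1100, 1250, "+", "r")
        pm = sp.profile_matrix(track, [region], flank=100, body_bins=7, flank_bin_size=20)
        oracle = brute_profile_row(values, 1000, region, 100, 7, 20)
        assert np.allclose(pm.values[0], oracle)

    def test_random_track_matches_oracle_both_strands(self, rng):
        values = rng.uniform(0, 5, size=600)
        track = track_from_values(values, start=2000)
        for strand in "+-":
            region = GI("chr1", 2150, 2477, strand, "r")  # non-divisible body length
            pm = sp.profile_matrix(track, [region], flank=120, body_bins=13,
                                   flank_bin_size=30)
            oracle = brute_profile_row(values, 2000, region, 120, 13, 30)
            assert np.allclose(pm.values[0], oracle)

    def test_region_beyond_track_coverage_gets_zeros(self):
        track = pd.DataFrame([("chr1", 0, 1_000, 3.0)],
                             columns=["chrom", "start", "end", "value"])
        region = GI("chr1", 50_000, 56_000, "+", "r")
        pm = sp.profile_matrix(track, [region], flank=1000, body_bins=10, flank_bin_size=100)
        assert np.allclose(pm.values, 0.0)

    def test_strand_mirror_invariance(self, rng):
        # mirroring the genome (coordinates and strands) preserves the profile
        L = 30_000
        values = rng.uniform(0, 3, size=100)
        starts = np.sort(rng.choice(np.arange(0, L - 100, 100), size=100, replace=False))
        track = pd.DataFrame(
            [("chr1", int(s), int(s) + 100, float(v)) for s, v in zip(starts, values)],
            columns=["chrom", "start", "end", "value"],
        )
        region = GI("chr1", 12_000, 18_000, "+", "r")
        mirrored_track = pd.DataFrame(
            [("chr1", L - e, L - s, v) for _, s, e, v in track.itertuples(index=False)],
            columns=["chrom", "start", "end", "value"],
        ).sort_values("start").reset_index(drop=True)
        mirrored_region = GI("chr1", L - region.end, L - region.start, "-", "r")
        pm = sp.profile_matrix(track, [region], flank=2000, body_bins=12, flank_bin_size=100)
        pm_m = sp.profile_matrix(mirrored_track, [mirrored_region], flank=2000,
                                 body_bins=12, flank_bin_size=100)
        assert np.allclose(pm.values, pm_m.values)


class TestMeanProfile:
    def test_single_region_is_identity(self, rng):
        values = rng.uniform(0, 2, size=300)
        track = track_from_values(values)
        pm = sp.profile_matrix(track, [GI("chr1", 100, 200, "+", "r")],
                               flank=50, body_bins=5, flank_bin_size=10)
        assert np.allclose(sp.mean_profile(pm), pm.values[0])

    def test_two_constant_regions_average(self):
        track = pd.DataFrame(
            [("chr1", 0, 50_000, 1.0), ("chr1", 50_000, 100_000, 3.0)],
            columns=["chrom", "start", "end", "value"],
        )
        regions = [GI("chr1", 20_000, 26_000, "+", "a"), GI("chr1", 70_000, 76_000, "+", "b")]
        pm = sp.profile_matrix(track, regions, flank=1000, body_bins=10, flank_bin_size=100)
        assert np.allclose(sp.mean_profile(pm), 2.0)


class TestSimulatedTracks:
    def test_noiseless_track_has_exact_levels(self):
        regions = [GI("chr1", 10_000, 16_000, "+", "a")]
        track = sim.simulate_signal_track(regions, 50_000, enrich_level=5.0,
                                          background_level=1.0, noise=0.0, seed=0)
        pm = sp.profile_matrix(track, regions, flank=5000, body_bins=60, flank_bin_size=50)
        nf = pm.n_flank_bins
        assert np.allclose(pm.values[0, nf:-nf], 5.0)
        assert np.allclose(pm.values[0, :nf], 1.0)

    def test_enriched_body_exceeds_flanks_with_noise(self):
        regions = [GI("chr1", 10_000 + 30_000 * i, 16_000 + 30_000 * i, "+", f"r{i}")
                   for i in range(5)]
        track = sim.simulate_signal_track(regions, 200_000, enrich_level=5.0,
                                          background_level=1.0, noise=0.5, seed=3)
        pm = sp.profile_matrix(track, regions, flank=5000, body_bins=60, flank_bin_size=50)
        prof = sp.mean_profile(pm)
        nf = pm.n_flank_bins
        assert prof[nf:-nf].mean() > prof[:nf].mean()

    def test_region_outside_genome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sim.simulate_signal_track([GI("chr1", 0, 60_000)], 50_000, 5.0, 1.0)

    def test_seeded_determinism(self):
        regions = [GI("chr1", 1_000, 7_000)]
        a = sim.simulate_signal_track(regions, 20_000, 5.0, 1.0, noise=1.0, seed=4)
        b = sim.simulate_signal_track(regions, 20_000, 5.0, 1.0, noise=1.0, seed=4)
        pd.testing.assert_frame_equal(a, b)
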