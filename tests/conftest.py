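"""Shared fixtures and independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from l1locus.formats_io import GenomicInterval


# ---------------------------------------------------------------------------
# Per-base brute-force oracles for interval arithmetic (independent of the
# sweep implementation: they materialize base-level membership sets).
# ---------------------------------------------------------------------------


def base_set(intervals) -> set:
    return {(iv.chrom, p) for iv in intervals for p in range(iv.start, iv.end)}


def brute_subtract(a, b) -> set:
    return base_set(a) - base_set(b)


def brute_overlaps(iv, others) -> list:
    mine = {(iv.chrom, p) for p in range(iv.start, iv.end)}
    return sorted(
        o.id for o in others if mine & {(o.chrom, p) for p in range(o.start, o.end)}
    )


def random_intervals(rng, n, max_coord=2000, chroms=("chr1", "chr2"), prefix="iv"):
    out = []
    for i in range(n):
        start = int(rng.integers(0, max_coord - 1))
        end = int(rng.integers(start + 1, min(start + 200, max_coord) + 1))
        out.append(
            GenomicInterval(chroms[int(rng.integers(0, len(chroms)))], start, end,
                            ".", f"{prefix}_{i}")
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_simulation():
    """One small simulated dataset shared by read-only tests."""
    from l1locus import synthetic_data as sim

    cfg = sim.SimulationConfig(seed=7, n_genes=60, n_l1=40)
    genes, l1s = sim.simulate_annotation(cfg)
    counts_genes, counts_l1, sheet, truth = sim.simulate_counts(cfg, genes, l1s)
    return cfg, genes, l1s, counts_genes, counts_l1, sheet, truth
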