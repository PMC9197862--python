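"""Shared fixtures: per-base boolean-array oracles and small planted worlds."""

from __future__ import annotations

import numpy as np
import pytest

from regulome.core_io import GenomicInterval
from regulome.synthetic_data import SimulationConfig, make_genome_and_genes


def bitmap(intervals, chrom_sizes):
    """Per-base boolean occupancy arrays, one per chromosome."""
    arrays = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    for iv in intervals:
        arrays[iv.chrom][iv.start : iv.end] = True
    return arrays


def bitmap_covered_bp(intervals, chrom_sizes):
    return sum(int(a.sum()) for a in bitmap(intervals, chrom_sizes).values())


def bitmap_jaccard(set_a, set_b, chrom_sizes):
    a = bitmap(set_a, chrom_sizes)
    b = bitmap(set_b, chrom_sizes)
    inter = sum(int((a[c] & b[c]).sum()) for c in chrom_sizes)
    union = sum(int((a[c] | b[c]).sum()) for c in chrom_sizes)
    return inter / union if union else float("nan")


def random_intervals(rng, n, chrom_sizes, max_len=500):
    out = []
    chroms = list(chrom_sizes)
    for _ in range(n):
        c = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_sizes[c] - 1))
        length = int(rng.integers(1, min(max_len, chrom_sizes[c] - start) + 1))
        out.append(GenomicInterval(c, start, start + length))
    return out


@pytest.fixture(scope="session")
def oracle():
    """Bundle of per-base brute-force oracles."""

    class Oracle:
        bitmap = staticmethod(bitmap)
        covered_bp = staticmethod(bitmap_covered_bp)
        jaccard = staticmethod(bitmap_jaccard)
        random_intervals = staticmethod(random_intervals)

    return Oracle


@pytest.fixture(scope="session")
def tiny_config():
    """A small, fast world for structural tests."""
    return SimulationConfig(
        seed=7,
        n_chroms=2,
        chrom_length_bp=400_000,
        n_genes=60,
        n_elements=300,
        n_tissues=5,
        specific_weight=0.9,
        n_tfs=9,
        n_modules=3,
        sites_per_module=60,
        n_conservation_peaks=100,
        n_fragments=2_000,
        n_upstream_tfs=15,
        n_mirnas=8,
        n_target_tfs=20,
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_config):
    return make_genome_and_genes(tiny_config)


@pytest.fixture(scope="session")
def default_config():
    """The stated world at full scale (used by recovery experiments)."""
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_genome(default_config):
    return make_genome_and_genes(default_config)
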