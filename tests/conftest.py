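import numpy as np
import pytest

from germcomp.core import GenomicInterval
from germcomp.synthetic import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def sim_config():
    """Default study conditions; seed 7 exercises the replicate-noise tails."""
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(sim_config):
    return generate_dataset(sim_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_intervals(rng, n, chrom="chr1", max_pos=10_000, max_len=400):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


# ------------------------------------------------------- brute-force oracles

def brute_merge(intervals, gap_bp):
    """Transitive-closure merge via union-find; independent of the sweep."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def gap(a, b):
        if a.chrom != b.chrom:
            return float("inf")
        if a.start < b.end and b.start < a.end:
            return 0
        return max(a.start, b.start) - min(a.end, b.end)

    for i in range(n):
        for j in range(i + 1, n):
            if gap(intervals[i], intervals[j]) <= gap_bp:
                parent[find(i)] = find(j)
    groups = {}
    for i, iv in enumerate(intervals):
        groups.setdefault(find(i), []).append(iv)
    merged = [
        GenomicInterval(g[0].chrom, min(iv.start for iv in g),
                        max(iv.end for iv in g))
        for g in groups.values()
    ]
    return sorted(merged)


def brute_subtract(intervals, masks):
    """Per-base set subtraction."""
    mask_bases = {}
    for m in masks:
        mask_bases.setdefault(m.chrom, set()).update(range(m.start, m.end))
    out_bases = {}
    for iv in intervals:
        bases = set(range(iv.start, iv.end)) - mask_bases.get(iv.chrom, set())
        out_bases.setdefault(iv.chrom, set()).update(bases)
    return {c: b for c, b in out_bases.items() if b}


def bases_of(intervals):
    out = {}
    for iv in intervals:
        out.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    return out


def brute_interval_gap(a, b):
    """Number of bases strictly between two intervals (0 if overlapping)."""
    if a.chrom != b.chrom:
        return float("inf")
    if a.start < b.end and b.start < a.end:
        return 0
    lo, hi = min(a.end, b.end), max(a.start, b.start)
    return len(range(lo, hi))


def brute_point_gap(iv, chrom, pos):
    if iv.chrom != chrom:
        return float("inf")
    return min(abs(b - pos) for b in range(iv.start, iv.end))
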