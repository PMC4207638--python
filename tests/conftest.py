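import numpy as np
import pytest

from equicnv import SampleInfo, build_genome, design_probe_map


@pytest.fixture(scope="session")
def toy_genome():
    return build_genome(preset="toy")


@pytest.fixture(scope="session")
def toy_probe_map(toy_genome):
    return design_probe_map(toy_genome, seed=1)


@pytest.fixture(scope="session")
def exact_probe_map(toy_genome):
    """Jitter-free map: gaps are exactly the configured spacings."""
    return design_probe_map(toy_genome, jitter_fraction=0.0, seed=0)


@pytest.fixture
def samples4():
    return [
        SampleInfo("s1", breed="Exmoor", tissue="blood", sex="F"),
        SampleInfo("s2", breed="Exmoor", tissue="hair", sex="M"),
        SampleInfo("s3", breed="Friesian", tissue="blood", sex="F"),
        SampleInfo("s4", breed="Friesian", tissue="hair", sex="M"),
    ]


def brute_force_merge(intervals):
    """Transitive-closure merge oracle via union-find on the pairwise relation.

    ``intervals`` is a list of (chrom, start, end[, payload...]) tuples;
    returns sorted (chrom, start, end, member_index_set) groups. Two
    intervals relate iff same chromosome and (overlap >= 1 base or one's end
    equals the other's start).
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        ci, si, ei = intervals[i][:3]
        for j in range(i + 1, n):
            cj, sj, ej = intervals[j][:3]
            if ci != cj:
                continue
            overlap = si <= ej and sj <= ei
            adjacent = ei == sj or ej == si
            if overlap or adjacent:
                union(i, j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    out = []
    for members in groups.values():
        chrom = intervals[min(members)][0]
        start = min(intervals[i][1] for i in members)
        end = max(intervals[i][2] for i in members)
        out.append((chrom, start, end, frozenset(members)))
    return sorted(out, key=lambda g: (g[0], g[1], g[2]))


def brute_force_calls(values, threshold=0.5, min_probes=5):
    """Enumerate all maximal qualifying runs in a single-chromosome profile.

    Independent of the caller: checks every (i, j) window for all-beyond-
    threshold same-sign values and keeps the maximal ones.
    """
    n = len(values)
    qualifying = []
    for i in range(n):
        for j in range(i + min_probes - 1, n):
            window = values[i : j + 1]
            if all(v > threshold for v in window) or all(v < -threshold for v in window):
                qualifying.append((i, j))
    maximal = [
        (i, j)
        for i, j in qualifying
        if not any((a <= i and j <= b and (a, b) != (i, j)) for a, b in qualifying)
    ]
    return sorted(maximal)


@pytest.fixture
def random_intervals():
    def make(rng, n, chroms=("chr1", "chr2"), span=1000):
        out = []
        for _ in range(n):
            c = chroms[int(rng.integers(len(chroms)))]
            s = int(rng.integers(1, span))
            e = s + int(rng.integers(0, span // 4))
            out.append((c, s, e))
        return out

    return make
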