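import numpy as np
import pytest

import psimap as pm


@pytest.fixture
def genome():
    return pm.GenomeTable((("chr1", 1_000_000), ("chr2", 500_000)))


def make_region(region_id, chrom, start, end, type_codes=(1,), element_ids=None):
    if element_ids is None:
        element_ids = frozenset({f"{region_id}_e{i}" for i in range(len(type_codes))})
    return pm.PSIRegion(region_id, chrom, start, end,
                        frozenset(element_ids), frozenset(type_codes))


def make_record(chrom, pos, trait_id="t1", score=1e-10, variant_id=None, lead_id=None):
    return pm.GWASRecord(variant_id, chrom, pos, trait_id, score, lead_id)


def union_oracle(intervals, chrom_len):
    """Base-array union oracle: mark covered bases, extract maximal runs.

    Abutting intervals produce one run here, so this oracle checks covered
    bases, not region boundaries; use components_oracle for those.
    """
    cov = np.zeros(chrom_len + 1, dtype=np.int8)
    for s, e in intervals:
        cov[s:e] = 1
    padded = np.concatenate([[0], cov, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def components_oracle(intervals):
    """Brute-force union-find over pairwise overlap (shared >= 1 base,
    half-open): the connected components' extents, sorted. Quadratic and
    independent of the sweep implementation."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        si, ei = intervals[i]
        for j in range(i + 1, n):
            sj, ej = intervals[j]
            if si < ej and sj < ei:  # strict: abutting does not connect
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        root = find(i)
        s, e = intervals[i]
        if root in comps:
            cs, ce = comps[root]
            comps[root] = (min(cs, s), max(ce, e))
        else:
            comps[root] = (s, e)
    return sorted(comps.values())


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """A written default synthetic bundle (theta = 1, seed fixed)."""
    out = tmp_path_factory.mktemp("bundle")
    config = pm.default_config(seed=11)
    truth = pm.end_to_end_fixture(config, out)
    return out, config, truth
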