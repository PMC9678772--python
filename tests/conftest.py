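import numpy as np
import pytest

from chromcoloc import Genome, IntervalSet


@pytest.fixture
def toy_genome():
    return Genome({"chr1": 10_000, "chr2": 8_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_interval_set(rng, genome, n, max_len=300):
    """Random genome-bound intervals (may overlap each other)."""
    chroms = list(genome.chrom_sizes)
    cs, ss, es = [], [], []
    for _ in range(n):
        c = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, genome.size(c) - length + 1))
        cs.append(c)
        ss.append(start)
        es.append(start + length)
    return IntervalSet.from_arrays(cs, ss, es, genome=genome)


def bitvector_union(iset, genome):
    """Brute-force base-wise union; returns dict chrom -> boolean coverage."""
    cover = {c: np.zeros(genome.size(c), dtype=bool)
             for c in genome.chrom_sizes}
    for iv in iset:
        cover[iv.chrom][iv.start:iv.end] = True
    return cover


def segments_from_bits(cover):
    """Re-segment a boolean coverage vector into (start, end) blocks."""
    out = {}
    for chrom, bits in cover.items():
        padded = np.concatenate([[False], bits, [False]]).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        out[chrom] = list(zip(starts.tolist(), ends.tolist()))
    return out
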