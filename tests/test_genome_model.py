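"""Interval algebra and BED I/O against brute-force oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromcoloc import (Genome, IntervalSet, coverage_bp, flank, merge,
                        nearest_tss_distance, overlap_events, read_bed,
                        write_bed)
from chromcoloc.genome_model import (BedParseError, CoordinateError,
                                     bin_tss_distances, read_chrom_sizes,
                                     write_chrom_sizes)

from conftest import bitvector_union, random_interval_set, segments_from_bits


# -- construction & I/O -------------------------------------------------------

def test_genome_validation():
    with pytest.raises(ValueError):
        Genome({"chr1": 0})
    with pytest.raises(ValueError):
        Genome({})


def test_interval_set_sorted_and_validated(toy_genome):
    s = IntervalSet.from_arrays(["chr1", "chr1"], [100, 50], [200, 80],
                                genome=toy_genome)
    assert [(iv.start, iv.end) for iv in s] == [(50, 80), (100, 200)]
    with pytest.raises(CoordinateError):
        IntervalSet.from_arrays(["chr1"], [200], [100], genome=toy_genome)
    with pytest.raises(CoordinateError):
        IntervalSet.from_arrays(["chr1"], [0], [20_000], genome=toy_genome)
    with pytest.raises(CoordinateError):
        IntervalSet.from_arrays(["chrZ"], [0], [10], genome=toy_genome)


def test_read_bed_sorting_and_errors(tmp_path, toy_genome):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\nchr1\t50\t80\n")
    s = read_bed(p, toy_genome)
    assert [(iv.start, iv.end) for iv in s] == [(50, 80), (100, 200)]

    empty = tmp_path / "empty.bed"
    empty.write_text("")
    assert len(read_bed(empty, toy_genome)) == 0

    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t200\t100\n")
    with pytest.raises(BedParseError, match="bad.bed:1"):
        read_bed(bad, toy_genome)

    bad.write_text("chr1\t100\t200\nchr1\tx\t300\n")
    with pytest.raises(BedParseError, match=":2"):
        read_bed(bad, toy_genome)


def test_bed_round_trip(tmp_path, rng, toy_genome):
    s = random_interval_set(rng, toy_genome, 50)
    p = tmp_path / "rt.bed"
    write_bed(s, p)
    s2 = read_bed(p, toy_genome)
    assert s2.df[["chrom", "start", "end"]].equals(
        s.df[["chrom", "start", "end"]])
    # and the file itself is stable under a second round trip
    p2 = tmp_path / "rt2.bed"
    write_bed(s2, p2)
    assert p.read_bytes() == p2.read_bytes()


def test_bed_preserves_name_score(tmp_path, toy_genome):
    p = tmp_path / "ns.bed"
    p.write_text("chr1\t10\t20\tpeak1\t3.5\nchr1\t30\t40\n")
    s = read_bed(p, toy_genome)
    ivs = list(s)
    assert ivs[0].name == "peak1" and ivs[0].score == 3.5
    assert ivs[1].name is None and ivs[1].score is None


def test_chrom_sizes_round_trip(tmp_path, toy_genome):
    p = tmp_path / "g.sizes"
    write_chrom_sizes(toy_genome, p)
    g2 = read_chrom_sizes(p)
    assert g2.chrom_sizes == toy_genome.chrom_sizes


# -- merge --------------------------------------------------------------------

def test_merge_basics(toy_genome):
    s = IntervalSet.from_arrays(["chr1", "chr1"], [0, 5], [10, 15],
                                genome=toy_genome)
    assert [(iv.start, iv.end) for iv in merge(s)] == [(0, 15)]
    # bookended intervals share 0 nucleotides and stay separate
    s = IntervalSet.from_arrays(["chr1", "chr1"], [0, 10], [10, 20],
                                genome=toy_genome)
    assert [(iv.start, iv.end) for iv in merge(s)] == [(0, 10), (10, 20)]


def test_merge_matches_bitvector_oracle(rng):
    genome = Genome({"chrT": 10_000})
    s = random_interval_set(rng, genome, 200, max_len=120)
    got = {(iv.chrom, iv.start, iv.end) for iv in merge(s)}
    segs = segments_from_bits(bitvector_union(s, genome))
    want = {("chrT", a, b) for a, b in segs["chrT"]}
    assert got == want


def test_merge_idempotent(rng, toy_genome):
    s = random_interval_set(rng, toy_genome, 100)
    m1 = merge(s)
    assert merge(m1) == m1
    assert coverage_bp(m1) == coverage_bp(s)


# -- flank --------------------------------------------------------------------

def test_flank_examples():
    g = Genome({"c": 1000, "d": 100})
    s = IntervalSet.from_arrays(["c"], [100], [200], genome=g)
    assert [(iv.start, iv.end) for iv in flank(s, 50)] == [(50, 250)]
    s = IntervalSet.from_arrays(["d"], [10], [20], genome=g)
    assert [(iv.start, iv.end) for iv in flank(s, 50)] == [(0, 70)]
    assert flank(s, 0) == s
    with pytest.raises(ValueError):
        flank(s, -1)


def test_flank_composition_covers_like_single_flank(rng):
    # on a huge chromosome (no clipping) flank(a)+flank(b) == flank(a+b)
    genome = Genome({"c": 10_000_000})
    cs, ss = ["c"] * 30, (rng.integers(100_000, 9_000_000, 30)).tolist()
    s = IntervalSet.from_arrays(cs, ss, [x + 500 for x in ss], genome=genome)
    two = merge(flank(flank(s, 300), 700))
    one = merge(flank(s, 1000))
    assert two == one


# -- overlap_events -----------------------------------------------------------

def brute_overlap_flags(query, catalog, min_frac, mode="both"):
    flags = []
    for q in query:
        hit = False
        for c in catalog:
            if q.chrom != c.chrom:
                continue
            inter = min(q.end, c.end) - max(q.start, c.start)
            if inter <= 0:
                continue
            ok = True
            if mode in ("both", "query"):
                ok &= inter >= min_frac * q.length
            if mode in ("both", "catalog"):
                ok &= inter >= min_frac * c.length
            if ok:
                hit = True
                break
        flags.append(hit)
    return np.array(flags)


def test_overlap_events_trivial(toy_genome, rng):
    s = random_interval_set(rng, toy_genome, 20)
    n, flags = overlap_events(s, s, 0.1)
    assert n == 20 and flags.all()
    other = IntervalSet.from_arrays(["chr2"], [7000], [7100], genome=toy_genome)
    lone = IntervalSet.from_arrays(["chr1"], [0], [100], genome=toy_genome)
    assert overlap_events(lone, other, 0.1)[0] == 0


def test_overlap_events_ten_percent_boundary():
    g = Genome({"c": 1000})
    q = IntervalSet.from_arrays(["c"], [0], [100], genome=g)
    cat = IntervalSet.from_arrays(["c"], [90], [190], genome=g)
    assert overlap_events(q, cat, 0.1)[0] == 1  # 10 bp = 10% of both
    cat = IntervalSet.from_arrays(["c"], [90], [200], genome=g)  # 110 bp
    assert overlap_events(q, cat, 0.1)[0] == 0  # <10% of catalog side
    assert overlap_events(q, cat, 0.1, mode="query")[0] == 1


@pytest.mark.parametrize("mode", ["both", "query", "catalog"])
@pytest.mark.parametrize("min_frac", [0.0, 0.1, 0.5])
def test_overlap_events_matches_nested_loop_oracle(rng, toy_genome, mode,
                                                   min_frac):
    q = random_interval_set(rng, toy_genome, 120)
    c = random_interval_set(rng, toy_genome, 120)
    n, flags = overlap_events(q, c, min_frac, mode=mode)
    want = brute_overlap_flags(q, c, min_frac, mode)
    assert np.array_equal(flags, want)
    assert n == int(want.sum())


def test_overlap_events_rejects_bad_args(toy_genome, rng):
    s = random_interval_set(rng, toy_genome, 5)
    with pytest.raises(ValueError):
        overlap_events(s, s, 1.5)
    with pytest.raises(ValueError):
        overlap_events(s, s, 0.1, mode="weird")


# -- nearest TSS --------------------------------------------------------------

def test_nearest_tss_examples():
    g = Genome({"c": 10_000})
    peak = IntervalSet.from_arrays(["c"], [100], [200], genome=g)
    tss = IntervalSet.from_arrays(["c"], [150], [151], genome=g)
    assert nearest_tss_distance(peak, tss)[0] == 0
    tss = IntervalSet.from_arrays(["c"], [250], [251], genome=g)
    assert nearest_tss_distance(peak, tss)[0] == 50
    # chromosome without TSS -> inf sentinel
    g2 = Genome({"c": 10_000, "d": 10_000})
    peak = IntervalSet.from_arrays(["d"], [0], [10], genome=g2)
    tss = IntervalSet.from_arrays(["c"], [5], [6], genome=g2)
    assert np.isinf(nearest_tss_distance(peak, tss)[0])


def test_nearest_tss_matches_exhaustive_oracle(rng, toy_genome):
    peaks = random_interval_set(rng, toy_genome, 100)
    tss_pos = random_interval_set(rng, toy_genome, 60, max_len=1)
    got = nearest_tss_distance(peaks, tss_pos)
    tss_list = list(tss_pos)
    for i, p in enumerate(peaks):
        ds = [0 if (t.start < p.end and t.end > p.start)
              else min(abs(p.start - t.end), abs(t.start - p.end))
              for t in tss_list if t.chrom == p.chrom]
        want = min(ds) if ds else np.inf
        assert got[i] == want


def test_tss_distance_bins():
    d = np.array([0, 1, 10_000, 10_001, 100_000, 2_000_000, np.inf])
    b = bin_tss_distances(d)
    assert b["0"] == 1 and b["(0,10kb]"] == 2 and b["(10kb,100kb]"] == 2
    assert b["(100kb,1Mb]"] == 0 and b[">1Mb"] == 2
    assert b.sum() == len(d)


# -- coverage -----------------------------------------------------------------

def test_coverage_examples(toy_genome):
    s = IntervalSet.from_arrays(["chr1", "chr1"], [0, 5], [10, 15],
                                genome=toy_genome)
    assert coverage_bp(s) == 15
    assert coverage_bp(IntervalSet([], genome=toy_genome)) == 0


def test_coverage_matches_bitvector_oracle(rng, toy_genome):
    s = random_interval_set(rng, toy_genome, 150)
    want = sum(int(v.sum()) for v in bitvector_union(s, toy_genome).values())
    assert coverage_bp(s) == want


# -- property tests -----------------------------------------------------------

interval_lists = st.lists(
    st.tuples(st.integers(0, 990), st.integers(1, 200)), min_size=1,
    max_size=40).map(
        lambda pairs: [(s, min(s + l, 1000)) for s, l in pairs])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(interval_lists)
def test_merge_and_coverage_properties(pairs):
    g = Genome({"c": 1000})
    s = IntervalSet.from_arrays(["c"] * len(pairs), [p[0] for p in pairs],
                                [p[1] for p in pairs], genome=g)
    m = merge(s)
    # disjoint, non-touching, order-preserving
    prev_end = -1
    for iv in m:
        assert iv.start > prev_end or prev_end == -1
        assert iv.start >= prev_end
        prev_end = iv.end
    assert merge(m) == m
    assert coverage_bp(m) == coverage_bp(s)
    # coverage monotone under union with another set
    extra = IntervalSet.from_arrays(["c"], [0], [500], genome=g)
    both = IntervalSet(
        __import__("pandas").concat([s.df, extra.df], ignore_index=True),
        genome=g)
    assert coverage_bp(both) >= coverage_bp(s)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(interval_lists, st.integers(0, 3))
def test_min_frac_zero_equals_any_overlap(pairs, shift):
    g = Genome({"c": 1000})
    q = IntervalSet.from_arrays(["c"] * len(pairs), [p[0] for p in pairs],
                                [p[1] for p in pairs], genome=g)
    cat = flank(q, shift)
    n, flags = overlap_events(q, cat, 0.0)
    want = brute_overlap_flags(q, cat, 0.0)
    assert np.array_equal(flags, want) and n == want.sum()
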