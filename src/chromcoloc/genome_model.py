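"""Genome and interval data model with interval algebra and BED-family I/O.

All coordinates are 0-based half-open (BED native). An :class:`IntervalSet`
is a sorted, validated collection of intervals on a :class:`Genome`; the
algebra implemented here (merge, flank, fractional-overlap counting, nearest
distances, base coverage) is the foundation every downstream analysis stage
builds on. Strand is ignored throughout: every comparison in this pipeline
is strand-agnostic.

Merging follows the "at least one shared nucleotide" rule: intervals that
merely touch end-to-start share zero bases and are kept separate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Genome",
    "GenomicInterval",
    "IntervalSet",
    "BedParseError",
    "CoordinateError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "merge",
    "flank",
    "overlap_events",
    "nearest_tss_distance",
    "nearest_gap",
    "bin_tss_distances",
    "coverage_bp",
    "TSS_DISTANCE_BINS",
]


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; carries the line number."""


class CoordinateError(ValueError):
    """Raised when an interval falls outside its chromosome."""


@dataclass(frozen=True)
class Genome:
    """A genome as an ordered mapping of chromosome name to length in bp."""

    chrom_sizes: dict

    def __post_init__(self):
        if not self.chrom_sizes:
            raise ValueError("genome must have at least one chromosome")
        for name, size in self.chrom_sizes.items():
            if int(size) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {size}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def size(self, chrom: str) -> int:
        return int(self.chrom_sizes[chrom])

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    @property
    def chroms(self) -> list:
        return list(self.chrom_sizes)


class GenomicInterval(NamedTuple):
    """A 0-based half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


_COLUMNS = ["chrom", "start", "end", "name", "score"]


class IntervalSet:
    """A sorted collection of :class:`GenomicInterval`, optionally genome-bound.

    Intervals are kept sorted by ``(chrom, start, end)``. When a genome is
    attached, every interval is validated to lie within its chromosome.
    The underlying storage is a pandas DataFrame (``.df``) with columns
    chrom, start, end, name, score.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] | pd.DataFrame,
                 genome: Genome | None = None):
        if isinstance(intervals, pd.DataFrame):
            df = intervals.copy()
            for col in ("name", "score"):
                if col not in df.columns:
                    df[col] = None
            df = df[_COLUMNS]
        else:
            rows = [tuple(iv) for iv in intervals]
            df = pd.DataFrame(rows, columns=_COLUMNS) if rows else pd.DataFrame(
                {c: [] for c in _COLUMNS})
        df["start"] = df["start"].astype(np.int64) if len(df) else df["start"]
        df["end"] = df["end"].astype(np.int64) if len(df) else df["end"]
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort",
                            ignore_index=True)
        self._df = df
        self.genome = genome
        self._validate()

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_arrays(cls, chroms: Sequence[str], starts, ends,
                    genome: Genome | None = None,
                    names=None, scores=None) -> "IntervalSet":
        df = pd.DataFrame({
            "chrom": list(chroms),
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
            "name": list(names) if names is not None else None,
            "score": list(scores) if scores is not None else None,
        })
        return cls(df, genome=genome)

    def _validate(self):
        df = self._df
        if len(df) == 0:
            return
        bad = df["start"] >= df["end"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CoordinateError(
                f"interval with start >= end: "
                f"{df.chrom.iat[i]}:{df.start.iat[i]}-{df.end.iat[i]}")
        if (df["start"] < 0).any():
            raise CoordinateError("negative start coordinate")
        if self.genome is not None:
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in self.genome:
                    raise CoordinateError(f"unknown chromosome {chrom!r}")
                if int(sub["end"].max()) > self.genome.size(chrom):
                    raise CoordinateError(
                        f"interval exceeds chromosome {chrom!r} "
                        f"(length {self.genome.size(chrom)})")

    # -- container protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self._df.itertuples(index=False):
            name = None if pd.isna(row.name) else row.name
            score = None if row.score is None or (
                isinstance(row.score, float) and np.isnan(row.score)) \
                else float(row.score)
            yield GenomicInterval(row.chrom, int(row.start), int(row.end),
                                  name, score)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self._df[["chrom", "start", "end"]]
        b = other._df[["chrom", "start", "end"]]
        return a.equals(b)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals)"

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def chrom_counts(self) -> dict:
        return self._df["chrom"].value_counts().to_dict()

    def by_chrom(self) -> Iterator[tuple]:
        """Yield ``(chrom, starts, ends)`` with numpy arrays sorted by start."""
        for chrom, sub in self._df.groupby("chrom", sort=True):
            yield chrom, sub["start"].to_numpy(), sub["end"].to_numpy()

    def lengths(self) -> np.ndarray:
        return (self._df["end"] - self._df["start"]).to_numpy()


# -- I/O ----------------------------------------------------------------------

def read_chrom_sizes(path) -> Genome:
    """Read a two-column ``chrom.sizes`` TSV (name, length) into a Genome."""
    sizes: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected two columns")
            sizes[fields[0]] = int(fields[1])
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for name, size in genome.chrom_sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_bed(path, genome: Genome | None = None) -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet`.

    Columns 4 and 5 (name, score) are preserved when present; further
    columns are ignored. Malformed lines raise :class:`BedParseError`
    naming the offending line number; coordinates outside the bound
    genome raise :class:`CoordinateError`.
    """
    chroms, starts, ends, names, scores = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})")
            if start < 0:
                raise BedParseError(f"{path}:{lineno}: negative start")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            names.append(fields[3] if len(fields) > 3 else None)
            if len(fields) > 4 and fields[4] not in (".", ""):
                scores.append(float(fields[4]))
            else:
                scores.append(None)
    return IntervalSet.from_arrays(chroms, starts, ends, genome=genome,
                                   names=names, scores=scores)


def write_bed(iset: IntervalSet, path) -> None:
    """Write BED3/BED6 (tab-separated, no header); round-trips coordinates."""
    with open(path, "w") as fh:
        for iv in iset:
            if iv.name is None and iv.score is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.name if iv.name is not None else "."
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")


# -- interval algebra ---------------------------------------------------------

def merge(iset: IntervalSet) -> IntervalSet:
    """Union intervals sharing >= 1 bp into disjoint blocks.

    Bookended intervals (``end == next start``) share zero nucleotides and
    are NOT merged. Name/score annotations are dropped (a merged block has
    no unique annotation).
    """
    chroms, starts, ends = [], [], []
    for chrom, s, e in iset.by_chrom():
        run_end = np.maximum.accumulate(e)
        # new block where this start is >= the running max end of all before it
        is_new = np.ones(len(s), dtype=bool)
        if len(s) > 1:
            is_new[1:] = s[1:] >= run_end[:-1]
        block = np.cumsum(is_new) - 1
        n_blocks = int(block[-1]) + 1
        bs = s[is_new]  # sorted by start, so each block starts at its first interval
        be = np.zeros(n_blocks, dtype=np.int64)
        np.maximum.at(be, block, e)
        chroms.extend([chrom] * n_blocks)
        starts.extend(bs.tolist())
        ends.extend(be.tolist())
    return IntervalSet.from_arrays(chroms, starts, ends, genome=iset.genome)


def flank(iset: IntervalSet, pad: int) -> IntervalSet:
    """Extend every interval by ``pad`` bp on both sides, clipped to the
    chromosome. The result is NOT auto-merged."""
    if pad < 0:
        raise ValueError(f"pad must be >= 0, got {pad}")
    if pad == 0 or len(iset) == 0:
        return IntervalSet(iset.df, genome=iset.genome)
    df = iset.df.copy()
    df["start"] = np.maximum(df["start"] - pad, 0)
    if iset.genome is not None:
        limits = df["chrom"].map(iset.genome.chrom_sizes).to_numpy()
        df["end"] = np.minimum(df["end"] + pad, limits)
    else:
        df["end"] = df["end"] + pad
    return IntervalSet(df, genome=iset.genome)


def _overlap_flags_arrays(qs, qe, cs, ce, crun, min_frac, mode) -> np.ndarray:
    """Vectorized per-query overlap flags on one chromosome.

    ``cs``/``ce`` must be sorted by start with ``crun`` the running maximum
    of ``ce``; the query arrays need no particular order.
    """
    n = len(qs)
    hi = np.searchsorted(cs, qe, side="left")
    lo = np.searchsorted(crun, qs, side="right")
    counts = np.maximum(hi - lo, 0)
    total = int(counts.sum())
    flags = np.zeros(n, dtype=bool)
    if total == 0:
        return flags
    qidx = np.repeat(np.arange(n), counts)
    first = np.repeat(np.cumsum(counts) - counts, counts)
    j = np.arange(total) - first + np.repeat(lo, counts)
    inter = np.minimum(ce[j], qe[qidx]) - np.maximum(cs[j], qs[qidx])
    ok = inter > 0
    if mode in ("both", "query"):
        ok &= inter >= min_frac * (qe[qidx] - qs[qidx])
    if mode in ("both", "catalog"):
        ok &= inter >= min_frac * (ce[j] - cs[j])
    hit = np.bincount(qidx[ok], minlength=n)
    flags[hit > 0] = True
    return flags


def overlap_events(query: IntervalSet, catalog: IntervalSet,
                   min_frac: float = 0.1,
                   mode: str = "both") -> tuple[int, np.ndarray]:
    """Count query intervals colocalizing with the catalog.

    A query interval is flagged when some catalog interval intersects it
    with intersection length ``>= min_frac * len(query)`` and (depending on
    ``mode``) ``>= min_frac * len(catalog)``:

    - ``both`` (default): the fraction must hold on both intervals;
    - ``query``: only on the query interval;
    - ``catalog``: only on the catalog interval.

    With ``min_frac = 0`` the rule degenerates to "any 1-bp overlap".
    Returns ``(count, flags)`` where ``flags`` is a per-query boolean array
    aligned with the sorted order of ``query.df``.
    """
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError(f"min_frac must be in [0, 1], got {min_frac}")
    if mode not in ("both", "query", "catalog"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    flags = np.zeros(len(query), dtype=bool)
    cat = {chrom: (s, e, np.maximum.accumulate(e))
           for chrom, s, e in catalog.by_chrom()}
    offset = 0
    for chrom, qs, qe in query.by_chrom():
        n = len(qs)
        if chrom in cat:
            cs, ce, crun = cat[chrom]
            flags[offset:offset + n] = _overlap_flags_arrays(
                qs, qe, cs, ce, crun, min_frac, mode)
        offset += n
    return int(flags.sum()), flags


def nearest_gap(query: IntervalSet, targets: IntervalSet) -> np.ndarray:
    """Edge-to-edge gap in bp from each query interval to the nearest target
    interval on the same chromosome (0 when they overlap; bookended intervals
    have gap 0). Chromosomes without any target yield ``inf``.

    Output is aligned with the sorted order of ``query.df``.
    """
    out = np.full(len(query), np.inf)
    tgt = {chrom: (s, np.maximum.accumulate(e))
           for chrom, s, e in targets.by_chrom()}
    offset = 0
    for chrom, qs, qe in query.by_chrom():
        n = len(qs)
        if chrom in tgt:
            ts, trun = tgt[chrom]
            idx = np.searchsorted(ts, qe, side="left")
            left = np.full(n, np.inf)
            has_left = idx > 0
            prev_end = trun[np.maximum(idx - 1, 0)]
            # any target starting before q.end and ending past q.start overlaps
            overlap = has_left & (prev_end > qs)
            left[has_left] = qs[has_left] - prev_end[has_left]
            right = np.full(n, np.inf)
            has_right = idx < len(ts)
            right[has_right] = ts[idx[has_right]] - qe[has_right]
            d = np.minimum(left, right)
            d[overlap] = 0.0
            out[offset:offset + n] = np.maximum(d, 0.0)
        offset += n
    return out


def nearest_tss_distance(peaks: IntervalSet, tss: IntervalSet) -> np.ndarray:
    """Unsigned bp distance from each peak to its nearest TSS (1-bp intervals),
    0 when the TSS falls inside the peak, ``inf`` when the chromosome carries
    no TSS. Equidistant ties resolve to the same distance either way."""
    return nearest_gap(peaks, tss)


TSS_DISTANCE_BINS = (0, 10_000, 100_000, 1_000_000)
_BIN_LABELS = ("0", "(0,10kb]", "(10kb,100kb]", "(100kb,1Mb]", ">1Mb")


def bin_tss_distances(distances: np.ndarray) -> pd.Series:
    """Bin TSS distances into {0, (0,10 kb], (10,100 kb], (100 kb,1 Mb], >1 Mb}.

    Returns counts per bin label (infinite distances land in ``>1Mb``).
    """
    d = np.asarray(distances, dtype=float)
    counts = {
        _BIN_LABELS[0]: int((d == 0).sum()),
        _BIN_LABELS[1]: int(((d > 0) & (d <= 10_000)).sum()),
        _BIN_LABELS[2]: int(((d > 10_000) & (d <= 100_000)).sum()),
        _BIN_LABELS[3]: int(((d > 100_000) & (d <= 1_000_000)).sum()),
        _BIN_LABELS[4]: int((d > 1_000_000).sum()),
    }
    return pd.Series(counts)


def coverage_bp(iset: IntervalSet) -> int:
    """Total bases covered by the set (computed after merging)."""
    if len(iset) == 0:
        return 0
    merged = merge(iset)
    return int(merged.lengths().sum())
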