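"""PWM motif scanning and global-control enrichment.

Position frequency matrices (JASPAR text format) are turned into log-odds
position weight matrices and scanned over both strands of interval
sequences. A window is a hit when its log-odds score reaches a configurable
fraction of the maximum (consensus) score. Enrichment of a motif in a query
sequence set against a control set is summarized as the ratio of hit rates
per kb scanned (fold enrichment) with a two-sided binomial p-value using the
control hit probability as the reference.

Hits are counted as total hit windows, not sequences with a hit: a single
peak frequently carries several binding sites for the same factor, and the
window count preserves that signal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from pyfaidx import Fasta
from scipy import stats

from .genome_model import IntervalSet

__all__ = [
    "PWM",
    "MotifHit",
    "MotifEnrichmentResult",
    "read_jaspar",
    "write_jaspar",
    "scan",
    "motif_enrichment",
    "extract_sequences",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class PWM:
    """A position frequency matrix with background model and pseudocount.

    counts: 4 x L non-negative matrix, rows in A, C, G, T order.
    background: base frequencies summing to 1 (default uniform).
    pseudocount: added to every count before normalization (default 0.5).
    """

    motif_id: str
    counts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pseudocount: float = 0.5
    name: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must have 4 rows (A, C, G, T)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every column must have a positive count sum")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x L log2-odds matrix of (pseudocounted) frequencies over
        background."""
        c = self.counts + self.pseudocount
        p = c / c.sum(axis=0, keepdims=True)
        return np.log2(p / self.background[:, None])

    def max_score(self) -> float:
        """Score of the consensus sequence (column-wise maxima)."""
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.log_odds().argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    """A scoring window: 0-based forward-strand start, strand, log-odds."""

    position: int
    strand: str  # '+' or '-'
    score: float


@dataclass
class MotifEnrichmentResult:
    """Query-vs-control enrichment summary for one motif."""

    motif_id: str
    n_hits_query: int
    n_hits_control: int
    rate_query: float  # hits per kb scanned
    rate_control: float
    fold_enrichment: float
    p_value: float
    n_windows_query: int = 0
    n_windows_control: int = 0


# -- JASPAR I/O ---------------------------------------------------------------

def read_jaspar(path) -> list[PWM]:
    """Parse a JASPAR PFM text file (">ID NAME" headers, 4 bracketed count
    rows per record) into PWMs with a uniform background."""
    text = open(path).read()
    if not text.startswith(">"):
        raise ValueError(f"{path}: not a JASPAR file (no '>' header)")
    n_records = sum(1 for line in text.splitlines() if line.startswith(">"))
    try:
        with open(path) as fh:
            records = bio_motifs.parse(fh, "jaspar")
            pwms = [PWM(m.matrix_id or m.name,
                        np.array([list(m.counts[b]) for b in _BASES]),
                        name=m.name or "")
                    for m in records]
    except (ValueError, KeyError) as exc:
        raise ValueError(f"{path}: malformed JASPAR record: {exc}") from exc
    if len(pwms) != n_records:
        raise ValueError(f"{path}: {n_records - len(pwms)} record(s) could "
                         "not be parsed (expected 4 count rows per record)")
    return pwms


def write_jaspar(pwms: list[PWM], path) -> None:
    """Write PWMs in JASPAR PFM text format (round-trips counts exactly)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.name or pwm.motif_id}\n")
            for i, base in enumerate(_BASES):
                row = " ".join(format(v, "g") for v in pwm.counts[i])
                fh.write(f"{base} [ {row} ]\n")


# -- scanning -----------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


def _window_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Scores of all windows; NaN where the window contains a non-ACGT base."""
    L = lom.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    wins = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (wins >= 0).all(axis=1)
    scores = np.full(n, np.nan)
    if valid.any():
        v = wins[valid]
        scores[valid] = lom[v, np.arange(L)].sum(axis=1)
    return scores


def scan(seq: str, pwm: PWM, threshold_frac: float = 0.8) -> list[MotifHit]:
    """Scan both strands of ``seq`` with the PWM log-odds matrix.

    A window is a hit when its score is >= ``threshold_frac`` times the
    consensus (maximum) score. Windows containing N (or any non-ACGT base)
    are skipped. Positions are 0-based on forward coordinates for both
    strands. A sequence shorter than the motif yields no hits.
    """
    lom = pwm.log_odds()
    # reverse-complement matrix: scanning forward codes with it scores the
    # reverse complement of each window under the original matrix
    lom_rc = lom[::-1, ::-1]
    threshold = threshold_frac * pwm.max_score()
    codes = _encode(seq)
    hits: list[MotifHit] = []
    for strand, matrix in (("+", lom), ("-", lom_rc)):
        scores = _window_scores(codes, matrix)
        with np.errstate(invalid="ignore"):
            idx = np.flatnonzero(scores >= threshold)
        hits.extend(MotifHit(int(i), strand, float(scores[i])) for i in idx)
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _count_hits(seqs, pwm: PWM, threshold_frac: float) -> tuple[int, int]:
    """(total hit windows, total valid windows scanned over both strands)."""
    lom = pwm.log_odds()
    lom_rc = lom[::-1, ::-1]
    threshold = threshold_frac * pwm.max_score()
    n_hits = 0
    n_windows = 0
    for seq in seqs:
        codes = _encode(seq)
        for matrix in (lom, lom_rc):
            scores = _window_scores(codes, matrix)
            valid = ~np.isnan(scores)
            n_windows += int(valid.sum())
            with np.errstate(invalid="ignore"):
                n_hits += int((scores >= threshold).sum())
    return n_hits, n_windows


def motif_enrichment(query_seqs, control_seqs, pwms: list[PWM],
                     threshold_frac: float = 0.8
                     ) -> list[MotifEnrichmentResult]:
    """Enrichment of each motif in the query set against the control set.

    Hit rates are hits per kb scanned (both strands); the fold enrichment
    adds a pseudo-hit of 0.5 to each set to avoid division by zero. The
    p-value is a two-sided binomial test of the query hit count given the
    query window count and the control hit probability.
    """
    query_seqs = list(query_seqs)
    control_seqs = list(control_seqs)
    if not query_seqs or not control_seqs:
        raise ValueError("both sequence sets must be non-empty")
    results = []
    for pwm in pwms:
        hq, wq = _count_hits(query_seqs, pwm, threshold_frac)
        hc, wc = _count_hits(control_seqs, pwm, threshold_frac)
        if wq == 0 or wc == 0:
            raise ValueError(f"no scannable windows for motif {pwm.motif_id}")
        rate_q = (hq + 0.5) / (wq / 1000.0)
        rate_c = (hc + 0.5) / (wc / 1000.0)
        fold = rate_q / rate_c
        p0 = min(max((hc + 0.5) / (wc + 0.5), 1e-300), 1.0 - 1e-12)
        p = stats.binomtest(hq, wq, p0, alternative="two-sided").pvalue
        results.append(MotifEnrichmentResult(
            pwm.motif_id, hq, hc, float(rate_q), float(rate_c), float(fold),
            float(min(p, 1.0)), wq, wc))
    return results


def extract_sequences(intervals: IntervalSet, fasta_path, flank: int = 0
                      ) -> list[str]:
    """Uppercase sequences of the intervals (in sorted interval order) from
    an indexed FASTA, with an optional flank clipped to the chromosome."""
    fa = Fasta(str(fasta_path))
    seqs = []
    for iv in intervals:
        if iv.chrom not in fa:
            raise KeyError(f"chromosome {iv.chrom!r} missing from FASTA")
        chrom_len = len(fa[iv.chrom])
        start = max(iv.start - flank, 0)
        end = min(iv.end + flank, chrom_len)
        seqs.append(str(fa[iv.chrom][start:end]).upper())
    return seqs


def results_to_frame(results: list[MotifEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
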