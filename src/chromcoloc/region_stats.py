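"""Genomic-feature annotation of peak sets.

Covers the pairwise Fisher-exact overlap test between two interval sets
(bedtools-`fisher` contingency convention), the feature-class distribution
of a peak set against promoter/enhancer/CTCF/insulator-style annotations,
promoter construction around TSSs, and the fraction of peaks near open
chromatin (ATAC peaks).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import (Genome, IntervalSet, coverage_bp, flank, merge,
                           nearest_gap, overlap_events)

__all__ = [
    "FisherResult",
    "FeatureDistribution",
    "fisher_overlap",
    "fisher_from_table",
    "feature_distribution",
    "make_promoters",
    "open_chromatin_fraction",
]


@dataclass(frozen=True)
class FisherResult:
    """2x2 contingency table and two-tailed Fisher exact test result."""

    n11: int
    n12: int
    n21: int
    n22: int
    odds_ratio: float
    p_two_tailed: float

    @property
    def table(self):
        return np.array([[self.n11, self.n12], [self.n21, self.n22]])


@dataclass(frozen=True)
class FeatureDistribution:
    """Per-feature-class peak fractions, genome fractions and enrichment."""

    table: pd.DataFrame  # index: class; columns below
    # columns: fraction_of_peaks, fraction_of_genome, enrichment_ratio,
    #          n11, n12, n21, n22, odds_ratio, p_two_tailed


def fisher_from_table(n11: int, n12: int, n21: int, n22: int) -> FisherResult:
    """Two-tailed Fisher exact test on an explicit 2x2 table.

    The two-sided p sums hypergeometric probabilities of all tables at
    least as extreme as (no more probable than) the observed one. The odds
    ratio is the sample odds ratio ``n11*n22 / (n12*n21)`` (+inf allowed).
    """
    odds, p = stats.fisher_exact([[n11, n12], [n21, n22]],
                                 alternative="two-sided")
    return FisherResult(int(n11), int(n12), int(n21), int(n22),
                        float(odds), float(p))


def fisher_overlap(a: IntervalSet, b: IntervalSet, genome: Genome,
                   flank_bp: int = 0) -> FisherResult:
    """Fisher exact association between two interval sets.

    ``a`` is flanked by ``flank_bp`` before testing. The contingency table
    follows the bedtools-`fisher` convention: n11 = number of a-intervals
    overlapping b (>= 1 bp), n12 = remaining a, n21 = b-intervals not
    overlapping a, and n22 estimated as ``round(G / mean_len) - n11 - n12 -
    n21`` (floored at 0), where G is the genome length and mean_len the mean
    interval length over both sets. The raw table is carried in the result
    so the estimate can be audited.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("fisher_overlap requires two non-empty sets")
    a_f = flank(a, flank_bp) if flank_bp else a
    n_a_hit, _ = overlap_events(a_f, b, min_frac=0.0)
    n_b_hit, _ = overlap_events(b, a_f, min_frac=0.0)
    n11 = n_a_hit
    n12 = len(a_f) - n_a_hit
    n21 = len(b) - n_b_hit
    mean_len = float(np.concatenate([a_f.lengths(), b.lengths()]).mean())
    n22 = max(0, int(round(genome.total_bp / mean_len)) - n11 - n12 - n21)
    return fisher_from_table(n11, n12, n21, n22)


def feature_distribution(peaks: IntervalSet, features: dict,
                         genome: Genome, flank_bp: int = 0,
                         ) -> FeatureDistribution:
    """Distribution of a peak set over named feature classes.

    For each class: the fraction of (flanked) peaks with >= 1 bp overlap,
    the fraction of the genome covered by the class, their ratio (NaN when
    the class is empty), and a per-class Fisher exact result.
    """
    if len(peaks) == 0:
        raise ValueError("peaks must be non-empty")
    peaks_f = flank(peaks, flank_bp) if flank_bp else peaks
    rows = {}
    for name, feat in features.items():
        if len(feat) == 0:
            rows[name] = dict(fraction_of_peaks=0.0, fraction_of_genome=0.0,
                              enrichment_ratio=np.nan, n11=0, n12=len(peaks_f),
                              n21=0, n22=0, odds_ratio=np.nan,
                              p_two_tailed=np.nan)
            continue
        n_hit, _ = overlap_events(peaks_f, feat, min_frac=0.0)
        frac_peaks = n_hit / len(peaks_f)
        frac_genome = coverage_bp(feat) / genome.total_bp
        ratio = frac_peaks / frac_genome if frac_genome > 0 else np.nan
        fr = fisher_overlap(peaks_f, feat, genome)
        rows[name] = dict(fraction_of_peaks=frac_peaks,
                          fraction_of_genome=frac_genome,
                          enrichment_ratio=ratio,
                          n11=fr.n11, n12=fr.n12, n21=fr.n21, n22=fr.n22,
                          odds_ratio=fr.odds_ratio,
                          p_two_tailed=fr.p_two_tailed)
    table = pd.DataFrame.from_dict(rows, orient="index")
    return FeatureDistribution(table)


def make_promoters(tss: IntervalSet, upstream: int = 5000,
                   downstream: int = 1000) -> IntervalSet:
    """Promoter intervals ``[t - upstream, t + downstream)`` around 1-bp
    TSSs, clipped to the chromosome and merged.

    TSS input carries no strand in this pipeline, so "upstream" means lower
    coordinates; both pads are configurable.
    """
    df = tss.df.copy()
    starts = np.maximum(df["start"].to_numpy() - upstream, 0)
    ends = df["start"].to_numpy() + downstream
    if tss.genome is not None:
        limits = df["chrom"].map(tss.genome.chrom_sizes).to_numpy()
        ends = np.minimum(ends, limits)
    proms = IntervalSet.from_arrays(df["chrom"].tolist(), starts, ends,
                                    genome=tss.genome)
    return merge(proms)


def open_chromatin_fraction(peaks: IntervalSet, atac: IntervalSet,
                            max_dist: int = 10_000) -> float:
    """Fraction of peaks within ``max_dist`` bp of an open-chromatin
    interval (overlap counts as distance 0; the bound is inclusive)."""
    if len(peaks) == 0:
        raise ValueError("peaks must be non-empty")
    if len(atac) == 0:
        return 0.0
    d = nearest_gap(peaks, atac)
    return float((d <= max_dist).mean())
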