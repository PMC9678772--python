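"""Regulatory-element (RE) tables: selection, peak-proximity split, and
covariate comparison.

An RE table is a minimal GeneHancer-like schema (TSV with columns
``re_id, chrom, start, end, gh_score``); pairings live in a second table
(``re_id, gene, pair_score``, the likelihood score of the enhancer-gene
link). The analysis selects REs that pass an element-score threshold and
are paired to at least one differentially expressed gene, splits them by
proximity to a peak set, and checks that the two groups are comparable in
score, length and TSS distance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import Genome, IntervalSet, nearest_gap

__all__ = [
    "RESplit",
    "read_re_table",
    "write_re_table",
    "read_pairs_table",
    "read_gene_list",
    "re_table_to_intervals",
    "select_connected_res",
    "split_by_proximity",
    "compare_covariates",
]

RE_COLUMNS = ["re_id", "chrom", "start", "end", "gh_score"]
PAIR_COLUMNS = ["re_id", "gene", "pair_score"]


@dataclass
class RESplit:
    """Partition of an RE table by proximity to a peak set."""

    with_peaks: pd.DataFrame
    without_peaks: pd.DataFrame
    max_dist: int

    @property
    def n_with(self) -> int:
        return len(self.with_peaks)

    @property
    def n_without(self) -> int:
        return len(self.without_peaks)


# -- I/O ----------------------------------------------------------------------

def read_re_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(RE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"RE table missing columns: {sorted(missing)}")
    if df["re_id"].duplicated().any():
        raise ValueError("re_id values must be unique within an RE table")
    return df[RE_COLUMNS]


def write_re_table(df: pd.DataFrame, path) -> None:
    df[RE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pairs_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    return df[PAIR_COLUMNS]


def read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def re_table_to_intervals(df: pd.DataFrame,
                          genome: Genome | None = None) -> IntervalSet:
    return IntervalSet.from_arrays(df["chrom"].tolist(), df["start"],
                                   df["end"], genome=genome,
                                   names=df["re_id"].tolist(),
                                   scores=df["gh_score"].tolist())


# -- operations ---------------------------------------------------------------

def select_connected_res(res: pd.DataFrame, pairs: pd.DataFrame,
                         de_genes, min_score: float = 0.7) -> pd.DataFrame:
    """REs with element score above ``min_score`` (strict) that are paired
    to at least one differentially expressed gene.

    Gene symbols are compared case-insensitively. Pairs referencing an
    unknown re_id are skipped with a warning. The result is deduplicated by
    re_id and independent of input row order (sorted by re_id).
    """
    de = {g.strip().upper() for g in de_genes}
    known = set(res["re_id"])
    unknown = set(pairs["re_id"]) - known
    if unknown:
        warnings.warn(f"{len(unknown)} pair(s) reference unknown re_id(s); "
                      "skipped", stacklevel=2)
    pairs_ok = pairs[pairs["re_id"].isin(known)
                     & pairs["gene"].str.upper().isin(de)]
    connected = set(pairs_ok["re_id"])
    out = res[(res["gh_score"] > min_score) & res["re_id"].isin(connected)]
    return out.sort_values("re_id", kind="mergesort", ignore_index=True)


def split_by_proximity(res: pd.DataFrame, peaks: IntervalSet,
                       max_dist: int = 10_000,
                       genome: Genome | None = None) -> RESplit:
    """Partition REs into those within ``max_dist`` bp of a peak
    (edge-to-edge gap, overlap = 0, bound inclusive) and the rest."""
    if len(res) == 0:
        return RESplit(res.copy(), res.copy(), max_dist)
    ivs = re_table_to_intervals(res, genome=genome)
    d = nearest_gap(ivs, peaks)
    # nearest_gap output is aligned to the sorted interval order; map back
    order = res.sort_values(["chrom", "start", "end"],
                            kind="mergesort").index.to_numpy()
    near = pd.Series(False, index=res.index)
    near.loc[order] = d <= max_dist
    with_peaks = res[near].reset_index(drop=True)
    without_peaks = res[~near].reset_index(drop=True)
    return RESplit(with_peaks, without_peaks, max_dist)


COVARIATES = ("gh_score", "length", "tss_distance")


def compare_covariates(split: RESplit, tss: IntervalSet,
                       genome: Genome | None = None) -> pd.DataFrame:
    """Compare the two RE groups on element score, length and nearest-TSS
    distance with a two-sided Mann-Whitney U test.

    Returns a DataFrame indexed by covariate with the group medians and
    the p-value. Raises when either group is empty.
    """
    for label, grp in (("with_peaks", split.with_peaks),
                       ("without_peaks", split.without_peaks)):
        if len(grp) == 0:
            raise ValueError(f"group {label!r} is empty")

    def covariate_values(df: pd.DataFrame) -> dict:
        ivs = re_table_to_intervals(df, genome=genome)
        d = nearest_gap(ivs, tss)
        return {
            "gh_score": df["gh_score"].to_numpy(dtype=float),
            "length": (df["end"] - df["start"]).to_numpy(dtype=float),
            "tss_distance": d,
        }

    a = covariate_values(split.with_peaks)
    b = covariate_values(split.without_peaks)
    rows = {}
    for cov in COVARIATES:
        x, y = a[cov], b[cov]
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows[cov] = dict(median_with=float(np.median(x)),
                         median_without=float(np.median(y)),
                         u_stat=float(stat), p_value=float(p))
    return pd.DataFrame.from_dict(rows, orient="index")
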