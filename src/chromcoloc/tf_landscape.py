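"""Transcription-factor landscape over regulatory-element groups.

Given a split of regulatory elements into a peak-associated group and a
background group, this module computes per-TF dual-background enrichment
(chi-square with continuity correction between the two groups, plus an
optional genome-background q-value delegated to the shuffle-null engine),
per-Mb site densities and their ratio, a binary RE x TF presence matrix,
PCA with iterative SVD imputation for masked cells, and hierarchical
clustering of rows/columns (Euclidean for REs, Canberra for TFs, following
the convention that Canberra emphasizes presence/absence differences in
sparse binary profiles).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .enhancer_pairing import RESplit, re_table_to_intervals
from .genome_model import IntervalSet, coverage_bp, overlap_events
from .shuffle_coloc import ShuffleConfig, coloc_enrichment

__all__ = [
    "TFEnrichmentResult",
    "PresenceMatrix",
    "tf_dual_enrichment",
    "select_abundant_tfs",
    "build_presence_matrix",
    "pca_svd_impute",
    "hcluster",
]


@dataclass
class TFEnrichmentResult:
    """Dual-background enrichment record for one TF catalog."""

    tf: str
    n_with: int
    n_without: int
    density_with: float
    density_without: float
    density_ratio: float
    chi2_stat: float
    p_chi2: float
    q_fdr: float
    q_genome: float = np.nan


@dataclass
class PresenceMatrix:
    """Binary RE x TF matrix; NaN cells are masked (missing data)."""

    values: pd.DataFrame  # rows: re_id, cols: tf labels; 0/1 or NaN


def _count_sites_in(intervals: IntervalSet, catalog: IntervalSet) -> int:
    """Number of catalog sites overlapping (>= 1 bp) the interval group."""
    n, _ = overlap_events(catalog, intervals, min_frac=0.0)
    return n


def tf_dual_enrichment(catalogs: dict, split: RESplit,
                       fdr_method: str = "fdr_bh",
                       coloc_cfg: ShuffleConfig | None = None,
                       min_frac_coloc: float = 0.1) -> list[TFEnrichmentResult]:
    """Per-TF enrichment of the peak-associated RE group over the background
    group.

    For each TF the 2x2 table ``[[n_with, |with| - n_with], [n_without,
    |without| - n_without]]`` (REs containing >= 1 TF site) is tested by
    chi-square with Yates continuity correction; q-values are
    Benjamini-Hochberg across TFs by default. Densities are TF sites per
    Mb of each group's merged coverage. When ``coloc_cfg`` is given, a
    genome-background q is attached by running the shuffle-null
    colocalization of the with-peaks REs against the same catalogs.
    """
    if split.n_with == 0 or split.n_without == 0:
        raise ValueError("both RE groups must be non-empty")
    if not catalogs:
        raise ValueError("at least one catalog is required")
    genome = next(iter(catalogs.values())).genome
    ivs_with = re_table_to_intervals(split.with_peaks, genome=genome)
    ivs_without = re_table_to_intervals(split.without_peaks, genome=genome)
    mb_with = coverage_bp(ivs_with) / 1e6
    mb_without = coverage_bp(ivs_without) / 1e6
    if mb_with == 0 or mb_without == 0:
        raise ValueError("an RE group has zero coverage")

    results: list[TFEnrichmentResult] = []
    pvals = []
    for tf, cat in catalogs.items():
        n_with, _ = overlap_events(ivs_with, cat, min_frac=0.0)
        n_without, _ = overlap_events(ivs_without, cat, min_frac=0.0)
        table = np.array([[n_with, split.n_with - n_with],
                          [n_without, split.n_without - n_without]])
        if table[:, 0].sum() in (0, table.sum()) or \
                table[0].sum() == 0 or table[1].sum() == 0:
            chi2, p = 0.0, 1.0  # degenerate margin: no association testable
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        d_with = _count_sites_in(ivs_with, cat) / mb_with
        d_without = _count_sites_in(ivs_without, cat) / mb_without
        ratio = d_with / d_without if d_without > 0 else np.inf
        results.append(TFEnrichmentResult(tf, int(n_with), int(n_without),
                                          float(d_with), float(d_without),
                                          float(ratio), float(chi2), float(p),
                                          np.nan))
        pvals.append(p)
    q = multipletests(pvals, method=fdr_method)[1]
    for res, qv in zip(results, q):
        res.q_fdr = float(max(qv, res.p_chi2))
    if coloc_cfg is not None:
        coloc = coloc_enrichment(ivs_with, catalogs, min_frac_coloc, coloc_cfg)
        by_tf = {r.catalog_name: r.q_by for r in coloc}
        for res in results:
            res.q_genome = by_tf[res.tf]
    return results


def select_abundant_tfs(results: list[TFEnrichmentResult], n_with_total: int,
                        min_fraction_with: float = 0.75) -> list[str]:
    """TFs present in more than ``min_fraction_with`` of the peak-associated
    REs (strict inequality)."""
    if not results:
        raise ValueError("results must be non-empty")
    return [r.tf for r in results
            if r.n_with / n_with_total > min_fraction_with]


def build_presence_matrix(res: pd.DataFrame, catalogs: dict,
                          tfs: list[str]) -> PresenceMatrix:
    """Binary RE x TF presence matrix over the selected TFs.

    A cell is 1 when the TF has >= 1 site overlapping the RE. A cell is
    masked (NaN) when the TF catalog carries no data for the RE's
    chromosome -- absence of evidence rather than evidence of absence.
    Rows that are all zero (over unmasked cells) are excluded; row and
    column labels are ordered lexicographically.
    """
    unknown = set(tfs) - set(catalogs)
    if unknown:
        raise ValueError(f"unknown TF catalog(s): {sorted(unknown)}")
    tfs = sorted(tfs)
    genome = next(iter(catalogs.values())).genome if catalogs else None
    ivs = re_table_to_intervals(res, genome=genome)
    order = res.sort_values(["chrom", "start", "end"],
                            kind="mergesort")["re_id"].tolist()
    mat = pd.DataFrame(index=order, columns=tfs, dtype=float)
    for tf in tfs:
        cat = catalogs[tf]
        cat_chroms = set(cat.df["chrom"].unique())
        _, flags = overlap_events(ivs, cat, min_frac=0.0)
        col = flags.astype(float)
        sorted_chroms = ivs.df["chrom"].to_numpy()
        col[~np.isin(sorted_chroms, list(cat_chroms))] = np.nan
        mat[tf] = col
    keep = (mat == 1).any(axis=1)
    mat = mat[keep]
    mat = mat.sort_index(kind="mergesort")
    return PresenceMatrix(mat)


def pca_svd_impute(matrix: PresenceMatrix | pd.DataFrame, n_components: int,
                   tol: float = 1e-6, max_iter: int = 100):
    """PCA of a (possibly masked) matrix via iterative SVD imputation.

    Columns are centered; missing cells are initialized at the column mean
    and refined by repeatedly reconstructing them from a rank-
    ``n_components`` SVD until the largest absolute change drops below
    ``tol`` (or ``max_iter`` sweeps). On a complete matrix the loop is a
    no-op and the result equals plain centered-SVD PCA.

    Returns ``(scores, loadings, explained_variance)`` as DataFrames /
    Series labeled PC1..PCk, with the sign convention that each component's
    largest-magnitude loading is positive. ``explained_variance`` uses the
    sample (ddof=1) normalization, so at full rank it sums to the total
    column variance.
    """
    df = matrix.values if isinstance(matrix, PresenceMatrix) else matrix
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError("n_components exceeds matrix rank bound")
    miss = np.isnan(X)
    if miss.all(axis=0).any():
        raise ValueError("a column is entirely missing")
    col_mean = np.nanmean(X, axis=0)
    Xf = np.where(miss, col_mean, X)
    if miss.any():
        for _ in range(max_iter):
            mu = Xf.mean(axis=0)
            C = Xf - mu
            U, s, Vt = np.linalg.svd(C, full_matrices=False)
            R = (U[:, :n_components] * s[:n_components]) @ Vt[:n_components] + mu
            delta = np.max(np.abs(Xf[miss] - R[miss]))
            Xf[miss] = R[miss]
            if delta < tol:
                break
    mu = Xf.mean(axis=0)
    C = Xf - mu
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # fix signs: largest-|loading| entry of each component made positive
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    pcs = [f"PC{k + 1}" for k in range(n_components)]
    scores = pd.DataFrame(U * s, index=df.index, columns=pcs)
    loadings = pd.DataFrame(Vt.T, index=df.columns, columns=pcs)
    explained = pd.Series(s ** 2 / max(n - 1, 1), index=pcs,
                          name="explained_variance")
    return scores, loadings, explained


def canberra(x, y) -> float:
    """Canberra distance ``sum |x_i - y_i| / (|x_i| + |y_i|)`` with 0/0
    terms contributing 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    num = np.abs(x - y)
    den = np.abs(x) + np.abs(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / den, 0.0)
    return float(terms.sum())


def hcluster(matrix: PresenceMatrix | pd.DataFrame, axis: str = "rows",
             metric: str = "euclidean", linkage: str = "average"):
    """Agglomerative clustering of matrix rows or columns.

    Returns ``(ordered_labels, linkage_matrix)`` where the linkage matrix
    is in scipy ``hierarchy.linkage`` format and the label order is the
    dendrogram leaf order. Masked cells must be imputed first (use
    :func:`pca_svd_impute` or fill); NaNs raise.
    """
    df = matrix.values if isinstance(matrix, PresenceMatrix) else matrix
    if axis == "cols":
        df = df.T
    elif axis != "rows":
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    if len(df) < 2:
        raise ValueError("need at least 2 items to cluster")
    if metric not in ("euclidean", "canberra"):
        raise ValueError(f"unknown metric {metric!r}")
    X = df.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains masked cells; impute before clustering")
    D = pdist(X, metric=metric)
    Z = hierarchy.linkage(D, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    return [df.index[i] for i in leaves], Z


def results_to_frame(results: list[TFEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
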