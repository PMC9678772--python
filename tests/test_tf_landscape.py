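"""Dual-background TF enrichment, presence matrix, PCA imputation, clustering."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from chromcoloc import (Genome, IntervalSet, build_presence_matrix, hcluster,
                        pca_svd_impute, select_abundant_tfs,
                        tf_dual_enrichment)
from chromcoloc.enhancer_pairing import RESplit
from chromcoloc.tf_landscape import PresenceMatrix, canberra

from conftest import random_interval_set


def yates_chi2(a, b, c, d):
    """Textbook continuity-corrected chi-square for a 2x2 table."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / n
    diff = np.maximum(np.abs(table - expected) - 0.5, 0.0)
    return float((diff ** 2 / expected).sum())


def test_chi2_matches_hand_formula_on_random_tables(rng):
    for _ in range(100):
        t = rng.integers(1, 100, size=4)
        chi2, p, _, _ = stats.chi2_contingency([[t[0], t[1]], [t[2], t[3]]],
                                               correction=True)
        want = yates_chi2(*t)
        assert chi2 == pytest.approx(want, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(want, 1), abs=1e-10)


def test_specific_table_oracle():
    chi2, p, _, _ = stats.chi2_contingency([[90, 27], [300, 552]],
                                           correction=True)
    assert chi2 == pytest.approx(yates_chi2(90, 27, 300, 552), abs=1e-10)
    assert p < 1e-10


def _make_split_and_catalogs(rng, n_with=40, n_without=120,
                             planted=("TF_A", "TF_B")):
    """REs on one chromosome; planted TFs get sites inside most with-group
    REs, null TFs are uniform."""
    g = Genome({"c": 50_000_000})
    rows_w = [(f"W{i:03d}", "c", int(s), int(s) + 1000, 1.0)
              for i, s in enumerate(rng.integers(0, 49_000_000, n_with))]
    rows_o = [(f"O{i:03d}", "c", int(s), int(s) + 1000, 1.0)
              for i, s in enumerate(rng.integers(0, 49_000_000, n_without))]
    with_df = pd.DataFrame(rows_w, columns=["re_id", "chrom", "start", "end",
                                            "gh_score"])
    without_df = pd.DataFrame(rows_o, columns=["re_id", "chrom", "start",
                                               "end", "gh_score"])
    catalogs = {}
    for tf in ("TF_A", "TF_B", "TF_C", "TF_D"):
        if tf in planted:
            # a site inside 90% of with-group REs + uniform background
            inside = [int(s) + 400 for s in with_df["start"]
                      if rng.random() < 0.9]
            bg = rng.integers(0, 49_000_000, 100).tolist()
            starts = inside + bg
        else:
            starts = rng.integers(0, 49_000_000, 200).tolist()
        catalogs[tf] = IntervalSet.from_arrays(
            ["c"] * len(starts), starts, [s + 150 for s in starts], genome=g)
    return RESplit(with_df, without_df, 10_000), catalogs


def test_tf_dual_enrichment_ranks_planted_tfs(rng):
    split, catalogs = _make_split_and_catalogs(rng)
    results = tf_dual_enrichment(catalogs, split)
    by_q = sorted(results, key=lambda r: r.q_fdr)
    assert {by_q[0].tf, by_q[1].tf} == {"TF_A", "TF_B"}
    for r in results:
        assert r.q_fdr >= r.p_chi2
        assert r.density_with >= 0 and r.density_without >= 0
        if r.tf in ("TF_A", "TF_B"):
            assert r.density_ratio > 1


def test_tf_everywhere_gives_p_one(rng):
    split, catalogs = _make_split_and_catalogs(rng, planted=())
    g = next(iter(catalogs.values())).genome
    whole = IntervalSet.from_arrays(["c"], [0], [50_000_000], genome=g)
    results = tf_dual_enrichment({"ALL": whole}, split)
    assert results[0].p_chi2 == 1.0


def test_density_arithmetic():
    g = Genome({"c": 10_000_000})
    with_df = pd.DataFrame([("W0", "c", 0, 500_000, 1.0)],
                           columns=["re_id", "chrom", "start", "end",
                                    "gh_score"])
    without_df = pd.DataFrame([("O0", "c", 9_000_000, 9_500_000, 1.0)],
                              columns=["re_id", "chrom", "start", "end",
                                       "gh_score"])
    starts = [100, 1000, 10_000, 100_000, 400_000]
    cat = IntervalSet.from_arrays(["c"] * 5, starts,
                                  [s + 100 for s in starts], genome=g)
    res = tf_dual_enrichment({"T": cat}, RESplit(with_df, without_df, 0))
    assert res[0].density_with == pytest.approx(10.0)  # 5 sites / 0.5 Mb


def test_select_abundant_tfs_boundary():
    from chromcoloc.tf_landscape import TFEnrichmentResult

    def rec(tf, n):
        return TFEnrichmentResult(tf, n, 0, 0, 0, 1, 0, 1, 1)

    picked = select_abundant_tfs([rec("keep", 88), rec("drop", 87)], 117)
    assert picked == ["keep"]  # 88/117 = 0.752 > 0.75 > 87/117


# -- presence matrix ----------------------------------------------------------

def test_presence_matrix_matches_nested_loop(rng):
    g = Genome({"c": 1_000_000, "d": 1_000_000})
    res = pd.DataFrame(
        [(f"R{i:02d}", "c" if i % 2 else "d", i * 40_000, i * 40_000 + 2_000,
          1.0) for i in range(20)],
        columns=["re_id", "chrom", "start", "end", "gh_score"])
    catalogs = {f"T{j}": random_interval_set(rng, g, 30) for j in range(6)}
    pm = build_presence_matrix(res, catalogs, list(catalogs))
    for re_row in res.itertuples(index=False):
        want = {}
        for tf, cat in catalogs.items():
            hits = any(c.chrom == re_row.chrom and c.start < re_row.end
                       and c.end > re_row.start for c in cat)
            want[tf] = 1.0 if hits else 0.0
        if all(v == 0 for v in want.values()):
            assert re_row.re_id not in pm.values.index
        else:
            got = pm.values.loc[re_row.re_id]
            for tf in catalogs:
                assert got[tf] == want[tf]
    assert list(pm.values.columns) == sorted(catalogs)


def test_presence_matrix_masks_missing_chromosomes():
    g = Genome({"c": 100_000, "d": 100_000})
    res = pd.DataFrame([("R1", "c", 0, 1000, 1.0), ("R2", "d", 0, 1000, 1.0)],
                       columns=["re_id", "chrom", "start", "end", "gh_score"])
    cat_c = IntervalSet.from_arrays(["c"], [100], [200], genome=g)
    cat_both = IntervalSet.from_arrays(["c", "d"], [100, 100], [200, 200],
                                       genome=g)
    pm = build_presence_matrix(res, {"ONLY_C": cat_c, "BOTH": cat_both},
                               ["ONLY_C", "BOTH"])
    assert pm.values.loc["R1", "ONLY_C"] == 1.0
    assert np.isnan(pm.values.loc["R2", "ONLY_C"])  # no data for chrom d
    assert pm.values.loc["R2", "BOTH"] == 1.0


# -- PCA ----------------------------------------------------------------------

def test_pca_complete_matrix_equals_sklearn(rng):
    from sklearn.decomposition import PCA

    X = pd.DataFrame(rng.normal(size=(25, 6)))
    scores, loadings, explained = pca_svd_impute(X, 3)
    sk = PCA(n_components=3).fit(X.to_numpy())
    assert np.allclose(np.abs(scores.to_numpy()),
                       np.abs(sk.transform(X.to_numpy())), atol=1e-8)
    assert np.allclose(explained.to_numpy(), sk.explained_variance_, atol=1e-8)
    # orthogonality of score columns
    gram = scores.to_numpy().T @ scores.to_numpy()
    assert np.allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
    # sign convention: largest-|loading| entry positive
    for col in loadings.columns:
        v = loadings[col].to_numpy()
        assert v[np.argmax(np.abs(v))] > 0


def test_pca_explained_variance_conserved_at_full_rank(rng):
    X = pd.DataFrame(rng.normal(size=(15, 4)))
    _, _, explained = pca_svd_impute(X, 4)
    total = X.var(ddof=1).sum()
    assert explained.sum() == pytest.approx(total)
    assert np.all(np.diff(explained.to_numpy()) <= 1e-12)


def test_pca_recovers_masked_rank_one_matrix(rng):
    u = rng.normal(size=40)
    v = rng.normal(size=8)
    X = np.outer(u, v)
    mask = rng.random(X.shape) < 0.1
    Xm = X.copy()
    Xm[mask] = np.nan
    scores, loadings, _ = pca_svd_impute(pd.DataFrame(Xm), 1)
    recon = scores.to_numpy() @ loadings.to_numpy().T + np.nanmean(Xm, axis=0)
    rmse = np.sqrt(np.mean((recon[mask] - X[mask]) ** 2))
    assert rmse < 0.05


def test_pca_rejects_all_missing_column():
    X = pd.DataFrame(np.ones((5, 3)))
    X.iloc[:, 1] = np.nan
    with pytest.raises(ValueError, match="missing"):
        pca_svd_impute(X, 1)


# -- clustering ---------------------------------------------------------------

def test_canberra_closed_forms():
    assert canberra([1, 0], [0, 1]) == pytest.approx(2.0)
    assert canberra([0, 0], [0, 0]) == 0.0
    assert canberra([1, 1], [1, 1]) == 0.0
    # scipy agreement on random binary vectors
    rng = np.random.default_rng(0)
    for _ in range(100):
        x, y = rng.integers(0, 2, 10), rng.integers(0, 2, 10)
        assert canberra(x, y) == pytest.approx(
            pdist(np.vstack([x, y]), metric="canberra")[0])


def test_identical_rows_merge_first(rng):
    X = pd.DataFrame(rng.normal(size=(6, 4)),
                     index=[f"r{i}" for i in range(6)])
    X.iloc[5] = X.iloc[2]
    order, Z = hcluster(X, axis="rows", metric="euclidean")
    assert Z[0, 2] == 0.0  # first merge at distance 0
    merged = {int(Z[0, 0]), int(Z[0, 1])}
    assert merged == {2, 5}


def brute_force_average_linkage(X, metric):
    """Naive agglomerative average linkage; returns merge heights."""
    clusters = {i: [i] for i in range(len(X))}
    D = squareform(pdist(X, metric=metric))
    heights = []
    next_id = len(X)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([D[i, j] for i in clusters[a]
                             for j in clusters[b]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


@pytest.mark.parametrize("metric", ["euclidean", "canberra"])
def test_hcluster_matches_brute_force_oracle(rng, metric):
    X = pd.DataFrame(rng.random(size=(12, 5)))
    _, Z = hcluster(X, axis="rows", metric=metric)
    want = brute_force_average_linkage(X.to_numpy(), metric)
    assert np.allclose(np.sort(Z[:, 2]), np.sort(want), atol=1e-9)


def test_hcluster_argument_errors(rng):
    X = pd.DataFrame(rng.random(size=(5, 3)))
    with pytest.raises(ValueError, match="metric"):
        hcluster(X, metric="cosine")
    with pytest.raises(ValueError):
        hcluster(X.iloc[:1])


def test_planted_cobinding_tfs_cocluster(rng):
    """TFs planted together in the with-group REs co-cluster under
    Canberra and rank top by enrichment."""
    split, catalogs = _make_split_and_catalogs(rng, n_with=60)
    results = tf_dual_enrichment(catalogs, split)
    tfs = select_abundant_tfs(results, split.n_with, 0.5)
    assert {"TF_A", "TF_B"} <= set(tfs)
    pm = build_presence_matrix(split.with_peaks, catalogs, list(catalogs))
    order, Z = hcluster(pm.values.fillna(0.0), axis="cols", metric="canberra")
    pos = {tf: i for i, tf in enumerate(order)}
    assert abs(pos["TF_A"] - pos["TF_B"]) == 1  # adjacent leaves
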