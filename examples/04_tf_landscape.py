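"""TF landscape over RE groups: dual-background enrichment, PCA, clustering.

Constructs two RE groups where two TF catalogs are planted preferentially
in the peak-associated group, runs the chi-square dual-background screen,
builds the binary presence matrix, and clusters TFs with the Canberra
metric.
"""
import numpy as np
import pandas as pd

from chromcoloc import (Genome, IntervalSet, build_presence_matrix, hcluster,
                        pca_svd_impute, select_abundant_tfs,
                        tf_dual_enrichment)
from chromcoloc.enhancer_pairing import RESplit
from chromcoloc.tf_landscape import results_to_frame

rng = np.random.default_rng(9)
genome = Genome({"chr1": 50_000_000})
cols = ["re_id", "chrom", "start", "end", "gh_score"]

with_df = pd.DataFrame([(f"W{i:03d}", "chr1", int(s), int(s) + 1000, 1.0)
                        for i, s in enumerate(rng.integers(0, 49_000_000, 60))],
                       columns=cols)
without_df = pd.DataFrame([(f"O{i:03d}", "chr1", int(s), int(s) + 1000, 1.0)
                           for i, s in
                           enumerate(rng.integers(0, 49_000_000, 180))],
                          columns=cols)

catalogs = {}
for tf in ("IRF_like", "SMAD_like", "bystander1", "bystander2", "bystander3"):
    if tf in ("IRF_like", "SMAD_like"):
        inside = [int(s) + 400 for s in with_df["start"] if rng.random() < 0.9]
        starts = inside + rng.integers(0, 49_000_000, 120).tolist()
    else:
        starts = rng.integers(0, 49_000_000, 220).tolist()
    catalogs[tf] = IntervalSet.from_arrays(["chr1"] * len(starts), starts,
                                           [s + 150 for s in starts],
                                           genome=genome)

split = RESplit(with_df, without_df, 10_000)
results = tf_dual_enrichment(catalogs, split)
print(results_to_frame(results)
      [["tf", "n_with", "n_without", "density_ratio", "p_chi2", "q_fdr"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))

abundant = select_abundant_tfs(results, split.n_with, 0.5)
print(f"\nTFs in >50% of peak-associated REs: {abundant}")

pm = build_presence_matrix(split.with_peaks, catalogs, list(catalogs))
scores, loadings, explained = pca_svd_impute(pm, n_components=2)
print(f"presence matrix: {pm.values.shape[0]} REs x {pm.values.shape[1]} TFs; "
      f"PC1 explains {explained['PC1']:.3f} of variance")

order, _ = hcluster(pm.values.fillna(0.0), axis="cols", metric="canberra")
print(f"TF leaf order under Canberra clustering: {order}")
print()
print("The planted factors have small chi-square p, density ratios > 1 and "
      "sit adjacent\nin the dendrogram - the signature of co-binding at the "
      "peak-associated elements.")
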