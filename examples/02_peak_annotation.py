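"""Peak annotation: genomic feature classes, TSS distances, open chromatin.

Places peaks preferentially inside an enhancer-like feature class, then
prints the feature distribution (with Fisher tests), the nearest-TSS
distance bins, and the fraction of peaks near open chromatin.
"""
import numpy as np

from chromcoloc import (Genome, IntervalSet, bin_tss_distances,
                        feature_distribution, make_promoters,
                        nearest_tss_distance, open_chromatin_fraction)

rng = np.random.default_rng(5)
genome = Genome({"chr1": 10_000_000})

# an enhancer-like class covering 3% of the genome + TSSs + ATAC peaks
enh_starts = rng.integers(0, 9_700_000, 100)
enhancers = IntervalSet.from_arrays(["chr1"] * 100, enh_starts,
                                    enh_starts + 3_000, genome=genome)
tss_pos = rng.integers(0, 10_000_000, 150)
tss = IntervalSet.from_arrays(["chr1"] * 150, tss_pos, tss_pos + 1,
                              genome=genome)
atac_starts = rng.integers(0, 9_900_000, 120)
atac = IntervalSet.from_arrays(["chr1"] * 120, atac_starts,
                               atac_starts + 600, genome=genome)

# 30% of peaks planted inside enhancers, the rest uniform
n = 500
inside = enh_starts[rng.integers(0, 100, int(n * 0.3))] + 500
uniform = rng.integers(0, 9_990_000, n - int(n * 0.3))
starts = np.concatenate([inside, uniform])
peaks = IntervalSet.from_arrays(["chr1"] * n, starts, starts + 300,
                                genome=genome)

features = {"promoter": make_promoters(tss), "enhancer": enhancers}
dist = feature_distribution(peaks, features, genome)
print(dist.table[["fraction_of_peaks", "fraction_of_genome",
                  "enrichment_ratio", "odds_ratio", "p_two_tailed"]]
      .to_string(float_format=lambda v: f"{v:.3g}"))
print()
print("TSS distance bins (peak counts):")
print(bin_tss_distances(nearest_tss_distance(peaks, tss)).to_string())
print()
frac = open_chromatin_fraction(peaks, atac, max_dist=10_000)
print(f"fraction of peaks within 10 kb of open chromatin: {frac:.3f}")
print()
print("The enhancer class shows ~10x enrichment (30% of peaks on 3% of "
      "the genome);\nthe promoter class sits near its genome share "
      "(enrichment ratio ~0.9).")
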