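"""Colocalization screen: which TF catalogs share chromatin with a peak set?

Builds a synthetic genome in which query peaks are planted near the sites
of one TF catalog (and a second catalog co-binds the first), then runs the
shuffle-null enrichment screen at three scales and prints the q-values.
"""
import tempfile
from pathlib import Path

from chromcoloc import (ColocTarget, QuerySpec, ShuffleConfig, SyntheticSpec,
                        TFSpec, generate_dataset, multiscale_enrichment,
                        read_bed, read_chrom_sizes)

spec = SyntheticSpec(
    n_chroms=2, chrom_length=5_000_000,
    tf_specs=(TFSpec("IRF_like", 800, 200),
              TFSpec("SMAD_like", 800, 200, near="IRF_like", near_offset=300),
              TFSpec("bystander1", 800, 200),
              TFSpec("bystander2", 800, 200)),
    query_spec=QuerySpec(n_peaks=400, peak_length=400,
                         coloc_targets=(ColocTarget("IRF_like", 0.6, 500),)),
    seed=11)

with tempfile.TemporaryDirectory() as td:
    generate_dataset(spec, td)
    genome = read_chrom_sizes(Path(td) / "chrom.sizes")
    peaks = read_bed(Path(td) / "query_peaks.bed", genome)
    catalogs = {p.stem: read_bed(p, genome)
                for p in sorted((Path(td) / "catalogs").glob("*.bed"))}

    table = multiscale_enrichment(peaks, catalogs, min_frac=0.1,
                                  cfg=ShuffleConfig(n_shuffles=15, seed=1))

cols = ["catalog_name", "scale", "n_obs", "mean_null", "log2_effect",
        "q_by", "selected"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print()
print("The planted catalogs (IRF_like and its co-binder SMAD_like) show "
      "large positive\nlog2 effects and tiny q values at the 0-kb scale; "
      "the bystander catalogs do not.\nOn this small, dense toy genome the "
      "100-kb flanks merge into near-chromosome-wide\nblocks and the 1-Mb "
      "universe spans the whole genome, so those scales add nothing\nhere; "
      "they matter when signal sits near, but not on, the peaks (see the "
      "scale-\nseparation acceptance check).")
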