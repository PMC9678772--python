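"""Pipeline orchestration: configuration, stages, and a run manifest.

Each stage reads standard-format inputs (BED, TSV, FASTA, JASPAR), runs one
library module, and writes diff-able TSV outputs with a leading ``#``
metadata block. Outputs are written atomically (temp file + rename) and a
run manifest records parameters, input checksums and the package version
for every stage executed. The ``all`` mode chains
simulate -> coloc -> annotate -> re-pair -> tf-enrich -> motif-enrich from
one config, wiring the simulated files into the later stages.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enhancer_pairing import (compare_covariates, read_gene_list,
                               read_pairs_table, read_re_table,
                               re_table_to_intervals, select_connected_res,
                               split_by_proximity, write_re_table, RESplit)
from .genome_model import (IntervalSet, read_bed, read_chrom_sizes, write_bed,
                           nearest_tss_distance, bin_tss_distances)
from .motif_scan import read_jaspar, motif_enrichment
from .motif_scan import results_to_frame as motif_frame
from .region_stats import (feature_distribution, make_promoters,
                           open_chromatin_fraction)
from .shuffle_coloc import ShuffleConfig, multiscale_enrichment
from .synthetic_data import (ColocTarget, MotifSpec, QuerySpec, RESpec,
                             SyntheticSpec, TFSpec, generate_dataset)
from .tf_landscape import (build_presence_matrix, hcluster, pca_svd_impute,
                           select_abundant_tfs, tf_dual_enrichment)
from .tf_landscape import results_to_frame as tf_frame

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_stage",
           "run_all", "STAGES"]

log = logging.getLogger("chromcoloc")


class ConfigError(ValueError):
    """Raised when a run configuration is invalid; names the offending key."""


_PARAM_DEFAULTS = {
    # shuffle-null colocalization screen
    "n_shuffles": 15,
    "min_frac": 0.1,
    "overlap_mode": "both",
    "flank_bp": 100_000,
    "universe_bp": 1_000_000,
    "select_q": 0.05,
    "select_n": 100,
    # annotation
    "promoter_upstream": 5000,
    "promoter_downstream": 1000,
    "atac_max_dist": 10_000,
    # RE pairing
    "min_score": 0.7,
    "max_dist": 10_000,
    # TF landscape
    "fdr_method": "fdr_bh",
    "min_fraction_with": 0.75,
    "n_components": 2,
    # motif scanning
    "threshold_frac": 0.8,
}

_RANGES = {
    "n_shuffles": (2, 10_000),
    "min_frac": (0.0, 1.0),
    "flank_bp": (0, None),
    "universe_bp": (0, None),
    "select_q": (0.0, 1.0),
    "select_n": (0, None),
    "promoter_upstream": (0, None),
    "promoter_downstream": (0, None),
    "atac_max_dist": (0, None),
    "min_score": (0.0, None),
    "max_dist": (0, None),
    "min_fraction_with": (0.0, 1.0),
    "n_components": (1, None),
    "threshold_frac": (0.0, 1.0),
}

_INPUT_KEYS = ("chrom_sizes", "query_bed", "catalog_dir", "tss_bed",
               "atac_bed", "re_table", "re_pairs", "de_genes",
               "motif_query_fasta", "motif_control_fasta", "pwm_file",
               "features")


@dataclass
class RunConfig:
    """Normalized pipeline configuration (all defaults filled)."""

    seed: int = 0
    out_dir: str = "chromcoloc_out"
    log_level: str = "INFO"
    params: dict = field(default_factory=lambda: dict(_PARAM_DEFAULTS))
    inputs: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)


def validate_config(source) -> RunConfig:
    """Parse and normalize a config (YAML path, dict, or RunConfig).

    Defaults are filled, unknown keys rejected, and out-of-range values
    raise :class:`ConfigError` naming the key. Normalization is idempotent.
    """
    if isinstance(source, RunConfig):
        raw = asdict(source)
        flat = {"seed": raw["seed"], "out_dir": raw["out_dir"],
                "log_level": raw["log_level"], "inputs": raw["inputs"],
                "synthetic": raw["synthetic"], **raw["params"]}
    elif isinstance(source, dict):
        flat = dict(source)
    else:
        with open(source) as fh:
            flat = yaml.safe_load(fh) or {}
        if not isinstance(flat, dict):
            raise ConfigError("config must be a mapping")

    known = {"seed", "out_dir", "log_level", "inputs", "synthetic",
             *_PARAM_DEFAULTS}
    unknown = set(flat) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    params = dict(_PARAM_DEFAULTS)
    for key in _PARAM_DEFAULTS:
        if key in flat and flat[key] is not None:
            params[key] = flat[key]
    for key, (lo, hi) in _RANGES.items():
        v = params[key]
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigError(f"{key}: expected a number, got {v!r}")
        if (lo is not None and v < lo) or (hi is not None and v > hi):
            raise ConfigError(f"{key}: value {v} out of range")
    if params["overlap_mode"] not in ("both", "query", "catalog"):
        raise ConfigError(f"overlap_mode: {params['overlap_mode']!r}")
    if params["fdr_method"] not in ("fdr_bh", "fdr_by", "bonferroni"):
        raise ConfigError(f"fdr_method: {params['fdr_method']!r}")

    inputs = dict(flat.get("inputs") or {})
    bad = set(inputs) - set(_INPUT_KEYS)
    if bad:
        raise ConfigError(f"unknown input key(s): {sorted(bad)}")

    seed = flat.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError("seed: expected an integer")

    return RunConfig(seed=seed,
                     out_dir=str(flat.get("out_dir", "chromcoloc_out")),
                     log_level=str(flat.get("log_level", "INFO")),
                     params=params, inputs=inputs,
                     synthetic=dict(flat.get("synthetic") or {}))


# -- output helpers -----------------------------------------------------------

def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict,
               index: bool = False) -> None:
    head = "".join(f"# {k}={v}\n" for k, v in sorted(meta.items()))
    _atomic_write(path, head + df.to_csv(sep="\t", index=index,
                                         float_format="%.6g"))


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _config_hash(config: RunConfig) -> str:
    # hash the scientific configuration only (seed + parameters), not file
    # locations: the same analysis in a different directory is the same run
    blob = json.dumps({"seed": config.seed, "params": config.params,
                       "synthetic": config.synthetic},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _require(config: RunConfig, *keys: str) -> list:
    paths = []
    for key in keys:
        p = config.inputs.get(key)
        if not p:
            raise FileNotFoundError(f"stage requires input {key!r} in config")
        if not Path(p).exists():
            raise FileNotFoundError(f"input {key}={p} does not exist")
        paths.append(p)
    return paths


def _load_catalogs(catalog_dir, genome) -> dict:
    beds = sorted(Path(catalog_dir).glob("*.bed"))
    if not beds:
        raise FileNotFoundError(f"no .bed files in {catalog_dir}")
    return {p.stem: read_bed(p, genome) for p in beds}


# -- stages -------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path) -> list:
    syn = dict(config.synthetic)
    tf_specs = tuple(TFSpec(**d) for d in syn.pop("tf_specs", []))
    qd = dict(syn.pop("query", {}))
    targets = tuple(ColocTarget(**t) for t in qd.pop("coloc_targets", []))
    spec = SyntheticSpec(
        tf_specs=tf_specs,
        query_spec=QuerySpec(coloc_targets=targets, **qd),
        re_spec=RESpec(**syn.pop("re", {})),
        motif_spec=MotifSpec(**syn.pop("motif", {})),
        seed=config.seed,
        **syn,
    )
    data_dir = out / "data"
    manifest = generate_dataset(spec, data_dir)
    # wire the simulated files into this run's inputs for later stages
    config.inputs.update({
        "chrom_sizes": str(data_dir / "chrom.sizes"),
        "query_bed": str(data_dir / "query_peaks.bed"),
        "catalog_dir": str(data_dir / "catalogs"),
        "tss_bed": str(data_dir / "tss.bed"),
        "re_table": str(data_dir / "re_table.tsv"),
        "re_pairs": str(data_dir / "re_pairs.tsv"),
        "de_genes": str(data_dir / "de_genes.txt"),
        "motif_query_fasta": str(data_dir / "motif_query.fa"),
        "motif_control_fasta": str(data_dir / "motif_control.fa"),
        "pwm_file": str(data_dir / "motifs.jaspar"),
    })
    return [str(data_dir / f) for f in manifest["files"]]


def _stage_coloc(config: RunConfig, out: Path) -> list:
    sizes, query_bed, catalog_dir = _require(config, "chrom_sizes",
                                             "query_bed", "catalog_dir")
    genome = read_chrom_sizes(sizes)
    query = read_bed(query_bed, genome)
    catalogs = _load_catalogs(catalog_dir, genome)
    p = config.params
    cfg = ShuffleConfig(n_shuffles=int(p["n_shuffles"]), seed=config.seed)
    table = multiscale_enrichment(query, catalogs, float(p["min_frac"]), cfg,
                                  mode=p["overlap_mode"],
                                  flank_bp=int(p["flank_bp"]),
                                  universe_bp=int(p["universe_bp"]),
                                  select_q=float(p["select_q"]),
                                  select_n=int(p["select_n"]))
    path = out / "coloc.tsv"
    _write_tsv(table, path, {"stage": "coloc", "seed": config.seed,
                             "config": _config_hash(config),
                             "n_shuffles": p["n_shuffles"],
                             "min_frac": p["min_frac"]})
    return [str(path)]


def _stage_annotate(config: RunConfig, out: Path) -> list:
    sizes, query_bed, tss_bed = _require(config, "chrom_sizes", "query_bed",
                                         "tss_bed")
    genome = read_chrom_sizes(sizes)
    peaks = read_bed(query_bed, genome)
    tss = read_bed(tss_bed, genome)
    p = config.params
    features = {"promoter": make_promoters(tss, int(p["promoter_upstream"]),
                                           int(p["promoter_downstream"]))}
    for name, path in (config.inputs.get("features") or {}).items():
        features[name] = read_bed(path, genome)
    dist = feature_distribution(peaks, features, genome)
    meta = {"stage": "annotate", "config": _config_hash(config)}
    written = []
    path = out / "feature_distribution.tsv"
    _write_tsv(dist.table, path, meta, index=True)
    written.append(str(path))
    d = nearest_tss_distance(peaks, tss)
    bins = bin_tss_distances(d).rename("n_peaks").to_frame()
    path = out / "tss_distance_bins.tsv"
    _write_tsv(bins, path, meta, index=True)
    written.append(str(path))
    if config.inputs.get("atac_bed"):
        atac = read_bed(config.inputs["atac_bed"], genome)
        frac = open_chromatin_fraction(peaks, atac, int(p["atac_max_dist"]))
        df = pd.DataFrame({"max_dist": [p["atac_max_dist"]],
                           "fraction_near_open_chromatin": [frac]})
        path = out / "open_chromatin.tsv"
        _write_tsv(df, path, meta)
        written.append(str(path))
    return written


def _stage_re_pair(config: RunConfig, out: Path) -> list:
    sizes, query_bed, re_path, pairs_path, de_path = _require(
        config, "chrom_sizes", "query_bed", "re_table", "re_pairs", "de_genes")
    genome = read_chrom_sizes(sizes)
    peaks = read_bed(query_bed, genome)
    res = read_re_table(re_path)
    pairs = read_pairs_table(pairs_path)
    de_genes = read_gene_list(de_path)
    p = config.params
    selected = select_connected_res(res, pairs, de_genes,
                                    float(p["min_score"]))
    split = split_by_proximity(selected, peaks, int(p["max_dist"]),
                               genome=genome)
    meta = {"stage": "re-pair", "config": _config_hash(config),
            "min_score": p["min_score"], "max_dist": p["max_dist"],
            "n_selected": len(selected), "n_with": split.n_with,
            "n_without": split.n_without}
    written = []
    for label, grp in (("re_with_peaks", split.with_peaks),
                       ("re_without_peaks", split.without_peaks)):
        tsv = out / f"{label}.tsv"
        _atomic_write(tsv, grp.to_csv(sep="\t", index=False))
        bed = out / f"{label}.bed"
        if len(grp):
            write_bed(re_table_to_intervals(grp, genome=genome), bed)
        else:
            bed.write_text("")
        written.extend([str(tsv), str(bed)])
    if config.inputs.get("tss_bed") and split.n_with and split.n_without:
        tss = read_bed(config.inputs["tss_bed"], genome)
        cov = compare_covariates(split, tss, genome=genome)
        path = out / "re_covariates.tsv"
        _write_tsv(cov, path, meta, index=True)
        written.append(str(path))
    return written


def _stage_tf_enrich(config: RunConfig, out: Path) -> list:
    sizes, catalog_dir = _require(config, "chrom_sizes", "catalog_dir")
    genome = read_chrom_sizes(sizes)
    catalogs = _load_catalogs(catalog_dir, genome)
    with_path = out / "re_with_peaks.tsv"
    without_path = out / "re_without_peaks.tsv"
    if not with_path.exists() or not without_path.exists():
        raise FileNotFoundError("tf-enrich requires the re-pair stage "
                                "outputs (re_with_peaks.tsv / re_without_peaks.tsv)")
    p = config.params
    split = RESplit(pd.read_csv(with_path, sep="\t"),
                    pd.read_csv(without_path, sep="\t"),
                    int(p["max_dist"]))
    cfg = ShuffleConfig(n_shuffles=int(p["n_shuffles"]), seed=config.seed)
    results = tf_dual_enrichment(catalogs, split, fdr_method=p["fdr_method"],
                                 coloc_cfg=cfg,
                                 min_frac_coloc=float(p["min_frac"]))
    meta = {"stage": "tf-enrich", "config": _config_hash(config)}
    written = []
    path = out / "tf_enrichment.tsv"
    _write_tsv(tf_frame(results), path, meta)
    written.append(str(path))
    tfs = select_abundant_tfs(results, split.n_with,
                              float(p["min_fraction_with"]))
    if not tfs:  # fall back to all catalogs so the matrix stages still run
        tfs = sorted(catalogs)
    matrix = build_presence_matrix(split.with_peaks, catalogs, tfs)
    path = out / "presence_matrix.tsv"
    _write_tsv(matrix.values, path, meta, index=True)
    written.append(str(path))
    n_comp = min(int(p["n_components"]), *matrix.values.shape)
    scores, loadings, explained = pca_svd_impute(matrix, n_comp)
    for name, df in (("pca_scores", scores), ("pca_loadings", loadings),
                     ("pca_explained", explained.to_frame())):
        path = out / f"{name}.tsv"
        _write_tsv(df, path, meta, index=True)
        written.append(str(path))
    filled = matrix.values.fillna(0.0)
    if len(filled) >= 2:
        row_order, _ = hcluster(filled, axis="rows", metric="euclidean")
        col_order, _ = hcluster(filled, axis="cols", metric="canberra")
        path = out / "cluster_order.tsv"
        orders = pd.DataFrame({"axis": ["rows"] * len(row_order)
                               + ["cols"] * len(col_order),
                               "label": list(row_order) + list(col_order)})
        _write_tsv(orders, path, meta)
        written.append(str(path))
    return written


def _stage_motif_enrich(config: RunConfig, out: Path) -> list:
    qf, cf, pwm_path = _require(config, "motif_query_fasta",
                                "motif_control_fasta", "pwm_file")
    from pyfaidx import Fasta
    query = [str(rec[:]).upper() for rec in Fasta(qf)]
    control = [str(rec[:]).upper() for rec in Fasta(cf)]
    pwms = read_jaspar(pwm_path)
    p = config.params
    results = motif_enrichment(query, control, pwms,
                               float(p["threshold_frac"]))
    path = out / "motif_enrichment.tsv"
    _write_tsv(motif_frame(results), path,
               {"stage": "motif-enrich", "config": _config_hash(config),
                "threshold_frac": p["threshold_frac"]})
    return [str(path)]


STAGES = {
    "simulate": _stage_simulate,
    "coloc": _stage_coloc,
    "annotate": _stage_annotate,
    "re-pair": _stage_re_pair,
    "tf-enrich": _stage_tf_enrich,
    "motif-enrich": _stage_motif_enrich,
}

_STAGE_ORDER = ["simulate", "coloc", "annotate", "re-pair", "tf-enrich",
                "motif-enrich"]


def run_stage(name: str, config: RunConfig) -> dict:
    """Run one pipeline stage; returns its run-manifest entry.

    Outputs are written atomically under ``config.out_dir``; the manifest
    (``run_manifest.json``) is appended with the stage name, parameters,
    input checksums and package version. A missing input raises before any
    output is written.
    """
    if name not in STAGES:
        raise KeyError(f"unknown stage {name!r}; "
                       f"choose from {sorted(STAGES)}")
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("running stage %s -> %s", name, out)
    outputs = STAGES[name](config, out)
    entry = {
        "stage": name,
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "params": config.params,
        "inputs": {k: {"path": str(v), "sha256": _checksum(v)}
                   for k, v in config.inputs.items()
                   if isinstance(v, (str, os.PathLike)) and Path(v).is_file()},
        "outputs": sorted(outputs),
    }
    manifest_path = out / "run_manifest.json"
    entries = []
    if manifest_path.exists():
        entries = json.loads(manifest_path.read_text())
    entries.append(entry)
    _atomic_write(manifest_path, json.dumps(entries, indent=1) + "\n")
    return entry


def run_all(config: RunConfig) -> list:
    """Run every stage in order from one config (simulate first)."""
    config = validate_config(config)
    return [run_stage(name, config) for name in _STAGE_ORDER]
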