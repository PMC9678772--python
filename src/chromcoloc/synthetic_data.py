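"""Seeded synthetic datasets with planted structure for every pipeline stage.

The generator emulates the statistical shape of a regulatory-genomics
study: a multi-chromosome genome, TF binding-site catalogs (optionally
co-bound, i.e. one factor's sites planted near another's), query peaks that
colocalize with chosen catalogs at stated probabilities and offsets, a
regulatory-element table with element scores and gene pairings, a
differentially-expressed gene list, and motif-bearing sequence sets. The
planted truth (which peaks were assigned to which catalog, which REs were
placed near peaks, which sequences received a motif) is recorded in a JSON
manifest so recovery can be checked by direct counting.

All randomness flows from a single seed through named substreams, one per
artifact class, so regenerating one artifact class does not perturb the
others. Background objects are placed by rejection *away* from the planted
structure (non-proximal REs are kept beyond the proximity distance from
every peak; control sequences carry no inserted motif), which is what makes
the planted rates identifiable by counting.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (Genome, IntervalSet, write_bed, write_chrom_sizes)
from .motif_scan import PWM, write_jaspar

__all__ = [
    "TFSpec",
    "ColocTarget",
    "QuerySpec",
    "RESpec",
    "MotifSpec",
    "SyntheticSpec",
    "generate_dataset",
    "dinuc_shuffle",
    "builtin_motifs",
]


@dataclass(frozen=True)
class TFSpec:
    """One TF catalog: site count/length, optionally co-bound with another
    catalog (sites placed within ``near_offset`` bp of its sites)."""

    name: str
    n_sites: int = 2000
    site_length: int = 200
    near: str | None = None
    near_offset: int = 300


@dataclass(frozen=True)
class ColocTarget:
    """Planted colocalization of query peaks with one TF catalog.

    probability: chance that a given peak is placed near this catalog.
    max_offset_bp: maximum edge-to-edge gap of a planted peak to the site.
    min_offset_bp: minimum gap; 0 allows overlap, > 0 forbids it (used for
        near-but-not-overlapping scale-separation designs).
    """

    tf_name: str
    probability: float
    max_offset_bp: int = 500
    min_offset_bp: int = 0


@dataclass(frozen=True)
class QuerySpec:
    n_peaks: int = 1000
    peak_length: int = 400
    coloc_targets: tuple = ()


@dataclass(frozen=True)
class RESpec:
    """Regulatory-element table: element count, lengths, scores in a
    GeneHancer-like range, gene panel, DE fraction, and the planted
    peak-proximity rate (default 0.12, the order observed when ~1 in 8
    DE-linked elements carries a peak nearby)."""

    n_res: int = 969
    length_min: int = 500
    length_max: int = 4000
    score_low: float = 0.1
    score_high: float = 2.0
    n_genes: int = 400
    de_fraction: float = 0.25
    genes_per_re: int = 3
    peak_prox_rate: float = 0.12
    prox_max_dist: int = 10_000


@dataclass(frozen=True)
class MotifSpec:
    """Motif-bearing sequence sets: insertion rate is the per-query-sequence
    probability of one planted motif instance; controls never receive one."""

    planted_motif: str = "SYN_IRFLIKE"
    insertion_rate: float = 0.3
    seq_length: int = 500
    n_query: int = 200
    n_control: int = 200


@dataclass(frozen=True)
class SyntheticSpec:
    n_chroms: int = 3
    chrom_length: int = 10_000_000
    tf_specs: tuple = ()
    query_spec: QuerySpec = field(default_factory=QuerySpec)
    re_spec: RESpec = field(default_factory=RESpec)
    motif_spec: MotifSpec = field(default_factory=MotifSpec)
    seed: int = 0
    write_genome_fasta: bool = False

    def __post_init__(self):
        total = sum(t.probability for t in self.query_spec.coloc_targets)
        if any(not 0 <= t.probability <= 1 for t in self.query_spec.coloc_targets):
            raise ValueError("colocalization probabilities must be in [0, 1]")
        if total > 1.0 + 1e-9:
            raise ValueError("colocalization probabilities must sum to <= 1")
        if not 0 <= self.re_spec.peak_prox_rate <= 1:
            raise ValueError("peak_prox_rate must be in [0, 1]")
        if not 0 <= self.motif_spec.insertion_rate <= 1:
            raise ValueError("insertion_rate must be in [0, 1]")


_SUBSTREAMS = ("genome", "tf", "peaks", "re", "genes", "motifs")


def _rngs(seed: int) -> dict:
    return {name: np.random.default_rng(np.random.SeedSequence([seed, i]))
            for i, name in enumerate(_SUBSTREAMS)}


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def builtin_motifs() -> list[PWM]:
    """Four deterministic synthetic PFMs with strong consensus sequences.

    SYN_IRFLIKE carries a GAAA-repeat core reminiscent of IRF-family
    motifs; SYN_SMADLIKE a GC-rich SMAD-like core; the other two are
    arbitrary distinct controls. Each column gives 85 counts to the
    consensus base and 5 to each alternative.
    """
    consensi = {
        "SYN_IRFLIKE": "TTTCGAAACC",
        "SYN_SMADLIKE": "GTCTAGACGG",
        "SYN_CTRL1": "ACCATGGTAC",
        "SYN_CTRL2": "CAGGTAAGTA",
    }
    pwms = []
    for name, cons in consensi.items():
        counts = np.full((4, len(cons)), 5.0)
        for j, base in enumerate(cons):
            counts["ACGT".index(base), j] = 85.0
        pwms.append(PWM(name, counts, name=name))
    return pwms


def _place_uniform(rng, genome: Genome, n: int, length: int):
    """Uniform placement of n intervals over the genome (weighted by
    feasible starts per chromosome)."""
    chroms = genome.chroms
    feas = np.array([genome.size(c) - length + 1 for c in chroms], dtype=float)
    if (feas <= 0).any():
        raise ValueError(f"interval of length {length} does not fit")
    probs = feas / feas.sum()
    idx = rng.choice(len(chroms), size=n, p=probs)
    starts = rng.integers(0, feas.astype(np.int64)[idx])
    return [chroms[i] for i in idx], starts, starts + length


def _place_near(rng, genome: Genome, site, length: int,
                min_offset: int, max_offset: int):
    """One interval with edge-to-edge gap to ``site`` within
    [min_offset, max_offset]; min_offset 0 allows overlap/containment."""
    chrom, s_start, s_end = site
    size = genome.size(chrom)
    for _ in range(100):
        if min_offset <= 0:
            lo = s_start - length - max_offset
            hi = s_end + max_offset  # start range keeping gap <= max_offset
            start = int(rng.integers(lo, hi - length + 1))
        else:
            gap = int(rng.integers(min_offset, max_offset + 1))
            if rng.random() < 0.5:
                start = s_start - gap - length
            else:
                start = s_end + gap
        if 0 <= start and start + length <= size:
            return chrom, start, start + length
    raise ValueError(f"cannot place interval near {chrom}:{s_start}-{s_end}")


def _generate_tf_catalogs(rng, genome: Genome, tf_specs) -> dict:
    catalogs: dict = {}
    for spec in tf_specs:
        if spec.near is not None:
            if spec.near not in catalogs:
                raise ValueError(
                    f"catalog {spec.name!r} co-binds {spec.near!r}, which "
                    "must be declared earlier in tf_specs")
            anchor = catalogs[spec.near].df
            picks = rng.integers(0, len(anchor), size=spec.n_sites)
            chroms, starts, ends = [], [], []
            for i in picks:
                row = anchor.iloc[int(i)]
                c, s, e = _place_near(rng, genome,
                                      (row.chrom, int(row.start), int(row.end)),
                                      spec.site_length, 0, spec.near_offset)
                chroms.append(c)
                starts.append(s)
                ends.append(e)
        else:
            chroms, starts, ends = _place_uniform(rng, genome, spec.n_sites,
                                                  spec.site_length)
        catalogs[spec.name] = IntervalSet.from_arrays(chroms, starts, ends,
                                                      genome=genome)
    return catalogs


def _generate_peaks(rng, genome: Genome, qspec: QuerySpec, catalogs: dict):
    """Peaks with planted colocalization; returns (IntervalSet, assignment
    list aligned with generation order)."""
    targets = list(qspec.coloc_targets)
    probs = [t.probability for t in targets]
    probs.append(max(0.0, 1.0 - sum(probs)))
    chroms, starts, ends, assigned = [], [], [], []
    for _ in range(qspec.n_peaks):
        k = int(rng.choice(len(probs), p=np.array(probs) / sum(probs)))
        if k < len(targets):
            t = targets[k]
            cat = catalogs[t.tf_name].df
            row = cat.iloc[int(rng.integers(0, len(cat)))]
            c, s, e = _place_near(rng, genome,
                                  (row.chrom, int(row.start), int(row.end)),
                                  qspec.peak_length, t.min_offset_bp,
                                  t.max_offset_bp)
            assigned.append(t.tf_name)
        else:
            cs, ss, es = _place_uniform(rng, genome, 1, qspec.peak_length)
            c, s, e = cs[0], int(ss[0]), int(es[0])
            assigned.append(None)
        chroms.append(c)
        starts.append(s)
        ends.append(e)
    return IntervalSet.from_arrays(chroms, starts, ends, genome=genome), assigned


def _generate_res(rng, genome: Genome, respec: RESpec, peaks: IntervalSet):
    """RE table with a planted peak-proximity rate.

    Proximal REs are placed with gap <= prox_max_dist of a random peak;
    background REs are rejection-sampled to lie strictly beyond that
    distance from every peak, so the split fraction estimates the planted
    rate directly.
    """
    peak_rows = list(peaks.df[["chrom", "start", "end"]].itertuples(index=False))
    # per-chromosome sorted peak arrays for fast scalar gap queries
    peak_arr = {chrom: (s, np.maximum.accumulate(e))
                for chrom, s, e in peaks.by_chrom()}

    def gap_to_peaks(chrom: str, start: int, end: int) -> float:
        if chrom not in peak_arr:
            return np.inf
        ps, prun = peak_arr[chrom]
        i = int(np.searchsorted(ps, end, side="left"))
        if i > 0 and prun[i - 1] > start:
            return 0.0
        left = start - prun[i - 1] if i > 0 else np.inf
        right = ps[i] - end if i < len(ps) else np.inf
        return float(min(left, right))

    rows = []
    truth = []
    for i in range(respec.n_res):
        length = int(rng.integers(respec.length_min, respec.length_max + 1))
        proximal = bool(rng.random() < respec.peak_prox_rate)
        if proximal and peak_rows:
            row = peak_rows[int(rng.integers(0, len(peak_rows)))]
            c, s, e = _place_near(rng, genome,
                                  (row.chrom, int(row.start), int(row.end)),
                                  length, 0, respec.prox_max_dist)
        else:
            proximal = False
            for _ in range(1000):
                cs, ss, es = _place_uniform(rng, genome, 1, length)
                c, s, e = cs[0], int(ss[0]), int(es[0])
                if gap_to_peaks(c, s, e) > respec.prox_max_dist:
                    break
            else:
                raise ValueError("cannot place a background RE away from peaks")
        score = float(rng.uniform(respec.score_low, respec.score_high))
        rows.append((f"RE{i:05d}", c, s, e, round(score, 4)))
        truth.append(proximal)
    res = pd.DataFrame(rows, columns=["re_id", "chrom", "start", "end",
                                      "gh_score"])
    return res, truth


def _generate_genes(rng, genome: Genome, respec: RESpec):
    """Gene TSSs (1-bp intervals, uniform), a DE subset, and RE-gene pairs
    linking each RE to its nearest genes with a distance-decaying score."""
    chroms, starts, _ = _place_uniform(rng, genome, respec.n_genes, 1)
    genes = pd.DataFrame({
        "gene": [f"GENE{i:04d}" for i in range(respec.n_genes)],
        "chrom": chroms,
        "pos": np.asarray(starts, dtype=np.int64),
    })
    n_de = int(round(respec.de_fraction * respec.n_genes))
    de_idx = rng.choice(respec.n_genes, size=n_de, replace=False)
    de_genes = sorted(genes["gene"].iloc[np.sort(de_idx)].tolist())
    return genes, de_genes


def _pair_res_to_genes(res, genes, k: int):
    """Each RE pairs to its k nearest genes on the same chromosome;
    pair_score decays with distance (1 / (1 + d / 10 kb))."""
    rows = []
    by_chrom = {c: sub.sort_values("pos") for c, sub in genes.groupby("chrom")}
    for re_row in res.itertuples(index=False):
        sub = by_chrom.get(re_row.chrom)
        if sub is None:
            continue
        mid = (re_row.start + re_row.end) // 2
        d = np.abs(sub["pos"].to_numpy() - mid)
        order = np.argsort(d, kind="mergesort")[:k]
        for j in order:
            dist = int(d[j])
            score = 1.0 / (1.0 + dist / 10_000.0)
            rows.append((re_row.re_id, sub["gene"].iloc[int(j)],
                         round(score, 5)))
    return pd.DataFrame(rows, columns=["re_id", "gene", "pair_score"])


def _write_fasta(path, names_and_seqs, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in names_and_seqs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _generate_motif_sets(rng, mspec: MotifSpec, pwms: list[PWM]):
    planted = {p.motif_id: p for p in pwms}[mspec.planted_motif]
    probs = planted.counts / planted.counts.sum(axis=0, keepdims=True)
    L = planted.length

    def sample_instance() -> str:
        idx = [int(rng.choice(4, p=probs[:, j])) for j in range(L)]
        return "".join("ACGT"[i] for i in idx)

    query, control, truth = [], [], []
    for i in range(mspec.n_query):
        seq = _random_seq(rng, mspec.seq_length)
        inserted = bool(rng.random() < mspec.insertion_rate)
        if inserted:
            inst = sample_instance()
            if rng.random() < 0.5:  # random strand
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                inst = "".join(comp[b] for b in reversed(inst))
            pos = int(rng.integers(0, mspec.seq_length - L + 1))
            seq = seq[:pos] + inst + seq[pos + L:]
        query.append((f"query_{i:04d}", seq))
        truth.append(inserted)
    for i in range(mspec.n_control):
        control.append((f"control_{i:04d}", _random_seq(rng, mspec.seq_length)))
    return query, control, truth


def generate_dataset(spec: SyntheticSpec, out_dir) -> dict:
    """Generate every pipeline input under ``out_dir`` and return the
    manifest (also written to ``manifest.json``).

    Files: ``chrom.sizes``, ``catalogs/<tf>.bed`` per TF, ``query_peaks.bed``,
    ``re_table.tsv``, ``re_pairs.tsv``, ``de_genes.txt``, ``tss.bed``,
    ``motifs.jaspar``, ``motif_query.fa``, ``motif_control.fa``, optionally
    ``genome.fa``, plus ``manifest.json`` recording the spec, seed, and the
    planted truth. Identical spec + seed produce byte-identical outputs.
    """
    out = Path(out_dir)
    rngs = _rngs(spec.seed)
    genome = Genome({f"chr{i + 1}": spec.chrom_length
                     for i in range(spec.n_chroms)})

    # generate everything in memory first: no files on infeasible specs
    catalogs = _generate_tf_catalogs(rngs["tf"], genome, spec.tf_specs)
    peaks, peak_truth = _generate_peaks(rngs["peaks"], genome,
                                        spec.query_spec, catalogs)
    res, re_truth = _generate_res(rngs["re"], genome, spec.re_spec, peaks)
    genes, de_genes = _generate_genes(rngs["genes"], genome, spec.re_spec)
    pairs = _pair_res_to_genes(res, genes, spec.re_spec.genes_per_re)
    pwms = builtin_motifs()
    query_seqs, control_seqs, motif_truth = _generate_motif_sets(
        rngs["motifs"], spec.motif_spec, pwms)
    genome_seq = None
    if spec.write_genome_fasta:
        genome_seq = [(c, _random_seq(rngs["genome"], genome.size(c)))
                      for c in genome.chroms]

    out.mkdir(parents=True, exist_ok=True)
    (out / "catalogs").mkdir(exist_ok=True)
    write_chrom_sizes(genome, out / "chrom.sizes")
    for name in sorted(catalogs):
        write_bed(catalogs[name], out / "catalogs" / f"{name}.bed")
    write_bed(peaks, out / "query_peaks.bed")
    res.to_csv(out / "re_table.tsv", sep="\t", index=False)
    pairs.to_csv(out / "re_pairs.tsv", sep="\t", index=False)
    (out / "de_genes.txt").write_text("".join(g + "\n" for g in de_genes))
    tss = IntervalSet.from_arrays(genes["chrom"].tolist(), genes["pos"],
                                  genes["pos"] + 1, genome=genome,
                                  names=genes["gene"].tolist())
    write_bed(tss, out / "tss.bed")
    write_jaspar(pwms, out / "motifs.jaspar")
    _write_fasta(out / "motif_query.fa", query_seqs)
    _write_fasta(out / "motif_control.fa", control_seqs)
    if genome_seq is not None:
        _write_fasta(out / "genome.fa", genome_seq)

    manifest = {
        "seed": spec.seed,
        "spec": asdict(spec),
        "files": sorted(str(p.relative_to(out))
                        for p in out.rglob("*") if p.is_file()),
        "truth": {
            "peak_coloc_assignment": peak_truth,
            "peak_coloc_counts": {
                t.tf_name: peak_truth.count(t.tf_name)
                for t in spec.query_spec.coloc_targets},
            "planted_tfs": sorted({t.tf_name
                                   for t in spec.query_spec.coloc_targets}
                                  | {s.name for s in spec.tf_specs
                                     if s.near is not None}),
            "re_proximal": re_truth,
            "re_proximal_count": int(sum(re_truth)),
            "motif_inserted": motif_truth,
            "motif_inserted_count": int(sum(motif_truth)),
            "planted_motif": spec.motif_spec.planted_motif,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


# -- dinucleotide shuffle -----------------------------------------------------

def dinuc_shuffle(seqs, seed: int = 0) -> list:
    """Shuffle each sequence preserving its exact dinucleotide counts
    (Altschul-Erickson Euler-path shuffle). Deterministic under the seed."""
    rng = np.random.default_rng(seed)
    return [_dinuc_shuffle_one(s, rng) for s in seqs]


def _dinuc_shuffle_one(seq: str, rng: np.random.Generator) -> str:
    if len(seq) < 3:
        return seq
    # multigraph: vertex = symbol, edge u->v per adjacent pair
    adj: dict = {}
    for a, b in zip(seq, seq[1:]):
        adj.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = list(adj.keys())
    # choose a random terminal edge per non-last vertex until they form a
    # tree converging on the last symbol (Altschul-Erickson condition)
    for _ in range(10_000):
        terminal = {}
        for v in vertices:
            if v == last:
                continue
            terminal[v] = adj[v][int(rng.integers(0, len(adj[v])))]
        ok = True
        for v in terminal:
            node, seen = v, set()
            while node != last:
                if node in seen or node not in terminal:
                    ok = False
                    break
                seen.add(node)
                node = terminal[node]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - terminates with overwhelming probability
        raise RuntimeError("dinucleotide shuffle failed to find an Euler path")
    shuffled_adj = {}
    for v in vertices:
        edges = list(adj[v])
        if v != last:
            edges.remove(terminal[v])
        perm = rng.permutation(len(edges))
        edges = [edges[i] for i in perm]
        if v != last:
            edges.append(terminal[v])
        shuffled_adj[v] = edges
    # walk the Euler path
    out = [first]
    counters = {v: 0 for v in vertices}
    node = first
    for _ in range(len(seq) - 1):
        nxt = shuffled_adj[node][counters[node]]
        counters[node] += 1
        out.append(nxt)
        node = nxt
    return "".join(out)
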