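# Methods

This note documents the models, defaults and numerical choices behind
`chromcoloc`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Interval model

All coordinates are 0-based, half-open (BED native), strand-agnostic. A
`Genome` is an ordered map of chromosome name to length; an `IntervalSet`
keeps intervals sorted by (chromosome, start, end) and validates bounds
when a genome is attached. Merging unions intervals that share at least one
nucleotide; bookended intervals (end == next start) share zero bases and
stay separate. Flanking extends both sides and clips to the chromosome
without auto-merging, so callers decide when to collapse. Coverage is
computed on the merged set. Nearest-distance queries return edge-to-edge
gaps in bp (overlap = 0, bookended = 0) and an infinite sentinel when a
chromosome carries no target; equidistant ties are irrelevant because only
the distance is reported.

The fractional-overlap rule flags a query interval when some catalog
interval intersects it by at least `min_frac` (default 0.1) of *both*
interval lengths. The threshold's sidedness is genuinely ambiguous in
common tool descriptions, so it is exposed as a mode switch
(`both | query | catalog`); `min_frac = 0` degenerates to any-1-bp overlap.

## Shuffle-null colocalization

The null relocates each query interval uniformly over all feasible start
positions in its placement universe, preserving the interval-length
multiset and, with `by_chrom = True` (default), each interval's
chromosome. Shuffled intervals may overlap one another — the simple uniform
null. The universe is either whole chromosomes or an explicit interval set
(the multi-scale screen uses the merged 1-Mb neighborhood of the query as a
local background). The same shuffled replicates are reused across catalogs
within a run, which makes the full result table reproducible from one seed
and keeps catalogs exchangeable under the null.

Significance: with observed event count `n_obs` and null mean/sd `m`,
`s` over `n_shuffles` (default 15) replicates,

- the z denominator is `max(s, sqrt(m * (1 - m/n_query)))`. Null counts
  are sums of independent per-interval Bernoullis, so the binomial sd is a
  provable upper bound on the true null sd; flooring with it removes the
  heavy-tailed false positives that the noisy 15-replicate sd estimate
  otherwise produces (its CV is ~19% at n = 15) at a power cost below 2%.
- `p = 2 * Phi(-|z|)` when `m >= 10`; below that the normal approximation
  is invalid for counts and an exact two-tailed Poisson tail with rate
  `max(m, 1/n_shuffles)` is used (the rate floor keeps a null that never
  produced an event from claiming certainty). An empirical-p mode exists
  for large shuffle counts.
- a degenerate `s = 0` with `n_obs != m` falls back to an sd floor of 0.5
  events.
- q-values are Benjamini–Yekutieli across catalogs within one scale
  (step-up with the harmonic factor `c(m)`), implemented directly and
  cross-checked against statsmodels in the tests.
- the effect size is `log2((n_obs + 1) / (m + 1))`.

The multi-scale screen runs (a) the raw query genome-wide, (b) the query
flanked by 100 kb (merged first — 100-kb flanks overlap heavily) and
(c) the raw query against the 1-Mb local universe. The fractional-overlap
mode applies to the unflanked scales; at the flanked scale the fraction is
applied catalog-side only, because a 200-kb-wide flanked query can never
carry 10% of its own length in a typical binding site — a dual-sided
threshold would zero the scale out by construction. The screen filter
(`selected`) is q < 0.05 and catalog size > 100.

## Feature annotation

Fisher exact tests use the bedtools-`fisher` contingency convention:
n11/n12 from query intervals hit/missed, n21 from catalog intervals not
hit, and n22 estimated as `round(G / mean_len) - n11 - n12 - n21` (floored
at 0) with `G` the genome length and `mean_len` the mean interval length
over both sets. The estimate is crude by design; the raw table is always
emitted so it can be audited. Two-sided p sums hypergeometric probabilities
of tables no more probable than the observed one (scipy, verified against
exhaustive enumeration).

Promoters are `[t - 5 kb, t + 1 kb)` around 1-bp TSSs, merged; both pads
are configurable and "upstream" means lower coordinates because TSS input
carries no strand in this pipeline. Open-chromatin proximity counts peaks
whose gap to the nearest ATAC interval is at most 10 kb (inclusive).

## Enhancer–gene pairing

The RE table schema is a minimal GeneHancer-like TSV (`re_id, chrom,
start, end, gh_score`); pairings are `re_id, gene, pair_score`. Selection
keeps REs with element score strictly above 0.7 that pair to at least one
DE gene (case-insensitive symbols), deduplicated by `re_id`; pairs naming
unknown REs are skipped with a warning. The proximity split uses the 10-kb
edge-to-edge rule. Covariates (score, length, nearest-TSS distance) are
compared with a two-sided Mann–Whitney U — distribution-free, appropriate
for skewed genomic lengths and distances.

## TF landscape

Per TF, the 2×2 table of REs containing ≥1 site in each group is tested by
chi-square with Yates continuity correction (the R `chisq.test` default
for 2×2 tables); degenerate margins return p = 1. The FDR method is
Benjamini–Hochberg by default (configurable). Densities are TF sites
overlapping a group per Mb of the group's merged coverage — the
denominator choice (merged base coverage) is a design decision, logged
here because "per 1 Mb" does not fix it. The genome-background axis
delegates to the shuffle-null engine on the peak-associated REs.

The presence matrix is binary RE × TF over the abundant TFs (present in
more than 75% of the peak-associated REs, strict). A cell is masked (NaN)
when the TF catalog has no data for the RE's chromosome — absence of
evidence, the one scenario that makes SVD imputation meaningful on a 0/1
matrix. All-zero rows are excluded; labels are ordered lexicographically.

PCA centers columns and fills masked cells by iterative rank-k SVD
reconstruction (convergence when the largest absolute change in imputed
cells drops below 1e-6, at most 100 sweeps); on a complete matrix the loop
is a no-op and the result equals plain centered-SVD PCA. Signs are fixed by
making each component's largest-magnitude loading positive; explained
variances use the sample (ddof = 1) normalization so they sum to the total
column variance at full rank. Clustering is scipy average linkage on
Euclidean (REs) or Canberra (TFs) distances; Canberra's 0/0 terms
contribute zero, which makes it sensitive to presence/absence patterns in
sparse binary profiles.

## Motif scanning

PFM counts (JASPAR text format, read and written via Biopython) are
converted to log2-odds with a pseudocount of 0.5 per cell against a
uniform background (both configurable per PWM). Both strands are scanned by
scoring forward windows with the matrix and with its reverse-complement;
positions are 0-based forward coordinates. Windows containing non-ACGT
characters are skipped. A hit requires a score of at least `threshold_frac`
(default 0.8) of the consensus score — no threshold is canonical, so the
value is configurable and recorded in output metadata. Hits are counted as
total hit windows, not sequences with ≥1 hit, because a single bound region
frequently carries several instances.

Enrichment compares hit rates per kb scanned between query and control
sets (pseudo-hit 0.5 per set against division by zero) and tests the query
hit count with a two-sided binomial using the control hit probability. The
control probability is a plug-in estimate, so a control set several times
the query size is recommended (the calibration checks use 10:1); the
dinucleotide Euler-path shuffle (`dinuc_shuffle`) is provided as one
concrete control-set recipe.

## Synthetic data

`generate_dataset` emulates the statistical shape of the pipeline's
inputs: a multi-chromosome genome (default 3 × 10 Mb), TF catalogs of
uniform sites (default 2000 × 200 bp per factor; ~67 sites/Mb, the density
of a well-covered factor in an aggregated catalog) with optional
co-binding (one factor's sites placed within a small offset of another's),
query peaks (default 1000 × 400 bp) placed near a chosen catalog's sites
with a stated probability and offset, an RE table (default 969 elements,
scores uniform on [0.1, 2], peak-proximity rate 0.12 — about one in eight
elements near a peak), gene TSSs with a DE subset (default 25% of 400) and
distance-decaying pairings to each RE's three nearest genes, and motif
sequence sets (default 200 + 200 × 500 bp, insertion rate 0.3) with
instances sampled column-wise from the PFM.

Two design points make the planted rates identifiable by direct counting:
background REs are rejection-sampled to lie strictly beyond the proximity
distance from every peak, and control sequences never receive an
insertion. Randomness flows from one seed through named substreams (one
per artifact class), so regenerating one artifact class does not perturb
the others, and identical spec + seed reproduce every file byte for byte.

What the generator does *not* emulate: chromatin-state structure, GC/
repeat composition, peak-width and score distributions of real callers,
catalog-specific site clustering, or read-level noise. Passing tests
therefore demonstrate that the statistics recover planted structure at
realistic densities and stay calibrated under their own nulls — not that
any biological conclusion transfers to a particular real dataset.

A note on dependence: when peaks are planted at one catalog's sites, their
colocalization with *every* catalog inherits that catalog's chance
correlations with the anchor. This is real signal amplification, not an
artifact, and it occasionally (about one seed in twenty at the default
densities) lifts a null catalog past the q < 0.05 line — the same reason
aggregated-catalog screens on real data return many correlated hits.

## Problem sizes used by the checks

The demonstration and calibration runs use: 200 null simulations with 100
shuffles (colocalization calibration, 200 query × 200 catalog intervals of
500 bp on 2 Mb); 200 replicates of 30 query vs 300 control 300-bp
sequences (motif calibration); 500 replicates of 200 + 200 REs (covariate
type-I); 20 seeded datasets at the default generator scale (planted
recovery); and a 400-peak, 3 × 50-Mb design with gaps planted uniformly in
50–200 kb (scale separation — sized so that the ~⅓ of gaps falling inside
a 100-kb flank carry clear power). The whole suite and the acceptance
script each run in minutes on one CPU.

## Limitations

- The shuffle null treats query intervals as independent; clustered query
  sets (e.g. peaks concentrated at hotspots) are overdispersed relative to
  it, and q-values near the threshold should be read accordingly.
- The n22 cell of the Fisher convention is an estimate, not a count; use
  the emitted table when exactness matters.
- Motif enrichment treats the control hit probability as known; undersized
  control sets inflate the type-I rate.
- Strand is ignored everywhere, including promoters; TSS input with strand
  information is not currently exploited.
- No BAM/FASTQ handling, peak calling, liftover, de-novo motif discovery,
  or external database access.
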