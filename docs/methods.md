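# Methods

## Data model

A pooled inducible-shRNA screen in hiPSC clones is read out at three
levels, all handled by this package:

1. **Plasmid pools.** Each shRNA is paired at design time with a unique
   8-nt barcode (BC); during cloning every plasmid additionally acquires a
   random 6-nt unique clonal identifier (UCI). The concatenated UCI+BC key
   identifies a clone; the BC alone identifies the perturbation. QC
   sequencing libraries carry a 12-nt diversity index (DI) introduced
   during low-cycle PCR.
2. **Enrichment reads.** A targeted library amplifies the 3' UTR of the
   constitutively expressed repressor transcript. Read 1 carries the cell
   ID and UMI (16 + 12 nt for droplet chemistry; 8-nt UMI plus RT index
   on read 1 and PCR indexes in the read name for split-pool chemistry).
   Read 2 begins with a fixed 23-nt anchor (`CGGCTCCCCCAGATGAACGCGCC`)
   followed by the BC and UCI. Cassettes lacking an shRNA produce a
   variant anchor (`...CGCGTA`, two terminal substitutions); their cells
   are useful internal unperturbed controls.
3. **Annotated cells.** Downstream statistics operate on per-cell tables
   (cluster, condition, time point, clone, pseudotime, module scores)
   produced by any standard scRNA-seq toolchain; clustering, trajectory
   inference and module discovery themselves are out of scope.

## Pool QC

Reads are "partially deduplicated" by collapsing identical (DI, payload)
pairs while retaining multiplicities — the DI randomizes molecules before
amplification, so residual duplicates with distinct DIs are kept as
independent observations.

**Step-1 QC** verifies shRNA/UCI-BC pairing. After deduplication, UCI-BC
keys counted more than a threshold (default 100) are retained. A key is
assigned to shRNA *s* iff *s* was observed at least `dominance` (default
10) times more often than every other shRNA for that key; ties at exactly
the factor pass, and a key with a single observed shRNA trivially
dominates. Keys whose dominant shRNA differs from the shRNA encoded by
their embedded barcode are flagged as **swaps** (template-switching or
cloning artifacts) and drive later relabelling. shRNA recognition is an
exact match of the hairpin-defining sequence; unmatched reads are tallied
but not fatal. The read geometry assumed by the CLI
(`[DI 12][hairpin 21][UCI 6][BC 8]`) is a convention of this package and
each length is a flag.

**Step-2 QC** counts UCI-BC keys in the final pool, removes keys at or
below a threshold (default 1000) as NGS artifacts, and reports per-shRNA
count distributions. The same routine, applied to genomic DNA sequencing
of cultured pools, feeds **clone-drift tracking**: per sample, clone
counts are restricted to clones with an annotated phenotype, converted to
percentages (summing to 100 per sample), and aggregated per phenotype.

## Perturbation assignment

For each read pair, read 2 is reverse-complemented and concatenated to
read 1; the anchor is checked at the start of read 2 (equivalently the end
of the concatenated read) with Hamming distance at most `max_mismatch`
(default 0 — exact, matching the filtering the method prescribes; the flag
exists because anchor sequencing errors otherwise discard reads). `N`
bases never match. Cell ID and UMI come from read-1 coordinates; BC and
UCI are the bases immediately after the anchor (BC first by default; the
physical order is configurable because it is not fixed by the chemistry
description). Reads with barcodes absent from the design table, or cell
IDs outside the expression-matrix whitelist, are discarded, and every read
lands in exactly one report bin (short read, no anchor, invalid BC, off
whitelist, empty read, duplicate, collision loss, kept) so counts
reconcile at every stage.

Records are collapsed on (cell ID, UMI, UCI, BC). PCR chimeras — the same
cell and UMI attached to different UCI-BCs — are resolved by keeping the
record with the strictly largest duplicate count; on a tie *all* tied
records are dropped, a deliberately conservative choice that fabricates no
evidence. Distinct surviving UMIs are then counted per UCI-BC per cell.

Three filters gate assignment: (1) supporting UMIs strictly greater than
`min_umi` (10 droplet, 5 split-pool; the multiome preset's "at least 6"
is encoded as the equivalent strict bound 5 since counts are integers);
(2) the UCI-BC's share of the cell's UMIs strictly greater than 15%;
(3) the ratio to the second most abundant UCI-BC in the cell at least 5
(3 for multiome), infinite when the cell has a single UCI-BC. A cell is
`assigned` iff exactly one UCI-BC passes the depth and fraction gates and
it also passes the ratio gate; it is `multiple` (a genetic doublet,
excluded from all downstream statistics) iff two or more UCI-BCs pass the
depth and fraction gates; otherwise `unassigned`. Treating criteria 1–2 as
candidacy and criterion 3 as the final gate is required for doublets to be
observable at all — no two UCI-BCs can simultaneously dominate each other
fivefold — and matches the empty-cell rule below, which keys on "all below
the first two thresholds".

A cell becomes `empty` iff it has strictly more than 5 empty-anchor UMIs
and no UCI-BC passed the depth/fraction gates; assigned and doublet cells
are never overwritten. Finally, cells of clones flagged as swaps in the
step-1 pairing table are relabelled to the dominant shRNA their UCI
proves, leaving the UCI part of the clone identity untouched.

## Expression-matrix and clone gates

Cells are kept iff total UMIs > 200, expressed genes > 200, and
mitochondrial percentage < 30% (split-pool) or < 20% (droplet) — all
strict per the "more than / less than" convention. Genes are kept iff
protein-coding with at least 10 total counts (inclusive). Split-pool
nuclei are additionally screened for depth (≥ 500 UMIs) and doublets
(total UMIs ≤ mean + 2 sd, with mean and sd computed once on the
pre-filter population, not iteratively; both arms are applied jointly on
the raw population). Clones counted fewer than 20 times in *any* time
point or condition where they appear are set aside (flagged, not deleted);
absence from a grouping is not a violation. Clones are labelled with a
reference phenotype (e.g. unbiased vs neuroectoderm-primed pluripotent
state) when at least 75% of their reference-timepoint cells share the
corresponding cluster, else `mixed`.

## Fisher framework

The two-sided Fisher exact p-value is computed by exhaustive
hypergeometric enumeration in exact integer arithmetic: with margins
fixed, all tables whose probability numerator (an integer once the common
denominator C(N, c1) is factored out) is at most the observed numerator
contribute. This removes the floating-point tie ambiguity that
tolerance-based implementations handle heuristically; the test suite
cross-checks against both scipy and an independent rational-arithmetic
enumerator. Zero-margin tables are undefined and return p = 1 with a
warning. Benjamini–Hochberg adjustment is step-up, order-preserving,
capped at 1, and applied to exactly the set of tests performed within one
invocation (a per-unit family is available as an option).

**Enrichment/depletion** tests, per clone, the 2×2 table
`[[clone@target, others@target], [clone@baseline, others@baseline]]` over
shRNA-expressing cells only (empty cells are excluded from totals because
they are not wholly comparable). Fold change is the ratio of clone
fractions; 0/0 is undefined (NaN) and x/0 reports +inf. **Cell-type
representation** tests, per (unit, cluster), the 2×2 of in-cluster vs
out-of-cluster × interest vs control, where the control is either the
same clones without treatment (the paired, clone-aware design) or a
designated control shRNA. Units below 70 cells in every time point and
clusters below 40 cells in both compared groups are excluded before
adjustment, to avoid spending the error budget on underpowered
comparisons. `benchmark_controls` counts, per comparison, in how many
control settings it reaches significance — the readout used to show that
unmatched controls inflate false positives and negatives relative to the
paired design.

## Signed KS framework

Pseudotime or per-cell module scores are compared per unit with a
two-sample KS test: the two-sided p (BH-adjusted across units) decides
significance; two one-sided tests (each side BH-adjusted across units)
decide direction, reported only for significant units. The signed
statistic is +D when the condition of interest has the higher cumulative
distribution (its values are lower) and −D when lower (its values are
higher). The exact null distribution is used when `n_x * n_y ≤ 10,000`,
the asymptotic approximation otherwise; ties are handled by evaluating
the empirical CDFs at the data points, without jitter. Units with fewer
than 20 cells in either group are skipped (the method filters "by
numerosity" without printing a number; 20 matches the clone-retention
gate).

**Module scores.** Per cell, a module's score is the mean over its genes
of `log1p` counts-per-10k — invariant to library size, with all-zero
cells scoring 0; mean/median and log/linear are swappable strategy flags
since the upstream tool's aggregation internals are not pinned down.
Per (module, unit), the difference between the unit's mean score and the
control's (or, in the paired design, between the unit's treated and
untreated cells) is Z-scored across units (population sd), and modules
are ranked by maximum |Z| with stable label tie-breaks; zero-variance
modules rank last with a warning.

## Synthetic data

The generator defaults encode the study conditions the pipeline targets:
23 shRNAs per pool (with SCR/B2M-style controls), random barcodes at
pairwise Hamming ≥ 2, empty-cassette cells at 8% of all cells (the
observed ~7–9%), negative-binomial enrichment reads per cell (mean 20,
dispersion 10 — overdispersion is empirically realistic; the mean matches
the per-UCI coverage reported for noisy nuclei), substitution errors at a
configurable per-base rate, template-switching barcode swaps, ambient
molecules, and ~1:1 doublets. Quality strings are constant because the
pipeline never reads base qualities.

The annotation-level simulator plants cluster compositions (multinomial),
pseudotime shifts and module-score shifts per clone and condition, on top
of a clone-level baseline offset (sd 0.3) shared between a clone's treated
and untreated cells — the clonal variability that the paired design is
built to cancel. It emulates the *statistical* structure of the data only:
no transcriptome counts, no trajectory geometry, no batch structure.
Passing tests therefore demonstrate the correctness and calibration of the
decision rules, not robustness to upstream artifacts (misclustering,
pseudotime estimation error, ambient RNA in the expression matrix).

## Numerical choices and problem sizes

* Assignment is permutation-invariant in read order and deterministic;
  output rows are sorted by cell ID.
* Boundary conventions: criteria 1–2 strict, criterion 3 inclusive;
  matrix gates strict; gene floor and clone floor inclusive; phenotype
  majority inclusive at 75%; empty gate strict at 5.
* The validation suite runs the assignment oracle comparison on 50 random
  instances of ≤ 1,000 reads; recovery at 40 clones × 100 cells; Fisher
  fidelity over all 132,470 positive-margin 2×2 tables with N ≤ 40
  against exact rational enumeration; null calibration over 200 simulated
  datasets per framework; and power at 150-vs-150 cells (pseudotime,
  shift 1.5 sd) and 300-vs-300 cells (3× cluster enrichment). These sizes
  keep the whole suite to well under a minute per stage while leaving
  Monte-Carlo error small relative to the margins tested.

## Known limitations

* UMI error-correction networks and cell-barcode knee detection are out
  of scope: a whitelist is an input, and UMIs with sequencing errors
  count as distinct molecules (slightly inflating, never redirecting,
  support).
* shRNA recognition in step-1 pool QC is exact-match; highly degraded
  hairpin reads land in the `unmatched` bin.
* The collision tie rule discards both molecules; with very low
  duplication (every record dup_count 1) chimera resolution removes both
  reads of each collision.
* The empty-cassette caller counts any read matching the variant anchor;
  it does not model cross-talk from doubly mutated main-anchor reads
  (probability ~(ε/3)² per read).
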