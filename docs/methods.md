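# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic-data generators emulate, and what the test
suite does and does not demonstrate about real data.

## Ratio meta-analysis

Treated/control expression ratios are averaged on the **linear ratio
scale**, not the log scale: per-time-point arithmetic means over
experiments, then the arithmetic mean of the per-time-point means. This
two-level scheme weights time points, not individual measurements, equally,
and it is the convention that reproduces published derived average-ratio
columns from their per-time-point inputs. Missing values are excluded from
whichever mean they would enter; a gene with no values at all is dropped
and logged.

Display rounding is two decimals with ties away from zero (6.945 → 6.95).
Note that two-decimal printed inputs cannot always reproduce a mean that
was rounded from unrounded source data: a printed pair averaging to an
exact half-digit (x.xx5) may round either way depending on digits the
print has discarded. The worked-example fixture therefore asserts only rows
that are self-consistent at printed precision.

Regulation cutoffs are inclusive and configurable: induced at mean ≥ 2.0,
repressed at mean ≤ 0.5. Only the repressed cutoff has a published
anchor in this analysis chain; 2.0 is its reciprocal and consistent with
every induced entry in the reference tables, so it is the default rather
than an option.

The per-gene **meta score** is pluggable. The default —
Σₑ|log₂ rₑ| × #{e : |log₂ rₑ| ≥ 1} over per-experiment mean ratios —
rewards strong and consistent regulation, is symmetric in induction and
repression, and is deliberately documented as a stand-in: it does *not*
reproduce the meta-statistic column of the published tables, whose formula
is defined in prior work and can be supplied as an alternative scorer.
It returns NaN below two experiments.

## Core-set extraction

Gene lists are compared by normalized (upper-cased) identifier only; no
probe-to-gene remapping is attempted because the inputs are already
gene-level lists. The induced rule is at-least-k (default 3 of 4); the
repressed rule is exact-k with k = 2, reflecting that consistently
repressed genes are rare enough in practice that no gene reaches three
lists. Because "all transcripts listed in the source datasets" is ambiguous
as a denominator, `core_fraction` reports both the union-based and the
summed-list-size denominator. Venn rendering is deliberately not part of
the computational contract; the partition table is.

## Differential expression

The equal-variance Student t-test is the default; spreadsheet pipelines —
the historical home of this analysis — default to it, and Welch is
available behind a flag. Fold change is 2^(difference of log2 means), not
the ratio of linear means; with log-normal noise the former estimates the
median fold change and is the standard choice for RMA-scale data. Genes
with zero variance in both groups get p = 1 when the means are equal
(constant data carry no evidence) and p = 0 otherwise (an exact difference
against zero noise).

BH q-values implement the step-up rule directly: q(i) = min over j ≥ i of
p(j)·m/j on the ascending sort, clipped to 1, mapped back to input order.
The implementation is cross-checked in tests against an O(m²)
min-over-suffix oracle and against statsmodels.

A **QC gate** (`qc_expression_matrix`) excludes datasets whose replicates
do not agree: the mean pairwise Pearson correlation of log2 profiles within
each group must reach a threshold (default 0.5, deliberately permissive —
real replicate correlations on RMA data are typically > 0.9, while a failed
treatment arm is near 0). Failing datasets are excluded with a logged
reason, never silently processed.

The conserved-regulation join counts a core gene as conserved when **any**
of its orthologs is significant *and induced* in **at least one** rice
dataset — induced-only, because the core set it is applied to is the
induced one.

## Orthology

"Query the other database with the top results until the original protein
is no longer the top hit" is implemented as a prefix walk with
stop-at-first-failure: forward hits are visited in rank order and the walk
ends at the first subject whose top reverse hit is not the original gene.
A filter-all variant (keep every reciprocal hit regardless of failures in
between) is available for sensitivity analysis. Ranking is total and
deterministic — descending bit score, then ascending E-value, then
lexicographic subject ID — and self-hits are removed before the reverse
"top hit" is determined. A subject absent from the reverse table fails
reciprocity (and stops the walk) rather than being skipped, since absence
of evidence cannot support orthology. Identifiers are opaque; only exact
duplicates are collapsed. Merging two ortholog sources reports the pair
Jaccard-style overlap |both| / |union|.

## Motif scanning and enrichment

Scanning is exact degenerate matching (no position-weight scoring): a
window matches when every base lies in the corresponding IUPAC class. The
sequence character N matches nothing — including the motif symbol N, which
stands for "any unambiguous base". Overlapping occurrences are counted by
default because the AT-rich candidate elements (TATATATA and relatives)
overlap themselves heavily; excluding overlaps would silently shrink their
counts. Scanning is forward-strand by default — candidate elements are
reported as written, and a fixed documented strand convention is required
for reproducible motif lists — with `strand_mode="both"` adding the
reverse complement (note a palindromic site then counts twice, once per
strand).

Fold enrichment is the ratio of per-bp occurrence rates between sets
(identical to occurrences-per-promoter when windows share the nominal
1000 bp length, and length-normalized when they do not). Zero target
occurrences give fold 0; positive target with zero control occurrences
gives +inf. The primary p-value is the one-sided exact hypergeometric tail
on the presence/absence 2×2 table; a per-occurrence binomial test is
reported alongside, because published practice does not say which of the
two a given p-value is. **Selection** mirrors that practice: raw p ≤ α
(default 0.05) and occurrence fold ≥ 2, with at least one target
occurrence; no multiple-testing gate is applied to selection, but BH
q-values over the screened family are always emitted as an honesty column.
The consensus screen additionally flags motifs with p in (0.05, 0.06], a
borderline band worth reporting.

The octamer screen enumerates windows rather than motifs: every valid
8-mer window whose central dinucleotide matches (and which contains no N)
increments exactly one of the 4096 counters, which yields the conservation
identity Σ counts = #centered windows used as a structural test, and makes
the screen O(total sequence length) regardless of the motif family size.

Logos are occurrence-weighted position frequency matrices over all matches
of the chosen motifs in the target set; information is 2 − H(column) bits
with no small-sample correction, matching a plain base-frequency reading
of the column rather than a bias-corrected information claim.

## Synthetic data

Generators are pure functions of a `SimulationSpec`; one global seed fans
out to per-generator substreams keyed by stable labels (CRC32 of the
generator name), so adding a generator never shifts another's stream.
Defaults encode the study conditions the pipeline targets: four ratio
experiments with two time points; expression designs of 3 vs 3 replicates,
200 genes, 10% planted at log2 fold change 2 with noise SD 0.25 (log2);
promoter sets of 65 targets vs 103 controls, 1000 bp, base composition
(0.3, 0.2, 0.2, 0.3) — the ~60% A+T typical of plant upstream regions.
Planted motifs overwrite background at a uniform position (length
preserved); planting rates are per-promoter Bernoulli. Hit-table topology
plants a reciprocal prefix of configurable length followed by decoys whose
reverse top hit is a different gene.

What the generators do **not** emulate: probe-level microarray artifacts,
correlated noise across genes, dimer/repeat structure of real promoters,
positional bias of real *cis*-elements (planting is uniform), paralog
families blurring reciprocal hits. Passing the recovery suites therefore
demonstrates correctness of the operations and adequate power under clean
planted signal — not that real TAIR promoter sets would yield any
particular motif list. In particular, the published headline enrichment
figures for real promoter sets (ECRM ≈ 2-fold, combined motifs ≈ 3.5-fold)
depend on sequence sets that are not constructible offline and are out of
scope of the test suite; the planted-recovery and conservation properties
stand in for them.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale sizes chosen so each check is
statistically meaningful: the exact-test oracle is exhaustive over all 2×2
tables with set sizes ≤ 30 (245 025 tables, float agreement to 1e-9); BH is
checked at m = 1000 against the quadratic oracle; planted-octamer recovery
uses 100 replicates at the default 65/103 × 1000 bp geometry; the null
calibration uses 1000 genes. Ties in hit ranking are broken
deterministically as described; q-values are clipped to 1; information
content uses 0·log 0 = 0. Gene identifiers are compared case-insensitively
everywhere.

## Known limitations

- The default meta score is a stand-in; published meta-statistic columns
  cannot be reproduced from the two-time-point ratio inputs alone.
- Enrichment p-values assume promoters are independent; shared promoter
  structure between homologous genes violates this mildly.
- The octamer screen fixes the octamer length at 8 and the center at
  positions 4–5; other geometries require the generic consensus screen.
- `strand_mode="both"` merges counts; it does not deduplicate palindromic
  self-overlaps.
- The QC gate is a coarse replicate-agreement check, not a substitute for
  platform-specific quality metrics.
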