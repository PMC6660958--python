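# Methods

This note records the models, conventions and numerical choices behind
`slinet`, and what its synthetic benchmarks do and do not demonstrate.

## Humanization of the yeast interaction network

SGA screens report, per ordered gene pair, an interaction score ε and a
P-value. Strongly negative ε indicates a synthetic-lethal-like negative
interaction. The filter keeps records with ε < −0.2 **and** P < 0.05; both
comparisons are strict, so records exactly at a boundary are dropped. A
single stringent cutoff is applied to all records — no relaxed threshold for
interactions seen in reciprocal screens — and filtering runs before
translation (cheaper, and independent of it).

Translation is three-stage (yeast gene → yeast protein → human protein →
human gene). The middle stage uses the strict one-to-one ortholog map: only
clusters with exactly one member per species qualify, and, defensively, any
protein appearing in more than one qualifying cluster is discarded so the
result is always a bijection. Inparalog scores are parsed and carried on the
cluster type but do not influence filtering — one-to-one is a multiplicity
criterion, and no score threshold is applied before it (scores are exposed
for future use). Yeast systematic names are upper-cased before joins; human
symbols are used verbatim. An identifier that is ambiguous in a bridge file
(one key, conflicting values) is dropped by the reader, keeping it
unresolvable rather than arbitrarily resolved.

Records with any unresolvable endpoint, and pairs whose endpoints translate
to the same symbol, are dropped. Duplicate/reciprocal records for one human
pair collapse to a single undirected edge. The retained edge attributes come
from the record with the most negative ε, ties broken by smaller P, then by
first occurrence; the first two keys make the outcome independent of record
order except under exact ties. The dedup *counts* are unaffected by this
rule; only which duplicate's attributes survive depends on it, and a
deterministic rule is required for reproducible output.

## Paired differential expression

Inputs are already RSEM gene-normalized; no re-normalization is done. Zeros
are treated as missing measurements, not biology, so a gene is analyzed only
if every tumor and every normal value is strictly positive across all
patients. Shapiro–Wilk normality fractions per tissue are computed as a
diagnostic only (constant vectors are indeterminate and excluded from the
denominator); the pipeline uses the rank test regardless of the outcome.

The test is the two-sided Wilcoxon signed-rank on per-patient pairs. Zero
differences are dropped before ranking (classic Wilcoxon). The null is
evaluated exactly by exhaustive sign-flip enumeration (scipy's permutation
machinery, midranks for ties) up to effective n = 13, by the standard exact
distribution up to n = 25 when |differences| are tie-free, and by the normal
approximation with continuity correction otherwise. All differences zero
yields P = 1 with a degeneracy flag. Benjamini–Hochberg runs once across all
genes surviving the zero filter (statsmodels' step-up implementation).

Fold change is the mean over patients of log2(tumor/normal) — the mean of
per-patient log ratios, **not** the log of a ratio of means; with
multiplicative noise this makes planted log2 effects directly interpretable.
A gene is called down iff mean log2 ratio ≤ −1 and adjusted P < 0.05 (up
symmetrically); the fold-change boundary is inclusive, the α boundary strict.

The unpaired mode (independent cohorts, e.g. other cancer types) uses the
two-sided Mann–Whitney U per gene, exact when both groups have ≤ 8 tie-free
samples, with direction from the group medians. A cancer type shares the
panel signature when at least `min_down` (default 8, i.e. strictly more than
7 of a 15-gene panel) panel genes are significantly down.

When a combined matrix is read, samples are paired by TCGA-style barcode:
the last dash-separated field's leading two characters are the sample-type
code (01 tumor, 11 normal); patients lacking either tissue are dropped, and
among multiple aliquots of one type the lexicographically first column wins
(deterministic).

## Subnetwork, comparison, drug response

The disease subnetwork keeps every network edge with ≥ 1 down-regulated
(seed) endpoint. Seed–seed edges are kept and counted once — necessary for
node/edge arithmetic to be self-consistent — and a seed with no incident
edge is excluded entirely, preserving the no-isolated-nodes invariant of the
parent graph.

Network overlap is an exact set intersection of canonicalized unordered
symbol pairs (upper-cased, sorted, self-pairs dropped); attributes are
ignored because predictions, not scores, are being compared. Harmonization
drops edges with any endpoint not labeled one-to-one; a gene absent from the
multiplicity table counts as non-one-to-one.

Drug stratification cuts at the arithmetic mean of marker expression, with
values exactly at the mean assigned to the low group (a deterministic
convention; the cutoff rule is unit-agnostic). The IC50 comparison is a
two-sided Mann–Whitney U (sidedness is a parameter), exact for small
tie-free groups. IC50s are compared on the scale given in the input
(GDSC-style tables use natural-log µM); no re-transformation, since the rank
test is invariant to monotone transforms. Dose–response output is
aggregation only (group mean ± SE of published survival percentages per
concentration, SE = 0 with a flag for single-line groups); no 4PL curve
fitting.

## Synthetic-data generators

The generators define the benchmark conditions:

* **GI tables** — a chosen fraction of unique gene pairs is planted strong
  (ε ~ U(−1, −0.25), P < 0.049 drawn as a decreasing function of |ε| with
  multiplicative noise); the rest fail at least one cutoff by construction
  (either ε > −0.2, or strong ε with P ≥ 0.05). A fraction of strong pairs
  additionally appears as a swapped reciprocal record. Base records are
  unique unordered pairs, so the generator rejects requests beyond C(n,2)
  base records; reciprocal duplicates are extra rows on top.
* **Ortholog resources** — a planted one-to-one core plus distractor
  clusters cycling through 1×2, 2×1, 2×2, 1×3, 3×1 shapes; bridges are
  consistent functions covering every clustered protein.
* **Paired expression** — per-gene log-normal baselines (log-mean ~
  N(log 300, 1), patient scatter 0.7 on the natural-log scale); tumor =
  paired normal × 2^(planted effect) × 2^N(0, σ). Multiplicative log-normal
  noise matches positive continuous RSEM-style values and makes per-patient
  log2 ratios Gaussian around the planted effect. Zeros are sprinkled
  missing-at-random per cell.
* **Drug screens** — marker ~ N(5, 1), IC50 ~ N(3, 1) on the log scale, with
  the planted shift subtracted for lines at or below the mean marker; per-dose
  survival follows a logistic curve around each line's IC50.

Default end-to-end conditions: 120 yeast × 120 human genes with a 60%
one-to-one core, 400 GI records (50% strong, 30% reciprocal), 200 expression
genes × 100 patients with 10 genes planted at log2FC −2 and σ = 0.2, and a
200-line screen with a 3-SD IC50 shift. The per-cell zero rate defaults to
0.002, which removes roughly a third of genes under the all-patients
non-zero rule at 100 patients — the proportion observed in real paired
tumor/normal cohorts. Planted down genes are drawn preferentially from
predicted network nodes so the subnetwork stage is exercised.

What the generators do **not** emulate: genome-scale screen structure and
SGA batch effects, correlated gene expression, tumor purity, dose–response
measurement error structure, or realistic identifier vocabularies. Passing
recovery tests therefore demonstrates the correctness of the filtering,
translation, dedup and testing machinery under the stated noise models, not
performance on real cohorts.

## Problem sizes and reproducibility

The test suite and the acceptance script run at desk scale: calibration uses
200 genes × 100 patients × 20 null cohorts and 100 null/100 planted drug
screens; exhaustive test-statistic enumeration is checked up to 2^13 sign
assignments and C(12,6) relabelings. All randomness flows from explicit
seeds through `numpy.random.default_rng`; identical seeds give byte-identical
outputs, and all writers emit deterministically sorted files, so full reruns
are byte-reproducible (verified file-by-file in the tests).

Because planted down genes can legitimately be removed by the zero filter
(zeros are missing-at-random), end-to-end sensitivity is measured among
planted genes that survive the filter; the filter itself is verified exactly
against a brute-force scan.

## Known limitations

* Supplementary-style tables are read from XLSX/TSV/CSV; the legacy binary
  XLS dialect is not parsed.
* The raw-table rebuild path assumes pre-translated human gene pairs with
  ε/P columns; provenance columns beyond those are passed through untouched.
* The pipeline driver computes Shapiro–Wilk fractions only on request
  (`run_normality`), since they are diagnostic and dominate runtime on large
  matrices.
* `query_orthologs` reports proteins lacking a gene-symbol bridge entry by
  accession rather than omitting them, which favors visibility over symbol
  purity.
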