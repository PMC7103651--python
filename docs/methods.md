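# Methods

## Screening model

`icpscreen` operationalizes a two-criterion definition of an
immune-checkpoint-related gene (ICPRG) in a paired tumor/normal FPKM
cohort: a gene is a candidate when it is (i) co-expressed — Pearson
correlation strictly above τ — with at least one known checkpoint gene,
and (ii) upregulated at least φ-fold (inclusive) over matched normal
tissue within the screening stratum.  The surrounding stages (marker
stratification, paired differential expression, seeded networks, set
partition, stacked gene-set scores, gradient dose-response) prepare and
contextualize those two numbers per gene.

### Stratification

A tumor is marker-positive iff its marker FPKM strictly exceeds θ
(default 1.0).  Published interval notation of the form "FPKM > 1" /
"FPKM < 1" leaves the boundary undefined; we fix **strict positivity**, so
a marker value of exactly θ is negative.  The marker is always read from
the tumor sample, never the matched normal.

Gradient bins are **lower-inclusive half-open intervals** covering the
whole non-negative line.  The default edges (5, 2, 1, 0.5, 0.01) yield
[5, ∞), [2, 5), [1, 2), [0.5, 1), [0.01, 0.5), [0, 0.01): printed bin
labels such as "4.9–2" or "< 0.009" contain gaps (4.9–5, 0.009–0.01) that
the half-open convention closes, and every tumor falls in exactly one bin.

### Paired differential expression

* Fold change = (mean tumor FPKM + c) / (mean matched-normal FPKM + c),
  a ratio of stratum means rather than a mean of per-pair ratios — robust
  to near-zero normals.  The pseudocount c (default 1 FPKM) bounds folds
  for zero-expression genes; at c = 0 the fold is scale-equivariant.
* Significance: two-sided paired *t* test on log₂(FPKM + c) within-pair
  differences.  The paired design demands a paired test and the log scale
  stabilizes FPKM variance.  Degenerate inputs use the limit conventions:
  all-zero differences → p = 1; identical nonzero differences (s → 0 with
  a nonzero effect) → p = 0.
* Multiple testing: Benjamini–Hochberg step-up (via statsmodels), with the
  usual monotonization; q-values are a non-decreasing function of p rank
  and never exceed 1.
* The landscape filter partitions the universe into expressed-and-DE
  (mean FPKM > 1 and q < 0.05), expressed-not-DE, and low.

### Co-expression networks

Correlations are computed on log₂(FPKM + c) by default (linear-scale
Pearson on FPKM is dominated by high-abundance outliers; a config flag
restores the linear scale).  The gene universe per condition is genes with
mean raw FPKM above `universe_min_fpkm` (default 1) across the condition's
samples.  Edges require cc **strictly** above τ and, by default, must
touch a seed gene (depth-1 seeded neighborhoods, matching networks drawn
around the marker and the known checkpoint genes); an all-pairs mode
exists for set-level analyses.  A constant vector has an undefined
correlation; it is flagged as missing (NaN) and can never pass a
threshold, so zero-expression genes cannot acquire spurious edges.  Hub
genes are nodes whose supra-threshold degree strictly exceeds
`hub_degree` (default 45; analyses of smaller seeded networks may use 70
or any other value via config).

### The screen

Partnership with a single checkpoint gene suffices (different candidates
legitimately partner with different checkpoint genes).  The fold criterion
is inclusive: "a minimum 2-fold" admits exactly 2.0.  Known checkpoint
genes and the marker are excluded from candidacy.  Two optional flags
(off by default) let a marker edge satisfy the partnership criterion and
require candidates to share the marker's connected component.

The pipeline builds the screening network over **all tumor samples** by
default (`screen_condition: all_tumors`), while the fold-change criterion
stays within the positive stratum.  Rationale: with the generator's
two-level latent activity, activity is nearly constant *within* a stratum,
so a within-stratum network carries no co-expression signal; the
cross-stratum contrast is what links the module.  On real cohorts with
continuous within-stratum activity, `screen_condition: positive` restricts
the network to positive-stratum tumors.

### Gene sets and gradients

Stacked scores are plain per-sample sums of raw member FPKM ("stacked
FPKM"), compared between strata by a fold of pseudocounted means and an
unpaired two-sided *t* test on the log scale (unpaired because the two
strata are different patients).  Gradient profiles use unweighted per-bin
arithmetic means of raw FPKM (one point per bin, six by default); the
dose-response statistic is the Pearson cc between a gene's per-bin means
and the marker's, requiring at least three non-empty bins, with genes
flagged when cc strictly exceeds `gradient_cc_floor` (default 0.94).

## Synthetic cohorts

The generator emulates the statistical structure the screen assumes with a
single latent factor.  Each tumor s carries a dimensionless activity a_s;
matched normals have a = 0.  For gene g,

    log2(FPKM + c) = mu_g + beta_g * a_s + eps,  eps ~ N(0, sigma^2),

back-transformed with the pseudocount subtracted and floored at 0 (FPKM is
non-negative).  Module genes — the six checkpoint genes, the planted
candidates (default IFI30, GBP1, GBP4) and optionally further induced
genes — share one loading β (default 2, i.e. a 4-fold noise-free effect);
background genes have β = 0.  The marker shares β but sits on a fixed
0.1-FPKM baseline, so noise-free active tumors (≈ 3.4 FPKM at β = 2)
clear the θ = 1 threshold and inactive tumors stay below it.  Defaults:
40 pairs, 40 % of tumors active (two activity levels, 1 and 0),
baselines μ_g ~ U(2, 7) on the log₂ scale (≈ 3–130 FPKM), σ = 0.5.
The gradient variant draws activity from n evenly spaced levels
(near-equal bin occupancy); at two levels it reduces exactly to the
two-level cohort, seed for seed.

One `numpy` generator seeded with `rng_seed` governs all draws in a fixed,
documented order (baselines, activity permutation, noise matrix), so
cohorts are bit-reproducible.

Analytic consequences used by the tests: the noise-free pseudocounted
fold of a module gene in active tumors is exactly 2^β; on the log scale
every module gene is an affine function of activity, so noise-free
correlations are exactly 1; because loadings are shared, noise-free
*raw-FPKM* per-bin means are affine in the marker's, so gradient
correlations are exactly 1 as well.  In a mixed tumor population with an
active fraction p, the population correlation between two module genes is
β²p(1−p) / (β²p(1−p) + σ²) — at β = 2, σ = 0.5, p = 0.4 this is ≈ 0.79,
deliberately close to the τ = 0.8 threshold, which is why screen
partnership across six checkpoint genes (not any single edge) is the
operative criterion at that operating point.

### What the generator does *not* model

Library-size or gene-length artifacts, count noise at low abundance, batch
effects, per-patient baseline effects (pairing is statistically neutral
under the default model), continuous within-stratum activity, and
correlated background structure.  Passing tests therefore demonstrate that
the pipeline's logic and conventions recover a planted single-factor
module under realistic noise — not that any particular real cohort will
yield the same gene lists.

## Numerical choices

* All thresholds are strict except the screen's fold criterion (≥ φ).
* Text round-trips are bit-exact: floats are written in shortest
  round-trip decimal form and re-parsed with correctly rounded conversion.
* Edge lists are canonicalized (geneA < geneB lexicographically, sorted)
  for deterministic diffs; GraphML carries cc as an edge attribute; SIF
  uses the relation token `coexp` and drops cc by design.
* Pipeline artifacts contain no timestamps and use sorted JSON keys, so
  identical config + inputs produce byte-identical output.
* Validation happens at construction: duplicate IDs, negative or
  non-finite abundances, half pairs (a pair_id with only one tissue),
  multiple marker genes and out-of-range thresholds are all rejected with
  the offending identifier named.

## Problem sizes

The test-suite and acceptance-script cohorts are sized for a desk run:
recovery experiments use 20 replicate cohorts of 40 pairs with a 20-gene
module and 1000 background genes (β = 2, σ = 0.5); global-null
calibration uses 50 replicates with 300 background genes; gradient
experiments use 120 pairs over six bins.  These sizes give Monte-Carlo
standard errors well below the margins being checked while the whole
suite runs in well under a minute.

## Known limitations

* The per-gene test is a paired *t* on log-transformed FPKM, not a
  count-model test; with very few pairs (< ~5) its p-values are rough.
* Depth-1 seeded networks cannot discover module structure that never
  touches a seed; use the all-pairs mode for exploratory work.
* The gradient statistic correlates six means; with empty or tiny bins it
  is fragile by construction and the code enforces ≥ 3 usable bins.
* Exact reproduction of published per-gene p-values from the motivating
  cohort is out of scope: the underlying data are access-restricted and
  the original test behind those values is unnamed.
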