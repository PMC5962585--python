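# Methods

## Model and procedure

`blocktx` treats a merged compendium of differential-expression
experiments as a single rectangular matrix X of log2 fold-changes, rows =
RNAs, columns = experiments, with missing cells allowed (an RNA not
measured in a study, or a reference experiment without a ratio). Two
partitions are extracted from X with the same algorithm applied to the two
axes, and all downstream statistics are defined over those partitions.

### Pairwise-complete correlation and the significance gate

For any two profiles, Pearson r is computed over the jointly non-missing
observations; the overlap count n is tracked per pair. A pair with fewer
than `min_overlap` (default 3) complete observations, or with a constant
member, is *undefined*: it is flagged, never imputed, and always fails the
gate. Two-sided p-values for H0: r = 0 use t = r·√((n−2)/(1−r²)) with
n − 2 degrees of freedom; the gate passes a pair when its Bonferroni-
corrected p (multiplier = number of defined off-diagonal upper-triangle
pairs) is ≤ α (default 0.01). The base test against r = 0 is a
convention; the gate is configurable (`correction="none"`, α), and
because the correlation threshold dominates at realistic overlaps the
clustering is insensitive to the exact choice except at very small n.

### Clique-constrained agglomeration

Agglomeration is greedy and best-first: at each step, among all admissible
cluster pairs, the pair with the best linkage value merges. Complete
linkage (default) scores a merge by the *minimum* cross-pair r; `average`
and `single` variants are provided for robustness checks. Admissibility is
the clique constraint — every cross pair must have defined r strictly
greater than the threshold (default 0.5) *and* pass the gate — so every
emitted cluster satisfies, pair by pair, the membership condition; this is
asserted post hoc in the tests. The procedure is partitional by
construction (no dendrogram): when no admissible merge remains, clusters
of size ≥ 2 are emitted and everything else is a singleton.

Determinism: exact ties on the linkage value are broken by the
lexicographically smallest combined member-id tuple. Cluster numbers are
assigned at the first merge that creates a cluster and inherited as the
cluster grows (when two numbered clusters merge, the smaller — earlier —
number survives), so numbering reflects creation order, possibly with
gaps. Raising the threshold can only refine the partition; this
monotonicity is a tested invariant.

### Quantile normalization variants

Two column-normalization variants exist to check that clustering is not
driven by per-experiment fold-change distributions. The *rank* method is
classic quantile normalization: each column's values are replaced by the
cross-column mean quantile curve at their midrank quantiles; columns with
unequal non-missing counts are mapped through interpolated quantiles. The
*spline* method fits a monotone smooth from each column onto the reference
curve — implemented as a PCHIP interpolant through a matched-quantile grid
of ~2√n points anchored at the extremes (monotone by construction, no
smoothing-parameter failure modes) — preserving smooth distortions rather
than forcing identical distributions. Missing cells stay missing in both.

### Consistency sets

Per experiment, the top and bottom ceil(k·m/100) RNAs by fold-change
(m = non-missing count, k ∈ {1, 5, 10} conventionally) are extracted with
deterministic tie handling (stable sort on value, then RNA id). A PSR's
consistently enriched (depleted) set is the intersection of its
experiments' top (bottom) sets; RNAs missing in *any* of the PSR's
experiments are excluded first, since "consistent across the PSR"
presupposes measurement everywhere. Sets nest over k, and adding an
experiment can only shrink them — both tested invariants. Diagnostics
report Spearman rank correlations (experiment count vs combined set size;
up vs down sizes) and a two-sided Wilcoxon matched-pairs test on
(up, down) size pairs; the estimator is configurable to Pearson, and a
degenerate paired test (all differences zero) is reported as p = 1.

### Enrichment, regulation and interactions

Term over-representation is the one-sided hypergeometric tail with BH
adjustment applied within each query set's family of terms; the universe
defaults to the RNAs of the analyzed matrix (not the genome), which keeps
the null honest for compendium-restricted sets, and is configurable. Terms
with fewer than 2 members in the universe are untestable and skipped. An
optional term → broad-category recoding summarizes results by the minimum
adjusted p per category.

TF-sharing coherence uses the Jaccard index of per-gene regulator sets:
within-block coherence is the median over all member pairs, between-block
overlap the median over cross pairs. Nulls are resampled same-size gene
draws from the TF-annotated universe; empirical p-values use
(1 + #{null ≥ observed}) / (1 + n_samples) and are seed-reproducible.
Because the median of pairwise Jaccards is discrete, a coarse regulator
vocabulary ties the statistic and makes this convention conservative
(p-values pile above 0.5 under the null); calibration is exact only when
the statistic is effectively continuous, which the calibration tests make
explicit. Per-TF association uses Fisher's test with a Bonferroni
multiplier covering the full tested grid (#blocks × #TFs) and the network
output keeps edges at adjusted p < 0.01. Edge excess counts interactions
linking two members of the same block, PPI and GI separately (never
pooled), against same-size random draws from the network's gene universe
(or the matrix universe, configurable), same empirical-p convention.
Empty ∩ empty regulator sets score Jaccard 0: such pairs carry no
co-regulation evidence.

### The block-response map

Cells pair blocks of ≥ 10 RNAs with patterns of ≥ 5 experiments. Per
cell: each member RNA's median fold-change over the pattern's experiments
(non-missing only) forms a vector; a two-sided one-sample Wilcoxon
signed-rank test against 0 is applied with zeros dropped, exact
distribution for n ≤ 25 without ties in |values| and the normal
approximation with continuity correction otherwise. Cells with fewer than
4 measured RNAs are `no-data`; an all-zero vector is degenerate and
reported `no-change`. BH runs once, jointly over all performed tests (not
per pattern); cells at adjusted p < 0.05 are labeled by the sign of the
median of the vector. The large-change flag marks (block, pattern, k)
triples where strictly more than half the block's members lie in the
union of the pattern's top/bottom-k% sets; flags nest over k because the
sets do. Display ordering uses average-linkage hierarchical clustering of
Euclidean distances on rows and columns (labels encoded +1/−1/0, or
effect sizes), with NaN treated as 0 for distance purposes.

## The synthetic generator

The generator emulates the statistical shape of a merged multi-study
compendium, not array physics (no dye bias or intensity-level effects —
it works at the log-ratio level, as the analyses do). The model for RNA i
in experiment e:

    x[i, e] = λ·f[b(i), e] + shift(b(i), p(e)) + d[i, p(e)] + batch + ε

- **Blocks**: planted BTR sizes (default 20 blocks spanning 10–30 RNAs,
  plus 100 unassigned background RNAs). f is a per-(block, experiment)
  standard-normal factor shared by the block's members; with noise
  ε ~ N(0, σ²), within-block correlation from the factor alone is
  λ²/(λ² + σ²), so the loading is derived from `target_r` (default 0.8,
  σ = 0.3 ⇒ λ = 0.6). Planted shifts add further correlation on top.
- **Patterns**: planted PSR sizes (default 12 patterns spanning 5–15
  experiments, plus 12 unassigned experiments). Each (block, pattern)
  cell carries a signed shift: sign ∈ {−1, 0, +1} with probabilities
  (0.35, 0.30, 0.35), magnitude = effect (default 1.0 log2, ≈ two-fold)
  jittered by U(0.75, 1.25).
- **Condition-specific signature** d: background RNAs respond per pattern,
  the response shared by the pattern's experiments (unassigned experiments
  draw their own). Its SD is derived so the expected within-pattern
  experiment correlation hits `target_exp_r` (default 0.8) — the
  experiment-axis analogue of `target_r`. Without it, experiment-level
  correlation would be an uncontrolled side effect of the shifts.
- **Identifiable sign map**: within each pattern the factor values are
  mirrored ± pairs (plus a zero for odd sizes), making the factor's
  within-pattern distribution symmetric about 0, so the true median
  response of every cell equals its planted shift exactly. A merely
  mean-centred factor leaks a shared offset through the noise–median
  interplay and corrupts the no-change ground truth.
- **Missingness** is completely at random (default 10%); studies default
  to one per pattern (matching the observation that coherent experiment
  clusters are mostly single-study) with optional per-(study, RNA) batch
  shifts (`batch_sd`, default 0).

Companion tables plant one dedicated annotation term per block (covering
80% of members by default) over a background vocabulary, one TF per block
(90% coverage plus uniform background targets at 5%) among 30 background
TFs, and within-block PPI/GI edges at planted densities (0.30/0.20) over
a sparse background (0.005). All outputs are deterministic given the seed.

What the generator does *not* emulate — heavy-tailed fold-change
distributions, platform-dependent noise, correlated missingness beyond
MCAR, overlapping or hierarchical blocks, TF cross-talk — bounds what
passing tests show: recovery results demonstrate correctness of the
machinery under the planted model, not performance guarantees on real
compendia.

## Numerical conventions and edge cases

- Undefined correlations (low overlap, constant profiles) fail the gate;
  they are never imputed.
- Threshold semantics are strict (r > 0.5, flag counts > half).
- Empirical p-values always use the +1 convention; they can never be 0.
- Odds ratios get a 0.5 continuity correction only when a cell of the
  2×2 table is 0, for display.
- Sub-minimum structures (blocks < 10 RNAs, patterns < 5 experiments,
  terms < 2 universe members) are excluded before testing, not after.
- Matrix parsing accepts "", "NA", "NaN" (case-insensitive) as missing;
  the PCL dialect drops NAME/GWEIGHT columns and EWEIGHT rows; merges
  require globally unique experiment ids, with optional
  `<dataset>:<experiment>` prefixing.

## Problem sizes

The test suite and the acceptance script use the default scenario
(500 RNAs × 132 experiments), a 3000-cell null map (600 × 250) and 200
resampling replicates of 100 draws each — sizes at which every
calibration target has comfortable Monte-Carlo resolution while the whole
suite runs in seconds on a single core. Larger compendia (thousands of
RNAs and experiments) run through the same code paths; the agglomeration
is O(n²) per merge with vectorized updates.

## Known limitations

- The agglomeration order of the original formulation of this clustering
  is not uniquely determined by the method description; our tie-break
  (smallest combined member-id tuple) is one deterministic choice, so
  cluster numberings and borderline memberships may differ from other
  implementations at equal parameters.
- The significance gate tests H0: r = 0, not H0: r = 0.5; with a gate on
  r = 0.5 marginal clusters would shrink. The threshold itself does the
  heavy lifting at realistic overlaps.
- BH families: enrichment adjusts within each query set; the response map
  adjusts jointly over all cells. Both choices are deliberate and
  documented above; switching families changes borderline calls only.
- The spline normalization is a monotone quantile map, not a
  GCV-smoothed spline; it is used for robustness comparisons, not as a
  preprocessing recommendation.
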