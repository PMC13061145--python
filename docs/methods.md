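# Methods

## Cohort definition and body composition

Neonatal fat mass is a linear function of birth weight, flank skinfold and
length (`FM = 0.39055·BW + 0.0453·SF − 0.03237·L + 0.54657` kg); lean mass
and percent body fat follow by identity, so `FM + LBM = BW` holds exactly
for every sample. Maternal BMI bins are closed on their printed endpoints
(lean 18 ≤ BMI ≤ 24.9, obese 30 ≤ BMI ≤ 40); BMI between or outside the
bins excludes the sample. Adiposity tertiles are assigned by rank within
each BMI category: n samples split into ⌈n/3⌉ (T1, low), ⌈(n−n1)/2⌉ (T2)
and the remainder (T3, high), with ties broken by stable sample-id order.
Rank splitting (rather than quantile thresholds) guarantees achievable group
sizes for any n — 59 lean-stratum samples split 20/20/19, matching the
intended design. If every percent-body-fat value is identical no ordering
is meaningful and all samples are labelled T2 (excluded), deterministically.
Tertile labels are invariant to strictly monotone transforms of percent
body fat, which the tests enforce.

The cohort summary uses two-way ANOVA (maternal obesity × neonatal
adiposity) with type-II (partial) sums of squares because the design is
unbalanced, Tukey HSD grouping letters via a compact-letter-display
insert-and-absorb pass, and Fisher's exact test for categorical variables —
scipy's 2×2 test, or a Freeman–Halton enumeration over all tables with the
observed margins for larger tables (feasible at cohort scale, ~10⁴ tables
for a 2×4 with n ≈ 80).

## Differential-expression engine

The engine is a deliberate approximation of the standard count-based DE
stack, not a port of it:

* **Size factors** — median-of-ratios over genes positive in all samples.
* **Dispersion** — gene-wise method of moments on normalized counts,
  `α_g = max(10⁻⁸, (s² − m̄)/m̄²)`, with an optional (off by default)
  halfway log-space shrink toward a fitted `a₀ + a₁/mean` trend. No
  empirical-Bayes sharing, independent filtering or outlier replacement:
  the bootstrap-consistency layer, not per-fit refinement, carries the
  robustness burden, and gene-level numbers will differ from any
  empirical-Bayes implementation.
* **Model** — per-gene NB regression with log link, offset log size factor,
  design (intercept, adiposity HA=1, sex M=1 with female reference), fit by
  IRLS vectorized across genes (batched 3×3 weighted normal equations).
  Convergence is a deviance change below 1e-8 (relative, floored) within
  100 iterations; linear predictors are clipped at ±30 and fits with any
  |coefficient| > 20 (separation, all-zero genes) are flagged
  non-converged and carry NaN statistics rather than fabricated values.
  Wald z = β/SE with a two-sided normal p. In the α→0 limit the fit agrees
  with a Poisson GLM (cross-checked against statsmodels in tests), and on
  deterministic two-group counts the coefficient equals the log2 mean
  ratio.
* **PCA outlier screen** — samples are projected onto the first two
  principal components of log2(normalized+1) expression over the 500 most
  variable genes; a sample is flagged when its MAD-scaled distance from the
  coordinate-wise median exceeds k = 5. The criterion (top-500, PC1–2,
  5×MAD) is this package's own convention for an otherwise unspecified
  screen; it flags nothing on homogeneous data in tests and catches
  profile-distorted samples.

## Bootstrap selection

Resampling is with replacement, stratified within the LA and HA classes and
preserving class sizes, so the adiposity factor is estimable in every
iteration (unstratified pooled resampling is available behind a flag). An
iteration counts a gene significant when it converged with p < .05 and
linear |FC| > 1.5 — interpreted on the linear scale, i.e. |log2FC| >
log2(1.5) ≈ 0.585, the conventional reading and consistent with retained
genes at |median log2FC| ≈ 0.8. A gene is retained iff its majority
direction is significant in ≥ 50% of **all** B iterations (denominator B,
not the significant subset; the alternative is a flag). Exact ties
(n_up = n_down) are rejected as directionally inconsistent. Median log2FC
and median p are computed over all converged iterations by default
(significant-only behind a flag); non-converged iterations count as
non-significant and are excluded from medians. Selection is monotone in all
three thresholds, which a test asserts on real bootstrap output.

## Overlap, enrichment, network, validation

CNAAGs are the gene-id intersection of the two strata's NAAG sets,
concordant iff directions agree; unique sets are the set differences, and
the three pieces partition the NAAG union. Over-representation is the
one-sided hypergeometric tail `P(X ≥ k)` per term with BH adjustment across
terms (BH chosen as the standard FDR step-up; terms are flat gene sets from
GMT, with no ontology-hierarchy propagation). The enrichment universe
defaults to all genes surviving filters in the analysis.

Network edges come from a 3-column (node1, node2, combined_score) list,
canonicalized (lexicographic endpoint order, self-loops dropped, duplicates
collapsed to the maximum score) at a default combined-score cutoff of 400
(medium confidence). Edge confirmation is Pearson correlation of
log2(normalized+1) expression within the requested sample group, p from the
t transform with n−2 df, confirmed iff |r| > 0.3 and p < .05; unconfirmed
and zero-variance edges are retained unconfirmed for context. For the
common-gene network, correlations are computed within LE, within OB and
pooled, and all three are written. Hubs strictly exceed the interpolated
90th degree quantile, so a degree-regular graph has none. Interaction
enrichment replaces any database-internal background model with an
equal-size permutation null over the analysis universe:
`p = (1 + #{null ≥ observed})/(M + 1)` at M = 999, seeded; tests verify it
against an exhaustive null on enumerable universes.

Reference profiling z-scores each gene's expression across cell types
(zero for uniform rows) and reports the arg-max type; genes absent from the
reference are listed, not fatal. qPCR relative expression is
`2^(Ct_ref − Ct_target)` under assumed amplification efficiency 2 (the
efficiency is a parameter). Group comparisons use a Wilcoxon rank-sum test,
exact by enumeration of all C(n₁+n₂, n₁) mid-rank assignments up to
combined n = 20 and a tie- and continuity-corrected normal approximation
beyond; the paired signed-rank variant is provided separately for paired
designs. Spearman correlation is Pearson on mid-ranks with an exact
permutation p up to n = 8 and the t-approximation beyond; constant inputs
are flagged undefined (NaN) rather than coerced.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design: groups LELA/LEHA/OBLA/OBHA of
20/19/20/20 plus 20 middle-tertile samples per stratum (so tertile
assignment is exercised end-to-end), sex Bernoulli(½), and NB counts with
mean `depth · baseline · 2^(x·β)` and variance `μ + αμ²` (gene-wise or
scalar α, default 0.1). Size factors are log-uniform on [0.5, 2] —
a realistic library-size spread; the true depth distribution of any given
experiment is not modeled. Baselines are lognormal with median 150 counts
(σ = 1), placing planted genes in the moderately-expressed range where
n ≈ 20 per class yields the power the tertile-extremes design presumes.
Planted adiposity effects are ±1.0 log2FC — beyond the 1.5-fold threshold
with realistic power at n ≈ 20 — in four classes (shared-concordant,
shared-discordant, LE-unique, OB-unique) over a null background; a ±0.2
log2FC sex effect on 5% of genes keeps the sex covariate non-degenerate.
Middle-tertile samples receive half the adiposity effect (covariate 0.5).

Anthropometrics are constructed backwards from percent-body-fat targets
drawn in disjoint windows per intended class (LA ≈ [6, 9.8]%, MID ≈
[10.2, 13.8]%, HA ≈ [14.2, 20]%): birth weight and length are drawn from
class-typical truncated normals and the flank skinfold is solved from the
fat-mass equation, redrawing weight/length when the implied skinfold leaves
[0.5, 20] mm. This guarantees the tertile split recovers the intended
labels; real cohorts have overlapping adiposity distributions, so passing
recovery tests demonstrates correctness of the assignment machinery, not
robustness to boundary ambiguity.

Annotation, network, reference and Ct generators plant one enriched gene
set (80% of shared planted genes plus background), one clique among shared
genes over uniform background edges, one cell type expressing shared genes
at 50× (large enough that lognormal noise leaves it the arg-max type for
>95% of genes), and Ct values `a − b·log2(normalized+1) + noise` with an
adiposity-independent reference gene. All generators are pure functions of
(config, truth) with per-generator child seeds, so identical seeds give
identical outputs.

What the synthetic data does **not** model: gene–gene correlation beyond
the planted effects, GC/length biases, cell-type deconvolution, batch
effects, or count outliers. Recovery results therefore certify the
selection machinery under its stated model, not performance on arbitrary
real data.

## Problem sizes and defaults

Defaults collected in `PipelineConfig`: B = 100, p < .05, linear FC > 1.5,
consistency 0.5, |r| > 0.3, FDR < 0.1, combined score ≥ 400, hub quantile
0.9, PCA k = 5, 999 permutations, mandatory seed. The test suite and the
worked example use 200–300-gene simulations with 20 genes per planted
class — sizes at which each planted class still contains enough genes for
stable sensitivity/false-retention estimates while keeping a five-seed,
B = 100 recovery study a desk-scale computation; the machinery is
vectorized across genes and scales linearly to transcriptome-sized
matrices.

## Known limitations

* The NB engine intentionally omits empirical-Bayes dispersion shrinkage,
  so single-fit p-values are noisier than shrinkage-based implementations;
  the bootstrap layer is the compensating design choice.
* Wald p-values rely on asymptotic normality; at n ≈ 20 per class with
  near-separation they are approximate, and such fits are flagged rather
  than corrected.
* The permutation interaction-enrichment null draws uniformly over the
  universe and ignores degree correction; p-values are not comparable to
  database-internal enrichment scores.
* The Freeman–Halton enumeration and the exact rank tests are exponential
  in sample size and bounded to small inputs by design; larger inputs fall
  back to standard approximations.
* Reference profiling assumes gene symbols match between the expression
  matrix and the reference; no identifier mapping is attempted beyond exact
  symbol equality.
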