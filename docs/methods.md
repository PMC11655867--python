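# Methods

This note documents the models, estimators and design choices behind
`immunocarto`, in the order of the pipeline.

## Normalization

nCounter-style counts carry two per-sample technical scales: assay
efficiency (captured by the positive-control titration probes) and RNA
content (captured by housekeeping probes). Both are estimated as the
geometric mean of the relevant probes and removed in sequence: the
sample's counts are multiplied by
`f_i = mean_j(g_j) / g_i`, first with `g_i` the positive-control
geometric mean, then (on the intermediate matrix) with the
housekeeping geometric mean. Values are floored at 1 and
log2-transformed, so the final matrix is non-negative with exact zeros
below one count.

Two conventions exist for the direction of the factor. The default,
*corrective*, divides the grand mean of geometric means by the
sample's own geometric mean; it satisfies the defining property that
samples which are pure depth rescalings of one another normalize
identically. The mirror-image *literal* convention
(`g_i / mean_j(g_j)`) is also implemented for auditability; it
amplifies rather than removes depth differences and exists only so
that both readings of the procedure can be compared. Note that because
the reference (the grand mean of geometric means) is itself estimated
from the cohort, rescaling one sample moves every normalized value by
one common constant; the per-sample profile shape is exactly
invariant.

A geometric mean over counts containing zero is undefined; such
samples raise an error naming the sample (a configuration option to
add 0.5 before the geometric mean is deliberately not the default).
Negative-control probes are carried through but unused — the procedure
performs no background subtraction.

## Module discovery

Modules are derived by one-vs-rest differential expression of each
reference disease against the other reference diseases on the log2
matrix. The test statistic is a moderated t: per-gene pooled variances
`s²_g` (df `d = n₁+n₂−2`) are shrunk toward a prior fitted by the
standard empirical-Bayes method of moments on `log s²` (prior df `d₀`
from the inverse-trigamma of the excess log-variance spread, prior
variance `s₀²`), the posterior variance is
`(d₀ s₀² + d s²_g)/(d₀ + d)`, and the t statistic is referred to a t
distribution with `d + d₀` degrees of freedom, capped at the pooled df
across all genes. When the observed log-variance spread is no wider
than chi-square sampling noise, `d₀ = ∞` and all variances collapse to
their mean. This implementation reproduces the reference R linear-model
implementation to ~1e-4 relative error on p-values (cross-checked in
the test suite via Rscript). A plain Welch t-test is available as a
configurable fallback.

Genes pass at log2FC > 1 (fold change 2) with BH-adjusted p < 0.01,
up-regulated side only. Both thresholds are configuration; a raw-p
mode exists. The myeloid program cannot be split by a single
one-vs-rest contrast, so when neutrophilic-disease, COVID-skin and
Wells groups are all present, the neutrophilic / macrophagic /
eosinophilic modules are derived by contrasting those three groups
against each other. A gene passing several contrasts is assigned to
the contrast with the largest fold change, making the module lists
disjoint by construction. Manual functional curation is replaced by an
explicit user-supplied exclusion list: reproducibility over editorial
judgment.

## Scores, thresholds, activation, dominance

A module score is the arithmetic mean of the module genes' log2
values in one sample. Per module, a threshold `t_m` is fitted on the
reference cohort as the minimum of a Gaussian KDE (Silverman
bandwidth, 512-point grid) strictly between the two highest density
modes of the pooled scores; ties in mode height break toward the
lower-score mode. If the density is unimodal, or the valley falls
outside the open interval between the module-negative and
module-positive group means, the midpoint of the two group means is
used. Module-positive samples are those whose disease carries the
module at dominant (including co-dominant) level; at least three
positive and three negative reference samples are required.

Activation maps a score to [0, 1] through a logistic anchored at the
threshold: `a(x) = 1/(1+exp(−k_m(x−t_m)))` with
`k_m = ln(99)/min(t_m−min_m, max_m−t_m)`, where `min_m`/`max_m` are
the reference score extremes. This fixes the three properties the
construction needs — `a(t_m) = 0.5` exactly, and the nearer reference
extreme maps to 0.01 or 0.99 — while leaving the score aggregation
itself untouched.

A module is dominant when its activation exceeds 0.5 and a one-sided
bootstrap (module genes resampled with replacement within the sample,
default B = 1000, α = 0.05) puts its score above every other module's.
The bootstrap runs on *reference-centered* gene values (the sample's
log2 value minus the reference-cohort mean of that gene). Raw module
scores differ by several tenths of a log2 unit purely through which
genes landed in each module; comparing centered values tests what the
dominance concept means — which module is most strongly *activated*
relative to its own typical level — and corresponds to the normalized
(activation-scale) plots on which the >0.5 gate is defined. With raw
scores the same calls are made in clearly separated samples but
genuine dominants fail stochastically when module baselines differ;
candidate ordering, and the guarantee that a called dominant is the
maximally activated module, hold on the centered scale. Only the
top-ranked candidate can pass against all others, so ties in score
yield no dominant call. When no module dominates but at least two
exceed 0.5, modules within 30% of the highest activation
(multiplicative, `a ≥ 0.7·max`) are reported co-dominant; a single
module above 0.5 that fails the bootstrap yields status `none`.

## Cartography and classification

The reference map stores the sentinel matrix restricted to a gene set
(module genes by default, full panel as comparator), per-gene z-score
parameters, a complete-linkage dendrogram on 1 − Pearson correlation
between samples, and a 2-D UMAP embedding (default 15 neighbors capped
at n−1, fixed seed; deterministic given the seed). Constant genes are
dropped with a warning. Reference samples are diagnosed by cutting
their dendrogram at the number of diseases and mapping clusters to
diseases by optimal (Hungarian) assignment on the contingency table,
which removes the arbitrariness of majority mapping under ties.

Query samples are z-scored with the reference parameters, transformed
into the fitted embedding, and assigned the majority disease among
their k = 5 nearest reference samples, ties broken by smallest mean
distance to the tied diseases. Because the embedding transform is
approximate for training points, an embedding-free route (k-NN on
1 − Pearson distance in z-space, exactly self-matching and fully
deterministic) is provided and used where exactness matters.
Performance is reported as one-vs-rest precision/recall/specificity
per class and the pairwise Fowlkes–Mallows index.

## Treatment matching

Treatments map case-insensitively to target modules (anti-IL-4RA /
anti-IL-13 → Th2; anti-IL-17A, anti-IL-23 and anti-IL-12/23 → Th17;
JAK1/2 inhibitors → Th1); unknown treatments raise an error rather
than defaulting. Dominance for matching is the argmax of the supplied
module scores *without* the 0.5 activation gate, because published
post-treatment profiles mark dominant modules with scores below 0.5
(e.g. 0.43, 0.38); the stricter gated rule is available and flags such
rows as weak-dominant. Exact score ties give status `indeterminate`,
never an arbitrary pick. Cohort summaries report matched /
non-matched counts split by responder status, the observed response
rate, and the hypothetical rate after excluding non-matched patients.
Paired pre/post rows can be compared for a dominant-module switch.

## Synthetic cohorts

The generator emulates the count structure of a ~600-probe immune
panel. Gene-level parameters are drawn once per seed and shared by
every cohort sampled from the same generator, so sentinel, test,
erythroderma-like and pre/post samples live on one measurement scale:

- endogenous baselines: log2 levels ~ N(6.5, 1.5) (median ≈ 90
  counts); housekeeping ~ N(9, 0.8); positive controls a fixed ladder
  of log2 levels from 5 to 13; negative probes Poisson with mean 2.
- 7 modules × 15 genes plus 480 uninformative background genes,
  15 housekeeping, 6 positive, 8 negative probes.
- disease effects: each module gene carries a planted log2 effect
  ~ N(2.0, 0.5), applied at full strength for a disease's dominant
  module(s) and at a 0.4 fraction for subdominant modules.
- per-sample technical depth: lognormal with log-SD 0.3, multiplying
  every probe including controls (the quantity normalization must
  remove); per-sample per-gene biological noise: log2-normal, SD 0.3;
  counting noise: negative binomial (gamma–Poisson) with dispersion
  0.1 (Poisson when 0).

The default disease panel mirrors the studied cohorts: PsO (Th17
dominant, subdominant neutrophilic + IFN-I), AD (Th2, subdominant
Th1/Th17), LP (Th1), CLE (IFN-I), NeuD (neutrophilic), Wells
(eosinophilic), COVID-skin (macrophagic), BP (co-dominant Th2 +
myeloid), DHR (co-dominant Th2 + myeloid + IFN-I), and healthy skin
(no modules), with sentinel sample sizes LP 12, AD 16, PsO 25, NeuD
10, CLE 12, Wells 3, Healthy 8. Erythroderma-like queries are drawn
from a sentinel disease's generative profile with independent noise;
a module-switch scenario generates paired Th2-dominant pre-treatment
and Th1-dominant post-treatment samples.

What the generator does *not* emulate: batch effects, probe-level
cross-hybridization, background counts correlated with content,
gene–gene correlation beyond the module structure, realistic
inter-patient effect-size heterogeneity, or any histological feature.
Passing synthetic tests therefore demonstrates internal correctness of
the estimators under the planted model, not clinical performance.

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of roughly 80–150 samples
× 614 probes — module discovery at n = 10 per disease, clustering and
classification at the sentinel sample sizes above — sizes at which
every stage completes in seconds except UMAP fitting (tens of
seconds). Determinism: every stochastic step takes an explicit seed
(cohort generation, bootstrap, embedding); fixed seed gives
bit-identical matrices and byte-identical pipeline artifacts. Ties are
broken deterministically throughout (stable sorts; Hungarian
assignment; lower-score mode preference in threshold fitting).
Degenerate inputs raise typed errors (`ConfigurationError`,
`DataError`, `NormalizationError`, `StatisticsError`, `MappingError`)
rather than silently proceeding.

## Known limitations

- The fitted thresholds require each module to have ≥ 3
  module-positive reference samples; a panel without a macrophagic
  disease cannot fit the macrophagic threshold (the pipeline restricts
  scoring to fittable modules).
- The eosinophilic module rests on a 3-sample reference group; its
  threshold and discovery contrasts are correspondingly fragile.
- UMAP's transform of new samples is approximate; the Pearson-distance
  route is exact and preferred when reproducibility across platforms
  matters more than the 2-D geometry.
- Real module gene lists are treated as data (loadable from JSON); the
  package derives lists from expression only and cannot reproduce
  manual functional curation beyond the exclusion-list mechanism.
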