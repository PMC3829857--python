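# Methods

This note documents the statistical models implemented in `psormod`, the
defaults they use, what the synthetic-data generators emulate, and the design
choices made where the procedure left room for them.

## Paired differential expression

The cohort model is a paired lesional/uninvolved (PP/PN) design with study
blocks: for every patient the lesional sample is compared only to that
patient's uninvolved sample, which removes study- and batch-level offsets by
construction. Per gene, the vector of per-patient log2 differences
Δ<sub>i</sub> = PP<sub>i</sub> − PN<sub>i</sub> is tested against a zero
median with the one-sample Wilcoxon signed-rank test. Fold change is
2^(median Δ), so "median FC" is exchangeable with the median of per-patient
PP/PN ratios.

Signed-rank details: zero differences are discarded before ranking
(Wilcoxon's original treatment); tied absolute differences share midranks.
When the number of nonzero differences is ≤ 25 the null distribution of W⁺
is enumerated exactly by a generating-function pass over doubled midranks
(integers, so ties are handled without approximation); otherwise a normal
approximation with tie-variance and continuity corrections is used. Two-sided
p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))).

DEG gates: BH FDR < 0.05 with median FC > 1.50 (increased) or < 0.67
(decreased), and — the per-study consistency filter — the per-study median FC
must lie on the same side of 1 in every study individually. All inequalities
are strict. The direction indicator I is +1 iff median FC > 1; a median FC of
exactly 1 falls back to the sign of the mean log2 difference with ties broken
toward +1 (logged).

Representative-feature selection prefers gene-specific probe sets (excluding
`_s`/`_x` suffixed identifiers) and, among equally specific candidates, takes
the most highly expressed on average; lexicographic probe-id order breaks
exact mean ties. The expression filter keeps genes flagged above background in
at least 10% of samples (inclusive boundary); detection flags are an upstream
contract, not recomputed here.

## Co-expression modules

The keratinocyte/epidermis reference matrix is standardized in two steps:
per-gene centering (so positive values mark above-average expression for that
gene), then per-array z-scoring across genes (mean 0, variance 1 per sample).
Genes are clustered by average-linkage hierarchical clustering on Euclidean
distances, and modules come from a top-down dynamic dendrogram cut with a
minimum module size of 25 genes.

The sub-division criterion is the one genuinely open design choice here. The
rule implemented: a node is split into its two branches when its merge height
is at least 1.4 × the median merge height within its subtree (so the join
stands out from the typical within-cluster joins below it) and at least one
branch meets the minimum size. When only one branch is viable, the undersized
branch's genes are left unassigned (never forced into a neighbor) and descent
continues into the viable branch. Parent-versus-child height-gap rules were
rejected because they fail on dendrograms of many similar-sized modules,
where consecutive between-module joins occur at nearly equal heights; the
median-ratio rule recovers both two-module and twenty-module plants at
adjusted Rand index ≈ 1.0 in the package's simulations and never splits
pure-noise matrices, whose merge heights are nearly uniform.

Module naming follows the `GENE-N` convention: the member with the most GO
biological-process annotations (missing counts = 0, ties lexicographic) plus
the member count. The module medoid is the member profile minimizing the
summed Euclidean distance to all other members — a member object, not a
componentwise median — with distance ties resolved to the lexicographically
smallest gene id. The module fold-change score is the median across members
of the per-gene median FC across patients ("median of medians"); even-length
medians are midpoint means. The landscape ordination reduces the
standardized matrix to its first two principal components (SVD of the
column-centered matrix) and places each module at the median of its member
genes' PC scores; module relatedness is summarized by Euclidean distances
between medoids and an average-linkage dendrogram over them (Newick export).

## Rank-based enrichment (detection-rate-curve area)

Genes are ranked by the signed score I × −log₁₀(p); zero p-values are
clamped at −log₁₀ p = 300 with a warning, and score ties break by gene id so
the ordering is deterministic (the rank order is invariant to the logarithm
base). For a foreground set, the detection-rate curve tracks the cumulative
fraction of foreground genes recovered while walking down the ranking; with
both axes normalized to [0, 1], the statistic is the signed area between the
curve and the diagonal, positive when the foreground concentrates at top
ranks. Because that area is a linear function of the foreground rank sum, its
p-value is exactly the two-sided Wilcoxon rank-sum p comparing foreground and
background ranks; the package computes it directly (exact subset-count
dynamic program when the smaller group has ≤ 12 members and the total is
≤ 2000 — a cost cap — otherwise the normal approximation with tie and
continuity corrections). The test suite verifies the equivalence
bit-for-bit on the exact branch against an independently coded enumeration,
and `scipy.stats.mannwhitneyu` serves as a second, external cross-check.

DEM (differentially expressed module) calls use one BH family across all
modules tested: a module is a DEM when GSEA FDR < 0.05 together with a
fold-change score > 1.25 or < 0.80, or via the proportion route when its
Fisher-exact overlap with the DEG sets reaches FDR < 0.05. Fisher tests use
the conventional two-sided convention (sum of table probabilities not
exceeding the observed table's) and the conditional-MLE odds ratio.
Annotation enrichment is a plain one-sided hypergeometric over-representation
test per term with BH across terms (no ontology-graph conditioning); trait
overlap is the same Fisher machinery across a trait→gene map pre-filtered to
the expressed-gene universe, one BH family across traits.

## Perturbation screens and the moderated t

Small two-group experiments (cytokine stimulations, therapies, RNAi) are
ranked with an empirical-Bayes moderated t. Hyperparameters (d₀, s₀²) are
fitted by moment matching on log sample variances: with e = log s² −
ψ(df/2) + log(df/2), solve ψ′(d₀/2) = var(e) − mean(ψ′(df/2)) by Newton
inversion of the trigamma function, and s₀² from the corrected mean. When the
observed spread does not exceed the sampling floor, d₀ = ∞ (complete
shrinkage); literally constant variances return that constant as s₀². The
statistic uses the shrunken variance s̃² = (d₀s₀² + df·s²)/(d₀ + df) with
d₀ + df degrees of freedom; d₀ = 0 reduces to the ordinary t and d₀ = ∞ to a
fully pooled prior variance (normal reference). Paired designs take a
one-sample moderated t on per-pair differences. Per gene, the feature with
the lowest p wins (ties: larger |effect|, then feature id).

Cytokine hub edges require dual evidence: the detection-rate-curve p and the
Fisher overlap p (against the experiment's responsive sets, unadjusted
p < 10⁻³ per direction) must both clear 10⁻³ with agreeing direction. The
edge tier comes from the weaker of the two p-values: 10⁻³ / 10⁻⁶ / 10⁻⁹.
Responsive-set thresholds are unadjusted p-values; the dual gate is the
multiplicity control.

Methylation bias: M = log₂((methylated + floor)/(unmethylated + floor)) with
a default intensity floor of 1.0 to keep M finite at zero signal. Per-site
paired moderated t on PP−PN M differences, best site per gene, signed
ranking (hyper-methylated genes at top ranks), then the area statistic per
module; modules with no measured members are reported untestable.

## Motif enrichment

The dictionary is deduplicated by first removing motifs shorter than 4 bp,
then dropping any motif whose consensus matches an already retained motif
with mean absolute PPM difference < 0.02; first occurrences win. When a
consensus is absent it is derived from the PPM: per column, the IUPAC code
covering every base with probability ≥ 0.25.

Masking: interval masks (coding sequence, gaps, repeats; BED, 0-based
half-open, clipped with a warning when out of bounds) set bases to `N`.
Conservation masking runs afterwards: the threshold is the median PhastCons
score over still-unmasked bases, capped at 0.70, and bases scoring strictly
below it are masked.

Occurrences are exact IUPAC-consensus matches counted on both strands with
overlaps allowed; a window containing any masked base never matches, and a
position matching on both strands counts once (making counts invariant under
reverse complementation of the sequence). No PWM score threshold is applied
by default because the headline motifs are defined by consensus.

The enrichment test is a semiparametric logistic GAM: logit P(member) =
α + β·x₂ + f(x₁), with x₁ = log scanned (unmasked) length entering as a
penalized cubic P-spline smooth and x₂ = log(1 + count) as a parametric
term. The basis is a cubic B-spline on quantile knots (10 basis functions)
with a second-order difference penalty; the constant direction of the
coefficient space is projected out against the intercept. The penalty weight
is chosen by bisection so the smooth carries 4 effective degrees of freedom
at null-model weights, then fixed while the full model is fitted by
penalized IRLS. With a single smooth term this direct joint solve coincides
with the backfitting fixed point, so no inner backfitting loop is needed.
The statistic is Z = β̂/SE(β̂) from the penalized Fisher information, with a
two-sided normal p. A constant x₂ returns Z = 0, p = 1; non-convergence or
|β̂| > 15 (separation) is flagged with NaN statistics. In the package's null
simulations the Z variance is ≈ 0.95 and the 5%-level rejection rate is
within binomial error of nominal; under a length-confounded null the GAM
median |Z| stays near 0.65 while a logistic fit without the length smooth
inflates to ≈ 3.6.

Module screens BH-adjust across the dictionary (one family per module and
region kind); a motif is reportable at q < 0.10 with at least 5% of module
genes carrying ≥ 1 occurrence. Hotspot scans pool the site starts of the
enriched motifs and report, per window size (400/200/100/50 bp), the
left-most window maximizing the contained site count.

## Synthetic data

All generators are pure functions of their parameters and a seed, and their
outputs round-trip through the package's readers.

- **Paired cohort** — PN = baseline + study offset + patient effect + noise,
  all Gaussian on the log2 scale (baseline N(7, 1.5²); study offsets
  N(0, 0.3²) per (study, gene); patient effects N(0, 0.3²) shared within a
  pair; residual noise N(0, 0.5²)); PP adds a constant ±`effect_size` log2
  shift for planted DEGs (a fixed magnitude, split evenly between
  directions, so that stated planted-effect conditions translate directly
  into fold-change-gate behavior). Above-background flags follow a logistic
  detection probability increasing with expression, calibrated to flag
  ~95% of entries by default.
- **Module reference** — each planted module's genes are `scale·loading·f_m`
  plus Gaussian noise, with a per-sample standard-normal latent factor f_m
  and per-gene scales U(0.5, 1.5); background genes are pure noise. At
  noise 0 and loading 1, member profiles are identical up to scale.
- **Perturbation experiment** — the cohort generator specialized to an
  unpaired treated/control design with 2-3 arrays per arm and a planted
  responsive fraction, matching cytokine-experiment scale.
- **Sequences** — uniform-random backgrounds with Poisson-planted exact
  IUPAC occurrences at per-kilobase rates `rate_in`/`rate_out`; a positive
  `confound` lengthens enriched-set sequences by (1 + confound), coupling
  membership to length. Conservation scores are U(0, 0.6) outside and
  U(0.5, 1.0) inside planted sites.
- **Methylation** — per-site latent levels N(0, 2²) with paired PP/PN noise
  N(0, 0.5²); each biased gene has one designated site shifted by `delta_m`
  M units in PP.

What the generators do **not** emulate: probe-level artifacts, array QC
failures, batch effects beyond additive study offsets, heavy-tailed or
intensity-dependent noise, overlapping or correlated modules, motif PWM
mismatch structure, and spatial autocorrelation of conservation scores.
Passing recovery tests on this data therefore demonstrates correctness of
the statistical machinery under the assumed data-generating structure, not
robustness to every artifact of real microarray or sequence data.

## Problem sizes and numerical choices

The simulation-based checks use cohorts of 50 patients × 2000 genes (20 null
and 5 planted replicates), module references of 100 genes × 100 samples over
20 seeds, 500 GAM null replicates at 400 genes each, and 1000 random
rank-sum pairs — sizes chosen so the full property suite completes in well
under a minute per component on one CPU while leaving binomial error bands
tight enough to be informative.

Other numerical conventions: BH adjustment delegates to
`statsmodels.stats.multitest`; exact branches switch to normal
approximations at the documented thresholds (signed-rank n > 25; rank-sum
smaller group > 12 or total > 2000); the rank-sum exact dynamic program uses
double-precision integer counts (exact below 2⁵³); GAM IRLS stops at a
relative deviance change of 1e-8 (cap 100 iterations) with weights floored
at 1e-10.

## Known limitations

- The dynamic-cut significance rule is a package-specific realization of
  top-down dendrogram cutting; partitions can differ from other dynamic
  tree cut implementations on structures near the decision boundary.
- The GAM smooth's basis and effective degrees of freedom (cubic P-spline,
  4 edf) are configurable defaults; very small universes (< ~100 genes) can
  leave the smooth under-determined.
- Fisher overlap uses the "probability at most observed" two-sided
  convention; doubling-convention p-values differ by up to a factor 2 near
  the boundary.
- The module landscape's PC coordinates are computed from the standardized
  matrix supplied at build time; they are not comparable across differently
  filtered universes.
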