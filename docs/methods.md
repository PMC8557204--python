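# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices and the known limitations of `sympnet`.

## Estimation core

**Correlations.** All networks are estimated from Spearman correlations:
columns are rank-transformed (average ranks for ties) and the
product-moment correlation of the ranks is taken. Missing data are handled
by listwise deletion only, matching complete-case designs; `n_effective` is
the complete-case count and is the `n` used in the EBIC. Rank-based
correlation matrices can be indefinite under awkward missingness; when the
smallest eigenvalue falls below 1e-8 the matrix is repaired by clipping
eigenvalues at 1e-6 and re-standardizing to unit diagonal.

**Constrained MLE.** For a fixed edge structure, the Gaussian
maximum-likelihood precision matrix with zeros off-structure is computed by
iterative proportional fitting in its modified-regression form: cycling over
nodes, each node's covariance column is refreshed from the regression of the
node on its graph neighbours against the current fitted covariance W.
Convergence is declared when the largest absolute change in W over a sweep
falls below `tol` (1e-9 for standalone fits, 1e-7 for candidate evaluations
inside the search, 1e-10 for accepted models). At the optimum W matches the
sample matrix exactly on the diagonal and on every edge — the
moment-matching property used as a correctness invariant (tested at 1e-6) —
and the precision matrix is recovered nodewise with exact structural zeros.
The log-likelihood is l(K) = (n/2)(log det K − tr(SK) − p log 2π), evaluated
on the correlation scale throughout so edge weights are scale-free.

**Model search.** EBIC = −2l + |E| log n + 4|E|γ log p with γ = 0.5 by
default (the conservative standard in the EBIC-GGM literature; γ = 0
sensitivity runs are recommended, `--gamma 0`). The search has two phases:

1. *Start path*: 40 thresholds geometrically spaced over the observed range
   of |sample partial correlation| generate candidate structures, each fit
   and scored; the best (including the empty model) seeds phase 2. Warm
   starts flow along the path.
2. *Greedy refinement*: every single-edge addition and removal is evaluated
   (warm-started from the current fitted covariance) and the largest strict
   EBIC decrease is applied until none exists. Ties within 1e-10 prefer
   removals over additions, then the lowest lexicographic node pair, making
   the selection deterministic. Since every accepted move strictly lowers
   the EBIC no cycling is possible; a visited-structure hash set guards the
   invariant anyway. The returned model is a single-edge-local EBIC optimum;
   on 4-node problems it coincides with the exhaustive optimum in ≥ 90% of
   simulated instances (asserted in the test suite).

## Network measures

- **Expected influence**: one-step signed strength Σ_j w_ij, z-scored across
  nodes. When all raw values coincide the z-scores are undefined and 0 is
  returned with a warning.
- **Predictability**: R² of OLS of each node on its selected-graph
  neighbours, 0 for isolated nodes. This neighbourhood-OLS form matches the
  unregularized, sparse fits produced here; it approximates the
  regularized-nodewise predictability measure used with penalized networks.
- **Small-world ω** = L_rand/L − C/C_latt on the *binarized* graph
  (the lattice and random references are defined for unweighted graphs).
  L and C are the characteristic path length and mean clustering of the
  observed graph (largest component if disconnected, with a warning);
  L_rand averages 100 degree-preserving rewirings (4m double-edge swaps
  each); C_latt comes from a ring lattice with matched node and edge counts,
  filled offset by offset with leftover edges assigned from node 0 upward.
  ω ≈ 0 indicates small-world structure, ω < 0 lattice-like, ω > 0
  random-like. Complete graphs return ω = 0 exactly. ω is reported with a
  stochastic reference, so repeated calls agree only up to rewiring noise
  unless the seed is fixed.
- **Layout**: Fruchterman–Reingold with |w_ij| as attraction strengths,
  seeded and deterministic.

## Bridge analysis

Communities (symptoms vs disease clusters) are designated a priori, never
detected. Bridge expected influence is one-step only — the signed sum of a
node's edges into foreign communities — because the definition in use quotes
direct edges; z-scores are computed within each community. Network
cross-loadings use

    raw(i, c)  = sign(Σ_{j∈c} w_ij) · Σ_{j∈c} |w_ij|
    std(i, c)  = raw(i, c) / sqrt(M_c),   M_c = Σ_{i∉c} Σ_{j∈c} |w_ij|

i.e. a community-mass normalization; the loadings literature has variants,
so the exact formula is echoed in the output's metadata and the magnitude
cutoffs (0.15 / 0.25 / 0.35, strict ≥ binning into
negligible/small/moderate/large) are configuration, not constants.

## Covariate adjustment

Mixed-type networks add age (continuous), sex (binary) and education
(3-level ordinal, treated as continuous after integer coding — a documented
pragmatic simplification) as nodes. Each node is regressed on all others
with an L1-penalized GLM matched to its scale: logistic for binary,
Gaussian after a Blom rank-based inverse-normal transform for
continuous/ordinal/count nodes. The penalty path has 50 log-spaced values
from λ_max (first all-zero fit) down by 1e-3; the per-node penalty is chosen
by EBIC with the same γ as the GGM. Directed standardized coefficients are
aggregated by the AND rule — the undirected weight is the mean of the two
directed coefficients when both are nonzero, else exactly 0 — the
conservative default of mixed-graphical-model practice. Logistic nodes whose
coefficients diverge (separation) are reported unstable and their edges
zeroed with a warning. With Gaussian-only data and a vanishing penalty the
aggregated weights recover the signs of the unregularized partial
correlations (tested). Crude vs adjusted cross-community edges are compared
as preserved / attenuated-to-zero / emergent.

## Stability

The case-dropping bootstrap removes random subject subsets at each
proportion of a grid (default 0.05–0.75 in steps of 0.05; configurable up
to 0.9), re-runs the supplied estimation-plus-centrality pipeline, and
records the Pearson correlation between reduced- and full-sample centrality
vectors on the raw (non-z) scale, which avoids degenerate within-replicate
standardizations. Replicate RNG streams derive from (seed, grid index,
replicate), so enlarging the replicate count never changes existing
replicates. The CS-coefficient for a metric is the largest grid proportion
such that at it *and every smaller grid proportion* at least 95% of
replicates correlate ≥ 0.7; failures and degenerate (constant) centrality
vectors count against the coverage. When the underlying network is pure
noise, centralities are near-constant and correlations are unstable by
construction — the CS-coefficient is then legitimately 0.

## Synthetic cohorts

The generator plants a ground-truth partial-correlation network and samples
subjects through a Gaussian copula:

- **Graph**: the symptom block gets a random spanning tree (guaranteeing
  connectivity) plus extra edges at density 0.2; the disease block is
  sparse at the same density; cross-block edges are exactly the planted
  positive bridges with distinct symptom endpoints. Within-block weights are
  uniform on (0.15, 0.35), bridges on (0.2, 0.3). Off-diagonals are
  contracted by 0.9 until the implied precision matrix (unit diagonal,
  K_ij = −w_ij) has minimum eigenvalue above 0.05; failure after 60
  contractions raises with diagnostics.
- **Symptoms**: latent Gaussians cut at fixed thresholds with cumulative
  probabilities (.60, .75, .85, .92, .96, .99), giving right-skewed 0–6
  severities whose modal category is 0 — thresholds are fixed rather than
  estimated because only low-severity skew, not exact margins, is known for
  the kind of cohort emulated.
- **Disease counts**: Gaussian copula to Poisson margins, mean 0.8 per
  cluster (total count ≈ 6.4 across 8 clusters, the right order for a 60+
  multimorbid population), plus a derived total count.
- **Covariates**: age ~ mean 73.1, SD 10.4, leaning on the first disease
  latent; sex (63% female) and 3-level education (15/50/35%) leaning weakly
  (coupling 0.25) on the first symptom latents — enough genuine confounding
  for adjustment analyses to have content.
- **Redundant items**: a planted redundant pair replaces the donor item and
  its duplicate by two independent noisy indicators of the *same* latent,
  calibrated to latent correlation 0.95. The symmetric construction matters:
  a one-sided noisy copy would have systematically attenuated third-item
  correlations, which the dependent-correlations screen (correctly) detects
  as a real difference; symmetric indicators differ only by sampling noise,
  like real near-duplicate questionnaire items.

All randomness flows from one integer seed through a single
`numpy.random.Generator`; cohorts are byte-for-byte reproducible.

What the generator does **not** emulate: item-specific marginal
distributions, informative missingness, measurement error correlated across
items, register-linkage artefacts, or age-dependent disease accrual. Passing
recovery tests therefore demonstrates the estimators work under the assumed
copula model at the stated sample sizes, not that real cohort data meet
those assumptions.

## Redundancy screen

Candidate pairs are those with Spearman correlation ≥ r_min = 0.50. For
each, the two items' correlations with every third item are compared with
the Hittner back-transformed z test for overlapping dependent correlations
(z statistic (z1 − z2)·sqrt((n−3)/(2 − 2c)) with the Silver–Dunlap
covariance term c evaluated at the back-transformed mean correlation); the
pair is redundant when fewer than prop_max = 0.25 of those comparisons
differ at alpha = 0.05. Resolution is greedy from the highest correlation
down, and merged items become ineligible, so the merge map is a partition.
Merging takes the per-subject arithmetic mean; a composite with any missing
member is missing (conservative). All three thresholds are configurable; at
n = 2,000 the screen recovers 5 planted pairs exactly in 18 of 20 seeds
(the misses are chance excesses of significant comparisons).

## Problem sizes used in validation

Oracle-equivalence and exhaustive-search checks run at p = 4 (200 and 100
instances); structure-recovery at the full study scale, p = 24 and
n = 2,860, over 20 seeds; stability checks use 8-node cohorts. These sizes
make every property measurable with tight Monte-Carlo error while keeping
the whole suite in the low minutes on one core.

## Limitations

- The greedy search certifies only single-edge-local EBIC optimality.
- Predictability on ordinal items uses linear R² on raw scores.
- Cross-loading normalization is one of several variants in circulation;
  comparisons across software should check the echoed formula first.
- The mixed-model adjustment treats counts and ordinals as Gaussian after
  rank-normalization; full multinomial nodes are out of scope.
- Small-world ω depends on the reference-graph conventions; values are
  comparable only under the same lattice/rewiring choices.
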