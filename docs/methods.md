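# Methods

## The model and its assumptions

`endevs` treats cohort heterogeneity as a diversity-measurement problem.
A normative model `g: X -> P(Y)` maps covariates to a predictive
distribution per feature; the standardized deviance
`Z_ij = (y_ij - mu_j(x_i)) / sqrt(sigma2_j(x_i) + eta2_j)` is a z-score
against that predictive distribution, where `sigma2` is the model's
epistemic variance at the subject's covariates and `eta2` the learned
feature noise. The measure assumes features are scored independently
(per-feature regressors; no joint multivariate deviance) and that the
deviance magnitudes, not their signs, define a subject's deviation pattern
(signed variants are provided as selection modes).

Per subject, the empirical survival function over that subject's deviance
magnitudes selects the top `100c%` features; the retained magnitudes are
renormalized into the pattern `psi_i`. Survival uses strict inequality
(`#strictly greater / M`), so the maximum always survives and ties survive
or fall together — deterministic and permutation invariant. The threshold
is applied per subject, not pooled across the cohort, so each pattern is a
row-local object. A subject with no positive magnitude has no deviation
pattern; such rows are rejected (or dropped with a logged warning by the
pipeline entry points). A consequence worth noting: because patterns are
row-local, bootstrap replicates can never *become* degenerate — degeneracy
is a property of the original rows, which is why degenerate rows are
filtered before resampling rather than triggering replicate redraws.

The decomposition at order `q` follows the ecology convention:
`gamma` is the Rényi heterogeneity (numbers equivalent) of the
weight-averaged pooled pattern; `alpha` is the weighted generalized mean of
within-subject heterogeneities,
`alpha_q = (sum_i w_i^q sum_j psi_ij^q / sum_k w_k^q)^(1/(1-q))`; and
`beta = gamma / alpha` is the ENDevs. The `q = 1` limits are
`exp(Shannon entropy)` for gamma and `exp(sum_i w_i H(psi_i))` for alpha
(natural logarithm throughout; the limit is verified against the general
formula at `q = 1 ± 1e-6` in the tests). At `q = inf`,
`alpha = max_k w_k / max_ij (w_i psi_ij)`. Weights default to `w_i = 1/N`;
arbitrary positive weights are accepted and renormalized. Pooling patterns
built at different thresholds is rejected.

For Bernoulli-parameter models (image-like data), the squared
Fisher–Hotelling–Rao geodesic distance
`d(p, y) = 2 arccos(sqrt(py) + sqrt((1-p)(1-y)))` replaces the squared
standardized residual. No variance normalization is applied to it — the
squared geodesic distance is itself the absolute deviance — because a
Bernoulli output layer carries no separate (sigma2, eta2) split.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `c` | grids `{0.01..0.07}` (cohort studies), `{0.01, 0.1, 0.3, 1}` (illustration) | extreme-value threshold; fraction of features retained per subject. Small `c` isolates each subject's most extreme deviations |
| `q` | 1 | Rényi order; `q=1` weighs patterns by their probability, `q=0` counts support, large `q` follows dominant features |
| `w_i` | `1/N` | subject weights in the pooled distribution |
| `B` | 1000 | bootstrap replicates (percentile 2.5/97.5 intervals) |
| `folds` | 10 | cross-validation folds for model criticism |
| `threshold` | 0.2 | minimum mean held-out `r² = 1 − SSE/SST` for a feature to be kept (r² may be negative) |

Probabilities below `1e-12` count as structural zeros at `q = 0`
(configurable); distributions are renormalized only when their sum is
within `1e-9` of 1, otherwise rejected.

## Normative-model backends

The reference backend fits one Gaussian-process regressor per feature
(scikit-learn): constant mean, ARD radial-basis kernel over the design
matrix plus a fitted white-noise term, hyperparameters optimized on the
marginal likelihood. Continuous covariates are z-scored with
training-split statistics only; categoricals are one-hot encoded against
training categories; responses are standardized per feature and
predictions rescaled. The predictive standard deviation returned by the
backend includes the noise term, so the epistemic part is recovered as
`total variance − eta2` (clipped at 0). A `linear` backend (Bayesian ridge
per feature) offers the same contract at a fraction of the cost for
near-linear problems and for fast tests. Any object producing
`(mu, sigma2, eta2)` — or Bernoulli parameters for the FHR route — can
feed the downstream stages.

## Resampling

Bootstrap intervals are percentile (2.5/97.5), not BCa: the estimator's
distribution over replicates is well behaved here, and percentile intervals
keep the procedure transparent. Replicates resample subjects with
replacement and weight each replicate's (possibly duplicated) subjects at
`1/n`. Seeding uses one `SeedSequence([seed, n])` per (root seed, sample
size), spawning one substream per replicate — so results are
bit-reproducible, raising `B` extends rather than reshuffles the stream,
and the accumulation curve at `n = N` coincides exactly with the
full-sample bootstrap. Accumulation subsamples are drawn with replacement
by default (matching the bootstrap convention); a without-replacement
option gives rarefaction-style curves. Note the estimator is biased
downward at small `n` (resampling duplicates subjects), which is why
accumulation curves approach, rather than attain, the plug-in value.

## Synthetic study conditions

The generator produces `M = 30` features per subject on an even grid `t`
over `[-2, 2]` via
`y_j = (x1 - 2) sin(x2 pi t_j) cos(x3 pi t_j) - cos(pi (t_j - x4)) + eps_j`,
`eps_j ~ N(x5, 0.1)`, covariates drawn i.i.d. from group-specific diagonal
Gaussians, `N = 50` per group. Defaults, chosen once as the package's study
conditions:

* all groups share covariate sds `(1, 0.3, 0.3, 1, 1)`. The spreads of
  `x2, x3` control the sin/cos frequencies; at sd 1 the product term
  oscillates too fast near `|t| = 2` for any smooth regressor to learn from
  50 subjects (held-out r² ≈ 0), which would make the normative model — and
  hence every deviance — meaningless. At sd 0.3 the GP criticism reaches
  mean held-out r² ≈ 0.6–0.96 depending on N, i.e. a normative model worth
  deviating from.
* the affected group shifts the means of `x1` (+2.5) and `x2` (+0.5).
  Shifting the *amplitude/frequency* covariates places every affected
  subject's deviation at the same high-`|t|` features, producing the
  coherent deviation patterns the measure is designed to detect. (A shift
  of the *phase* covariate `x4` does not work: each subject's phase then
  determines a different deviation location, so patterns never cohere.)

What the generator emulates: smooth nonlinear covariate-to-feature maps,
group differences expressed as covariate shift, homoscedastic Gaussian
noise with a covariate-driven mean. What it does not: site effects,
heteroscedastic or non-Gaussian noise, feature correlations beyond those
induced by shared covariates, missing data. Passing tests on it show the
pipeline detects coherent covariate-shift deviations under a well-specified
normative model — not that any particular clinical cohort will separate.

The class fixture gives each of `k` classes a disjoint active block
(level 0.85 over a 0.1 floor) among `M = 96` features, plus Gaussian noise
(sd 0.05) clipped into (0, 1). Within-class deviance is noise-driven and
diffuse; cross-class deviance concentrates at template differences — a
deliberately minimal analogue of image classes with circumscribed
between-class deviations, synthetic by construction.

## Problem sizes used in checks

The end-to-end experiment runs 20 seeded replications at `N = 50` per
group with `B = 200` bootstrap replicates; the calibration check uses
`M = 10` features at `N = 500` with 5-fold criticism; the class experiment
uses 3 classes × 40 observations. These sizes make the full verification
suite run in a few minutes on a single CPU while leaving the qualitative
results unambiguous.

## Numerical choices and edge cases

* Natural logarithm everywhere an entropy appears; `q = inf` accepted as a
  sentinel order (`1 / max p`).
* `q = 0` of a Gaussian diverges (unbounded support) and raises an error.
* Signed selection modes rank on `Z` or `-Z` but always weight patterns by
  `|Z|`, keeping `psi` a probability distribution.
* Zero predictive-plus-noise variance raises an error naming the feature.
* Constant response features are fitted in standardized space with unit
  scale, predicting the constant with near-zero noise.
* Criticism folds where a feature is constant in the held-out split
  contribute no r² for that feature (excluded from the mean, logged).

## Known limitations

* ENDevs is a plug-in estimate: downward biased in small samples when the
  true number of patterns is large (hence the accumulation curves).
* Per-feature GPs scale as O(N³) per feature; cohorts beyond a few
  thousand subjects need the linear backend or an external model feeding
  precomputed deviance matrices.
* The feature filter uses a hard r² threshold; features near the boundary
  flicker across seeds.
* No similarity-sensitive diversity: two patterns deviating on adjacent,
  correlated features count as fully distinct.
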