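# Methods

This note documents the statistical model, the numerical conventions, and
the design choices behind `shortform`, in the order the pipeline runs.

## Prediction model

A participant's observed score on dimension *d* (a total sum score, a
subscale sum, or an EFA factor score) is approximated as a weighted sum of
item responses plus an intercept:

    ŷ_d = Σ_j w_{jd} x_j + b_d.

With every item retained this is exact for sum-score targets (all weights
1, intercept 0) — a useful identity that the test suite asserts to machine
precision. Shortening the measure means forcing most w_{jd} to exactly
zero, which the Lasso does as a function of its penalty strength α.

## Two-step fit

Multidimensional targets are typically best served by *different* α per
dimension — an easy dimension tolerates heavy pruning, a hard one does not
— which rules out a shared-penalty multi-task Lasso. The implementation
therefore:

1. fits an independent Lasso per dimension at that dimension's α and keeps
   the items with non-zero coefficients;
2. takes the union of retained items across dimensions and refits
   ordinary least squares per dimension on that union.

Step 2 lets items selected for one dimension improve predictions of every
other dimension, and guarantees (by OLS optimality over a regressor
superset) that each dimension's training R² is at least its step-1 value —
a property checked on random instances in the tests. For a unidimensional
target step 2 changes nothing but is still run for uniformity.

## Standardization and the meaning of α

Inside the selection step both the items and the target are z-scored with
training-set means and SDs, and the objective is the usual
`(1/2n)·RSS + α·‖w‖₁`. The consequences:

- α is a correlation-scale quantity: the selection path runs from "all
  items" near α = 0 to "no items" at `max_j |corr(item_j, y)| < 1`.
- The same α draw distribution behaves identically whether the target is a
  sum score (SD in the tens), a subscale sum, or a centred factor score
  (SD ≈ 1). Without target standardization a fixed draw scale would prune
  sum-score models barely at all and factor-score models completely — the
  search could not treat target kinds uniformly.
- Only the retained *set* leaves step 1, and that set is invariant to any
  affine rescaling of the raw target, so the choice costs nothing
  downstream.

The refit (step 2) runs on raw responses, so exported weights apply
directly to raw item codes — important for spreadsheet scoring. Intercepts
are estimated in both steps: factor scores are centred while raw Likert
codes are not, and with sum-score targets and all items retained the
intercept comes out 0, preserving the exact-identity case.

## Randomized search

Per iteration, one α per dimension is drawn as `scale · Beta(1, 3)`;
Beta(1, 3) over-samples small strengths, which are the productive region
of the path. The default scale of 8 is suitable for a scale of roughly 22
items; because selection is standardized, draws above the kill-all
threshold (~0.9 here) simply produce empty unions, which are dropped and
logged rather than treated as errors — with the default 1000 iterations
several hundred informative candidates remain, densely covering lengths
from 1 item to the full measure. Both the Beta shape and the scale are
exposed as parameters.

Candidates are compared on a validation split by per-dimension R². The
scalar selection score `min_d(R²_d) · (1 − n_included/n_total)` uses the
*minimum* across dimensions so a model cannot look good while failing one
subscale. Ties in the score break toward fewer items, then toward the
earlier iteration (the tie-break rule is this package's convention).
`fit_at_size` complements the random search: it bisects a single shared α
to land on an exact retained-item count, exploiting the monotone
(stepwise) relation between α and model size; for one-dimensional targets
the candidate at a given size is unique, so this recovers exactly the
model the random search would eventually find.

## Targets

- **Sum / subscale scores** are plain row sums (subscales over a declared
  item partition; the partition must be exhaustive and disjoint).
- **Factor scores** come from a maximum-likelihood exploratory factor
  analysis with an oblimin (oblique) rotation, provided by
  `statsmodels.multivariate.factor.Factor`; rotation is skipped for a
  single factor, where it is the identity up to sign. Factor scores use
  the regression (Thurstone) estimator — the de-facto default of common
  factor-analysis toolchains. Eigenvalues reported for factor-count
  selection are those of the item Pearson correlation matrix; the
  programmatic retention rule is Kaiser's eigenvalue-greater-than-1
  criterion, standing in for a visual scree judgment, and the full
  eigenvalue sequence is returned so a human can overrule it via an
  explicit `n_factors`. Polychoric-correlation EFA and confirmatory factor
  analysis are out of scope.
- **Missing data** are rejected with an explicit error by default; an
  opt-in flag enables per-item mean imputation.

## Splitting and evaluation

`split(n, (p_train, p_val, p_test), seed)` assigns rows by a seeded
permutation; validation and test receive `ceil(n·p)` rows each and train
the remainder. This ceiling-for-holdouts rule reproduces the 972/325/325
partition of a 1622-row dataset at 60/20/20, which exact rounding-down
would not. Accuracy is R² = 1 − SS_res/SS_tot (computable below zero for
models worse than the mean), reported per dimension on the held-out test
split only for the finally selected model.

The sample-size sensitivity analysis draws `n_boot` subsamples **with
replacement** at each requested size from the train+validation pool,
splits each subsample 75/25 into train/validation, reruns the full search
with a reduced iteration budget (default 50; configurable), and evaluates
the best model at every observed length on the dataset's *fixed* test
partition, so curves are comparable across sizes. The 95% band is a
percentile (2.5/97.5) bootstrap interval.

## Synthetic data generator

The generator draws latent factor scores from a zero-mean multivariate
normal with a specified factor correlation matrix, forms each latent item
as loadings·factors plus a normal residual scaled so the latent item has
unit total variance (making loadings directly interpretable), and
discretizes through fixed thresholds: the response is the count of
thresholds below the latent value, plus one.

The `sticsa_like` preset emulates a high-reliability 22-item trait-anxiety
measure with two correlated factors: 11 items per factor in simple
structure, primary loadings drawn once from U(0.80, 0.95) under a fixed
preset-internal seed (so the preset names a single, stable population),
factor correlation 0.6, thresholds (−1, 0, 1) giving four roughly
symmetric response categories (expected proportions 0.159/0.341/0.341/
0.159). The defaults for downstream demonstrations use n = 2000
respondents split 1200/300/500.

What the generator does *not* emulate: careless or acquiescent
responding, missingness, item-level skew (screening-type scales whose
items mostly sit at the floor are plausibly harder and are not represented
here), and cross-loadings. Passing tests on this population therefore show
that the pipeline behaves correctly under a clean common-factor model with
high internal consistency; they do not bound its accuracy on noisier or
skewed real data.

## Numerical choices

- Lasso solving is scikit-learn coordinate descent with dual-gap tolerance
  1e-10 and a 10,000-iteration cap — tight enough to agree with an exact
  from-scratch coordinate-descent solver to 1e-6 in the coefficients on
  small instances. α = 0 is routed to least squares directly.
- Zero-variance items get a zero coefficient and a logged warning (floor
  effects occur in real data and should not abort a fit); a zero-variance
  *target* is an error.
- Rank-deficient refits fall back to the minimum-norm least-squares
  solution with a logged warning.
- All randomness flows through `numpy.random.default_rng` seeds; every
  fitted object, search, split and bootstrap is byte-reproducible for a
  fixed seed. The Lasso itself is deterministic (cyclic updates).

## Problem sizes used in the shipped analyses

The bundled demonstrations and the acceptance script use n = 2000
synthetic respondents (1200/300/500 split), 1000 search iterations at
scale 8, three replicate seeds for stochastic quantities, and 50 bootstrap
subsamples per sample size (sizes 50–500) for the sensitivity curve; these
sizes give stable medians while keeping a full rerun in the order of tens
of seconds.

## Known limitations

- Weight export assumes linear scoring; measures scored nonlinearly (e.g.
  clinical cut-point algorithms) are out of scope.
- The selection score treats all dimensions as equally important; there is
  no per-dimension weighting.
- Candidate models with identical item sets are not deduplicated in the
  frontier records (only `frontier_curve` aggregates per length).
- External validity of predicted scores (their correlations with other
  constructs) is not assessed by any shipped analysis.
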