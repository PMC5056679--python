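# Methods

## The model and its assumptions

The package estimates, for every incomplete case in a numeric table, how
badly a chosen single-imputation algorithm would reconstruct it, and offers
to reject cases whose estimated error is too large. The estimate rests on
three assumptions about the data:

1. the missingness pattern is predictive of accuracy — cases with few
   features missing tend to be imputed with lower error;
2. the error observed when a pattern is *simulated* in complete cases is
   predictive of the error of genuinely incomplete cases with similar
   patterns;
3. cases with similar feature values are imputed with similar accuracy.

These hold for data with low-dimensional latent structure and missingness
that is not adversarially informative. The method does not diagnose the
missingness mechanism; whether the complete cases are representative (i.e.
whether the data are MNAR in a harmful way) must be judged before using it.
The complete cases are the method's entire calibration substrate — they fit
the geometry, the imputer, and the error model — so a learning-curve check
that their number is sufficient is part of the pipeline.

## Error geometry

All errors are Euclidean distances between the true and the imputed
observation after projection into a 2-D principal-component space fitted on
the complete cases only (`PCAGeometry`). Two choices here were genuinely
open and are package conventions:

- **Standardization.** Features are z-scored by complete-case mean and
  standard deviation (ddof = 1) before the eigendecomposition. Real tables
  mix units (mm, mmHg, cell counts); without scaling one feature dominates
  the space. Consequently every error, kernel distance and threshold in the
  package is in standardized units. A zero-variance feature is kept but
  receives z-scores identically 0 (scale set to 1) and hence zero loadings;
  fitting fails only if fewer than two features have positive variance.
- **Fixed space.** The space is fitted once on all complete cases and
  shared by every leave-one-out split. Refitting it per split would change
  the error metric from cell to cell and reintroduce the rotation problem
  the complete-case space avoids.

Dimension 2 is the default (`n_components`); it is exposed because some
datasets need more structure than two axes to be imputed accurately.
Deterministic details: eigendecomposition of the complete-case correlation
matrix, eigenvalues sorted decreasing, and each axis's sign fixed so its
largest-magnitude loading is positive.

## Imputers

All imputers implement fit-on-complete-cases / fill-NaNs-on-transform, never
alter an observed entry, and operate in standardized coordinates.

- **Mean**: missing entries get the complete-case feature mean (0 in
  standardized coordinates when fitted on the full complete set).
- **k-nearest-neighbour** (default k = 3): neighbour distance is Euclidean
  over the query's observed features only; the filled value is the
  unweighted mean of the k nearest complete cases. Distance ties break by
  lower training-row index (deterministic); k larger than the available
  complete cases degrades gracefully to the mean over all of them.
- **PPCA**: the latent-variable Gaussian model x = Wz + μ + ε with
  isotropic noise, fitted by EM on the complete cases (covariance form;
  spectral initialization, so refits are bit-identical and no seed enters).
  Defaults: q = 2 latent dimensions, relative log-likelihood tolerance
  1e-6, max 500 iterations; non-convergence warns and reports the trace.
  A missing block is completed by its conditional mean given the observed
  block, computed through the q-dimensional posterior of z (single
  imputation; no posterior draw). On exactly low-rank data the noise
  variance collapses; it is floored at 1e-12 with a warning, which keeps
  the conditional mean well-defined and makes low-rank completion exact.

## Error simulation

Every observed pattern is simulated in every complete case; the imputer is
fitted on the other N_com − 1 complete cases and the projected error
recorded, giving the N_com × M matrix of true errors. The fit depends only
on the held-out case, not the pattern, so the implementation fits once per
leave-one-out split and fills all M masked copies in one call — numerically
identical to the cell-by-cell description, N_com fits instead of N_com·M.
Cells where the imputer fails, or where a user-supplied pattern has no
observed feature, hold NaN sentinels; downstream weighted averages exclude
them and renormalize.

## Kernel-weighted estimation

The estimate for a query is a doubly weighted average of the simulated
errors: pattern weights `exp(−γ‖μ̄_x − μ̄_m‖)` normalized over the M
patterns (Euclidean norm of the 0/1 difference, i.e. the square root of the
Hamming distance), and case weights `exp(−δ‖μ̄_x ⊙ (x̄ − x̄_n)‖)` normalized
over the complete cases, distance taken over the query's present features
in standardized coordinates. γ = δ = 0 gives uniform weights (the grand
mean of the error matrix); the weights always form a probability
distribution, so estimates are convex combinations of observed errors.

When the same machinery scores the simulated complete-case cells (for
threshold sweeps and the grid-search objective), each case's own simulated
errors are withheld from its estimate and its case weights renormalized
over the remaining N_com − 1 cases (`self_exclusion`, on by default).
Without it the estimator can trivially memorize the very cell it is asked
to predict. The flag exists for sensitivity analysis.

**Grid search.** The scales are chosen on a 21 × 21 grid over [0, 10]²,
minimizing the RMSE between estimated and actual errors over all valid
simulated cells — the same currency the learning curve reports. Ties break
toward smaller γ, then smaller δ, so the degenerate uniform estimator wins
only when nothing beats it. The pattern and present-feature distance arrays
are precomputed once; each grid point costs two small matrix products.

## Reject option and diagnostics

- **Threshold.** Acceptance is strict: a case is imputed iff estimated
  error < threshold. The threshold is in standardized 2-D error units
  (default 0.03, deliberately conservative) or, via `threshold_pct`, a
  percentage of the RMS of all valid simulated errors — a scale-free rule
  (100% ≈ "below-average expected error") that transfers across datasets.
  The right value is application-dependent; the sweep table (RMSE of actual
  errors among included vs excluded cells as the threshold varies) is the
  intended basis for choosing and reporting it.
- **Learning curve.** For each subsample size, s complete cases are drawn
  without replacement (seeded per replication via independent substreams,
  100 replications by default) and the whole pipeline is rerun on the
  subsample at fixed kernel scales; per-size means of the RMSE of estimated
  and of actual errors are reported. Kernel scales are held at the full-data
  grid-search optimum rather than re-searched per subsample (a 441×
  cost saving per replication; re-searching is available by refitting).
  Subsample indices are sorted, so at s = N_com every replication reproduces
  the full-data computation exactly.
- **New observations.** A new case with a known pattern is scored directly;
  an unseen pattern is first simulated across all complete cases (reusing
  the stored leave-one-out fits), appending one column to the error matrix.
  A complete new observation is accepted with estimate 0 by convention.

## Synthetic data

The generators produce the regime the method assumes and every test runs
on: a latent Gaussian factor model (default rank 2, noise sd 0.1, unit
loading scale) with three missingness mechanisms — MCAR (exact random cell
subset), block bias (random rows lose contiguous feature blocks, emulating
damaged regions of physical specimens), and group bias (per-cell dropout
with group-specific rates, rarer groups hit harder). Mechanism parameters
are scaled so the realized overall missing fraction lands within ±3
percentage points of the target. `make_study_split` then restores a random
60% of rows to fully observed, leaving ceil(0.4·N) incomplete — 91 of 226
at the reference size. The original object is never mutated, so the true
value under every mask is retained and actual imputation errors are exactly
computable.

What the synthetic data does *not* emulate: heavy tails, nonlinear latent
structure, mixed discrete/continuous features, and missingness that depends
on the missing value itself (true MNAR in the cell, not just the row/block).
Passing tests therefore demonstrate correctness of the machinery and its
behaviour in the favourable low-rank regime, not performance guarantees on
arbitrary real data.

## Problem sizes and numerical choices

The acceptance analysis runs at 226 rows × 23 features (135 complete, 91
incomplete, ~86 patterns), full 21×21 grid searches for all three imputers,
and a 100-replication learning curve at five sizes with the mean imputer —
chosen as a representative, quickly reproducible configuration. Unit and
property tests use 30–500-row instances with brute-force loop oracles at
6×5 scale.

Degenerate inputs: rows with all features missing are excluded from the
incomplete set (no value kernel can be evaluated) with a warning; fewer
than 3 complete cases aborts the pipeline; kernel weight underflow (all
similarities 0) raises rather than silently renormalizing noise; empty
included/excluded groups in sweeps yield NaN, never 0.

## Known limitations

- Accepted-case counts depend on the standardization convention and the
  grid-search objective; other conventions shift thresholds by a scale
  factor.
- The error lives in the 2-D PC plane: disagreement orthogonal to the plane
  is invisible to the error measure by construction.
- The grid search optimizes average agreement between estimated and actual
  error, not downstream utility; choosing γ, δ, and the threshold by
  cross-validation on a downstream analysis is out of scope.
- Categorical features are rejected at load time; only numeric tables are
  supported.
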