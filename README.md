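# rejectimpute — imputation with a reject option

Single imputation replaces every missing value with one estimate and then
treats the filled-in dataset as real. But the quality of an imputation
depends strongly on *what* is missing: a case missing one redundant feature
may be reconstructed almost perfectly, while a case missing the informative
half of its features cannot be. `rejectimpute` estimates the imputation
error of **each individual incomplete case** from the data itself, so cases
whose estimated error exceeds a threshold can be *rejected* — excluded from
the analysis — instead of silently imputed. It is aimed at biostatistical
and machine-learning settings (clinical tables, morphometric measurements)
where each observation's actual values matter downstream, e.g. in
classification, and multiple imputation is not an option.

The wrapper works with any single-imputation algorithm; three are built in:
probabilistic PCA (PPCA), feature-mean imputation, and 3-nearest-neighbour
imputation.

## Method

Let `X` be an `N × D` numeric matrix with `N_com` complete cases and
`N_miss` incomplete cases carrying `M` distinct *missingness patterns*
`μ̄_1 … μ̄_M` (length-`D` 0/1 vectors, 1 = present). The pipeline:

1. **Geometry.** Features are z-scored by complete-case mean/sd and a 2-D
   PCA space is fitted on the complete cases only. All errors are Euclidean
   distances between true and imputed points in this plane; fixing the space
   on complete cases avoids Procrustes-rotation ambiguity.
2. **Error simulation.** Every pattern is simulated in every complete case:
   case `n` is masked by `μ̄_m`, imputed by the algorithm fitted on the other
   `N_com − 1` complete cases (leave-one-out), and the true error is
   recorded, giving the matrix `Err ∈ R^(N_com × M)`.
3. **Error estimation.** For an incomplete case `x̄` with pattern `μ̄_x̄`,

       EstimatedErr(x̄) = Σ_m [S1(μ̄_x̄, μ̄_m) / Σ_m' S1] · Σ_n [S2(x̄, x̄_n) / Σ_n' S2] · Err_{n,m}

   with the pattern kernel `S1(μ̄_a, μ̄_b) = exp(−γ‖μ̄_a − μ̄_b‖)` and the
   value kernel `S2(x̄, x̄_n) = exp(−δ‖μ̄_x̄ ⊙ (x̄ − x̄_n)‖)`, which measures
   distance over the case's *present* features only. The scales `γ, δ` are
   grid-searched on `[0, 10]²` against the simulated cells themselves.
4. **Reject option.** A case is imputed iff `EstimatedErr < threshold`;
   everything else is reported as rejected. Threshold sweeps and learning
   curves (RMSE of estimated and actual errors vs number of complete cases,
   100 replications) support choosing the threshold and judging whether
   `N_com` is large enough.

## Worked example

```python
import numpy as np
from rejectimpute import (RejectingImputer, SyntheticSpec, apply_block_bias,
                          generate_lowrank, make_study_split)

# rank-2 data, 50% block-biased missingness, 60/40 complete/incomplete split
truth = generate_lowrank(SyntheticSpec(n_rows=120, n_features=10, latent_rank=2,
                                       noise_sd=0.1, seed=42))
masked = apply_block_bias(truth, missing_fraction=0.5, seed=43)
study = make_study_split(truth, masked, frac_missing_rows=0.4, seed=44)

model = RejectingImputer(imputer="ppca", threshold_pct=100).fit(study)
print(f"complete cases: {model.partition_.n_complete}, "
      f"incomplete: {model.partition_.n_incomplete}, "
      f"patterns: {model.partition_.n_patterns}")
print(f"grid-searched kernel scales: gamma={model.kernel_params_.gamma}, "
      f"delta={model.kernel_params_.delta}")
print(f"threshold (RMS of simulated errors): {model.threshold_:.3f}")
print(f"accepted {model.n_accepted_} / {len(model.decisions_)} incomplete cases")
```

prints

```
complete cases: 72, incomplete: 48, patterns: 37
grid-searched kernel scales: gamma=10.0, delta=1.5
threshold (RMS of simulated errors): 0.720
accepted 45 / 48 incomplete cases
```

72 complete cases were used to simulate all 37 observed missingness
patterns (the `72 × 37` matrix of true errors behind the estimates); the
grid search concentrated the pattern kernel strongly (γ = 10) — pattern
identity is highly informative here — and 45 of the 48 incomplete cases
have estimated error below the RMS-of-errors threshold, so they are imputed
while 3 are rejected. `model.transform(study)` returns the filled matrix,
`model.decisions_frame()` the per-case table, and
`model.score_new_observation(x)` handles newly arriving observations.

The same pipeline is available from the shell:

```bash
rejectimpute simulate --n-rows 120 --n-features 10 --out data.csv
rejectimpute evaluate --input data.csv --imputer ppca --threshold-pct 100 --out-dir out/
```

which writes `decisions.csv`, `err_matrix.csv`, `grid.csv`, `sweep.csv`,
`report.json` and the resolved `config.json`.

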