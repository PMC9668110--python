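# normadapt

Computational modeling of **fairness-norm adaptation** in a conditioning
Ultimatum Game (UG), for researchers in social decision-making and
developmental computational psychiatry.

In the paradigm, a responder faces 60 one-shot token splits of a 20-token
endowment from anonymous proposers: a 20-trial **baseline** block of medium
offers (drawn from N(8, 1.5) tokens), a 20-trial **conditioning** block of low
offers (N(4, 1.5)), and a 20-trial **post-conditioning** block of medium
offers again. If the responder's internal fairness norm adapts to the low
offers, rejection of otherwise identical medium offers should drop from
baseline to post-conditioning.

`normadapt` provides, end to end on synthetic cohorts:

- **Task generation** (`normadapt.task`) — seeded integer-token offer
  schedules with block structure and emotion-rating prompts (~67% of trials).
- **Choice models** (`normadapt.models`) — six candidates sharing the
  inequity-averse utility
  `U(s) = s − α·max(x − s, 0) − β·max(s − x, 0)`
  (envy α, guilt β, internal norm x) and the softmax choice rule
  `P(accept) = 1 / (1 + e^(−γU))`, differing in how the norm evolves:
  - `FS_fixed` / `FS_free`: non-learning (constant norm; 10 tokens or fitted),
  - `BO_fixed` / `BO_free`: Bayesian observer with a conjugate
    Normal–Inverse-χ² prior over the offer distribution
    (k₀ = 4, ν₀ = 10, σ̂₀² = 4), norm = prior mean μ̂ₜ₋₁,
  - `RW_fixed` / `RW_free`: Rescorla–Wagner norm-prediction-error learning
    `xₜ = xₜ₋₁ + ε(sₜ − xₜ₋₁)` with learning rate ε.
- **Synthetic cohorts** (`normadapt.simulate`) — 30 responders × 60 trials by
  default, parameters sampled from truncated Gaussians at the fitted-moment
  defaults (α 2.58 ± 2.53, β 0.17 ± 0.32, γ 1.78 ± 1.58, ε 0.16 ± 0.28), with
  ground-truth tables for recovery studies.
- **Fitting** (`normadapt.fitting`) — per-participant maximum likelihood via
  the scikit-learn-style estimator `NormModelMLE` (bounded multi-start
  L-BFGS-B), scored by BIC = k·ln n − 2LL and AIC = 2k − 2LL.
- **Model comparison & recovery** (`normadapt.comparison`) — summed-BIC/AIC
  winner selection, parameter-recovery summaries, model-confusion tables.
- **Model-free statistics** (`normadapt.behavior`) — block rejection-rate
  contrasts (paired t, Cohen's d = |t|/√n with a noncentral-t CI),
  Benjamini–Hochberg FDR correction, sliding-window rejection curves, a
  mixed-effects logistic regression of choice on offer size, and the
  emotion-rating contrast.

## Worked example

```python
import normadapt as na

trials, truth = na.simulate_cohort(na.CohortSpec(n_participants=30, seed=7))
fits = na.fit_cohort(trials, na.MODEL_IDS, na.OptimizerConfig(seed=1))
print(na.compare_models(fits).summary())

from normadapt.behavior import rejection_contrast
res = rejection_contrast(trials)
print(f"t({res.df}) = {res.t:.2f}, p = {res.p:.2g}, d = {res.cohens_d:.2f}, "
      f"mean diff = {res.mean_diff:.2f}%")
```

Output (seeds as above):

```
model           sum BIC      sum AIC    n
RW_fixed         836.04       584.72   30
RW_free          925.15       611.00   30
BO_fixed        1294.68      1106.19   30
BO_free         1353.12      1101.80   30
FS_fixed        1431.85      1243.36   30
FS_free         1538.86      1287.54   30
winner (BIC): RW_fixed; winner (AIC): RW_fixed
t(29) = -4.79, p = 4.5e-05, d = 0.87, mean diff = -8.67%
```

The Rescorla–Wagner model with a fixed initial norm recovers as the winning
model on data it generated, and the cohort rejects medium offers about 9
percentage points less after conditioning (negative t: a post-conditioning
decrease), the behavioral signature of norm adaptation.

The same pipeline is available from the shell:

```bash
normadapt simulate --seed 7 --out out/
normadapt fit      --seed 1 --out out/ --data out/trials.csv
normadapt compare  --out out/ --fits out/fits.csv
normadapt behavior --out out/ --data out/trials.csv
normadapt recover  --seed 1 --out out/ --replicates 10
```

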