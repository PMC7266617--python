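# replearn

Representational analyses for longitudinal motor-sequence-learning fMRI.

## The problem

When people practice finger sequences for weeks, does the cortical
activity pattern that encodes each sequence stay put, drift, or
reorganize? Answering this requires more than voxel-wise activation
statistics: it needs (i) unbiased estimates of how *distinct*
sequence-specific patterns are, (ii) a way to estimate the *correlation*
of a sequence's pattern across scanning sessions that is not dragged down
by session-specific noise, and (iii) group inference that controls
family-wise error over cortical maps without parametric assumptions.

`replearn` implements that analysis chain for a design with 26 subjects,
4 scanning sessions of 8 runs each, and 6 trained + 6 untrained
sequences per run:

- **First-level GLM** — boxcar regressors convolved with a two-gamma HRF
  (time to peak 5.5 s, undershoot 12.5 s), an onset-delay grid search over
  {0, 0.5, 1} s on the session-1 ROI-mean response, per-run condition
  betas, percent signal change `PSC = 100 β̄ / intercept`, and an
  error-trial-exclusion variant.
- **Crossnobis dissimilarities** — patterns are multivariately
  prewhitened by `Σ̂_reg^{-1/2}` (voxel covariance from GLM residuals,
  shrunk toward its diagonal), then the cross-validated squared
  Mahalanobis distance is computed over independent run pairs:
  `d(i,j) = mean_{m≠n} (β̂ᵢ^m − β̂ⱼ^m)ᵀ(β̂ᵢ^n − β̂ⱼ^n) / P`.
  The estimator is unbiased — zero expectation when two conditions evoke
  identical patterns — so negative values are meaningful. Cosine-angle
  dissimilarities, z-scored activation maps, classical MDS and a
  searchlight driver complete the stage.
- **Pattern component models (PCM)** — for each of 30 fixed correlations
  r on [0, 1], the marginal likelihood of two sessions' patterns is
  maximized over per-session log signal variances (a₁, a₂) and log noise
  variances (s₁, s₂) under the second-moment model
  `G = [[e^{a₁}I_k, r e^{(a₁+a₂)/2}I_k], [·, e^{a₂}I_k]]`.
  Type-II log-likelihood curves (relative to the per-subject model mean)
  are read as log-Bayes factors; the group comparison selects best models
  on n−1 subjects and evaluates them on the left-out subject.
- **Group inference** — one-sample/paired t-tests, two-way
  within-subject ANOVA, and sign-flip max-statistic permutation tests for
  peak-t and cluster-size FWE control.
- **Synthetic study generator** — trial tables (paired repetitions,
  randomized rests), true patterns with configurable cross-session
  correlation per sequence type, run-level estimates with Gaussian
  (identity or AR(1)) voxel noise, BOLD-like time series with retrievable
  ground-truth betas, and movement-time learning curves from 3.2 s to
  1.2 s. Every downstream stage is testable without any imaging data.

## Worked example

```python
import replearn as rl
from replearn.datasets import TRAINED, UNTRAINED
from replearn.pcm import prepare_session_pair

cfg = rl.SimConfig(n_subjects=12, n_sessions=2, n_voxels=160, seed=1)
true = rl.make_true_patterns(cfg)          # trained r(week1, week2) = 0.37
data = rl.make_run_estimates(true, cfg)    # untrained r = 0.65

conds = [c for c, t in cfg.sequence_type_map().items() if t == TRAINED]
pairs = [prepare_session_pair(rl.prewhiten(data[(s, 0)]),
                              rl.prewhiten(data[(s, 1)]), conds)
         for s in range(cfg.n_subjects)]
res = rl.CorrelationPCM(pairs).fit()
print(res.summary())
```

```
Correlation PCM results
====================================================
subjects:                  12
models (r grid):           30 on [0, 1]
winning correlation:       r = 0.379
evidence at winner:        11.97 +/- 0.49 (log-units vs model mean)
evidence range (max-min):  45.44
converged fits:            360/360
```

The generator embedded a true cross-session correlation of 0.37 for
trained sequences; the group evidence curve peaks at the nearest grid
value, r = 0.379. Running the same fit on the untrained sequences peaks
at r = 0.655, and `rl.crossval_group_test` on the two result objects
returns the out-of-sample log-Bayes factors with a one-sided paired
t-test (here t ≈ −9.3, p ≈ 8e−7: the two correlations genuinely differ).

A full pipeline run (simulation → RDMs → PCM → group stats) is one
command:

```bash
replearn all --out out/ --seed 1 --subjects 8
```

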