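# Methods

This note documents the models, estimators and numerical choices behind
`replearn`, what the synthetic-data generator does and does not emulate,
and the problem sizes the test suite uses.

## Study design emulated by the generator

The synthetic study mirrors a longitudinal sequence-learning experiment:
26 subjects (configurable), 4 scanning sessions of 8 runs, 12 conditions
per run (6 trained, 6 untrained 9-digit sequences). Within a run every
sequence is executed twice in a row and six times in total; a trial is
1 s preparation + 3.5 s execution/feedback + 0.5 s inter-trial interval
(5 s), and five 10-s rest periods are inserted at uniformly random trial
boundaries (the emulated protocol says rests were "added randomly", so a
uniform law over boundaries is our choice).

**True patterns.** Each sequence's true voxel pattern across the S
sessions is zero-mean multivariate normal: per-session variance
`signal_var`, session-pair correlation from an S×S matrix per sequence
type (validated positive semi-definite at construction), independent
across sequences and voxels. Independence across sequences is an
assumption — the within-session covariance between different sequences'
patterns is not constrained by the protocol, and 0 is the simplest
choice consistent with the scaled-identity G blocks used by the PCM
stage. Default correlations encode the phenomenon of interest: trained
patterns reorganize early (r(week1, week2) = 0.37) and stabilize later
(r(week2, week5) = 0.6); untrained patterns stay comparatively stable
(≈0.65). The remaining matrix entries were chosen once to be plausible
and PSD.

**Run-level estimates.** Observed condition-by-run patterns are truth
plus Gaussian noise with covariance `noise_var · Σ_voxel`, i.i.d. across
runs (runs are modelled as exchangeable partitions; no temporal
autocorrelation between run-level estimates). `Σ_voxel` is identity or
AR(1) with parameter ρ. Residual matrices for prewhitening are emitted
from the same noise law with a configurable row count (default 200 per
run; the residual dimensionality of a real GLM depends on run length and
is not otherwise constrained). Defaults `signal_var = 1`,
`noise_var = 8` put the per-session pattern SNR (signal variance vs
noise variance of an 8-run mean) at 1:1 — a moderate regime typical of
multivariate sequence analyses, where evidence curves are peaked but not
degenerate.

**Behavior.** Trained movement time decays exponentially from 3.2 s
toward a 1.2 s asymptote over a subject's cumulative trials (time
constant = total trials / 5); untrained sequences follow the same curve
scaled to 30% of the trained improvement (transfer magnitude is
otherwise unconstrained). Trial noise is lognormal with unit mean (the
trial-wise MT noise law is not constrained; lognormal keeps MTs positive
with realistic right skew). Error flags are i.i.d. Bernoulli with
per-session, per-type default rates of 0.14/0.15, 0.08/0.14, 0.06/0.09,
0.14/0.13 (trained/untrained).

**Not emulated:** spatial smoothness of BOLD beyond AR(1), physiological
and motion artifacts, surface geometry, scanner drift. Passing tests
therefore demonstrate correctness of the estimators under their stated
model, not robustness to those real-data nuisances.

## First-level GLM

The HRF is a difference of two gamma densities with shared scale,
`h(t) = γ(t; p₁, b) − c·γ(t; p₂, b)`. The three landmark constraints —
sampled maximum at 5.5 s, minimum at 12.5 s, undershoot-to-peak
amplitude ratio 1:6 — determine (p₁, p₂, c, b) by nested root-finding
(grid scan + Brent refinement of h′ inside a least-squares outer solve).
The kernel is normalized to peak 1 and is exactly 0 at t = 0. Only the
two landmark times are protocol constants; the two-gamma family and the
1:6 ratio are our parameterization.

Regressors are boxcars (trial onset → offset; overlapping trials of one
condition sum) convolved with the kernel on a 0.1-s grid, sampled at the
TR, and scaled so an isolated trial's regressor peaks at 1. That scaling
makes percent signal change well defined as `100 · mean(β) /
mean(intercept)` without further convention. Estimation is OLS per run
(no temporal autocorrelation model — downstream stages only require
run-level exchangeability); error-trial exclusion moves error trials
into one nuisance regressor per run. The onset-delay grid search fits
the voxel-mean ROI time course for delays {0, 0.5, 1} s on session-1
data and maximizes R²; ties break toward the smaller delay, and the
chosen delay is reused for all sessions.

## Prewhitening and crossnobis

The voxel noise covariance `Σ̂ = RᵀR / dof` from GLM residuals is
regularized as `(1−λ)Σ̂ + λ·diag(Σ̂)` and patterns are right-multiplied
by `Σ̂_reg^{−1/2}` (symmetric inverse square root). `λ = "auto"` uses
the Ledoit–Wolf analytic intensity; `λ = 1` reduces to dividing each
voxel by its residual s.d. and takes a cheap diagonal path.

Crossnobis: run means are removed within each partition (standard for
this estimator; it removes common activation without biasing pairwise
contrasts), then
`d(i,j) = Σ_{m≠n} (β̂ᵢ^m − β̂ⱼ^m)ᵀ(β̂ᵢ^n − β̂ⱼ^n) / (M(M−1)P)`,
computed vectorized via cross-run Gram matrices. Pair order is
lexicographic in condition id and fixed across the package. The 1-D
variant (e.g. movement times per sequence and run) standardizes by the
residual s.d. — estimated from the condition × partition interaction
when not supplied — and calls the same estimator with P = 1.

Cosine-angle dissimilarity `1 − cos(a, b)` is computed between mean
patterns without prewhitening (the statistic targets the relative
spatial distribution of raw activation; whether noise normalization
should precede it is an open choice, and we keep the raw-PSC reading).
Classical MDS is Torgerson double-centering of squared dissimilarities
with top-k eigenvectors; rotation/sign indeterminacy for longitudinal
plots is resolved by orthogonal Procrustes alignment to a reference
configuration.

## PCM correlation models

For one sequence type across two sessions, true patterns have
second-moment matrix `G(r, a₁, a₂)` with scaled-identity blocks (shared
signal variance across a type's sequences — the minimal structure for a
single cross-session correlation) and per-session i.i.d. noise
`e^{s_m}`. The marginal likelihood of the data
`L = −(NP/2)ln 2π − (P/2)ln|V| − ½tr(V⁻¹YYᵀ)`, `V = ZGZᵀ + Σ_noise`,
is evaluated through the rank decomposition of ZGZᵀ (matrix determinant
lemma + Woodbury), so cost scales with rank(G), not N.

Run intercepts are removed as fixed effects by projecting each run's k
condition patterns onto k−1 orthonormal contrasts; because the G blocks
are scaled identities, the projected model keeps the same structure with
k−1 pseudo-conditions and exactly i.i.d. noise, which makes the
conditioning exact rather than approximate. For fitting, the likelihood
collapses onto sufficient statistics (per-session residual sums of
squares and the 2×2 cross-session second moment of run means), reducing
every evaluation to closed-form 2×2 algebra; the reduced form is tested
to equal the generic Woodbury evaluation to 1e−10.

Each of the 30 grid models (equal steps on [0, 1] inclusive, step 1/29 —
the endpoint convention is ours) is maximized over (a₁, a₂, s₁, s₂) by
L-BFGS-B with analytic gradients in log-variance space, bounded below at
ln(1e−8) to keep V positive definite, restarted from a moment-based and
a default start. "Type-II log-likelihood" means exactly this per-subject
maximization over the variance parameters; evidence is reported relative
to the per-subject mean over models, and differences are read as
log-Bayes factors.

The crossvalidated group test chooses, for every left-out subject, the
best model of each condition set on the remaining n−1 subjects (summed
evidence, ties to the lower r) and records
`Δᵢ = loglik_A(i, r*_B) − loglik_A(i, r*_A)`; a one-sided paired t-test
(H1: mean Δ < 0) asks whether set A's patterns are better explained by
A's own best correlation — a directional hypothesis, hence one-sided.
If every fold selects identical models the statistic is degenerate and
(t, p) = (0, 1) is returned; this makes the test conservative in
high-signal regimes where model selection never varies. Tessel-style
maps report the argmax-r per location, masked where the winning model
beats the worst-fitting one by ≤ 1 log-unit on the group-mean curve.

## Group inference

The two-way within-subject ANOVA is computed from balanced sums of
squares, each effect tested against its subject-by-effect interaction
with conventional uncorrected dof (no sphericity correction); a zero
effect sum of squares is reported as F = 0. The sign-flip test samples
sign assignments uniformly with replacement from the 2ⁿ possibilities,
recomputes the group t-map per permutation, thresholds two-sidedly at
the uncorrected p (clusters labelled separately for positive and
negative excursions; cluster size is a node count), and records the
map-wise peak |t| and largest cluster. FWE p-values are
`(1 + #{null ≥ observed})/(1 + n_perm)` — the observed statistic counts
in its own null, so p ≥ 1/(n_perm+1). An exhaustive mode enumerates all
2ⁿ−1 non-identity assignments for exact small-n inference.

## Problem sizes used by the test suite

Statistical end-to-end checks run at desk scale, chosen once: crossnobis
null bias over 2000 simulated datasets (6 conditions × 8 runs × 160
voxels); PCM recovery over 50 replicates per true correlation
(20 subjects, 6 sequences, 8 runs, 500 voxels, univariate-standardized
prewhitening, 50 residual rows per run); crossvalidated-test size over
200 null replicates in a moderate-signal regime (12 subjects, 60 voxels,
signal 0.3 / noise 16, true r = 0.5 between grid points — chosen so
model selection actually varies across folds, which a calibration check
of this test requires) and power over 80 replicates at high signal
(20 subjects, r 0.3 vs 0.7); sign-flip calibration over 1000 null maps
(20 subjects × 200 locations, 200 permutations each). Seeds are fixed in
the tests.

## Known limitations

- The PCM noise model is i.i.d. within session after prewhitening;
  residual spatial correlation that survives shrinkage-regularized
  whitening is not modelled.
- The crossvalidated group test's null distribution has an atom at zero
  whenever fold selections coincide; its size is conservative at high
  SNR (see above) and only approximately nominal in between.
- The delay grid search assumes a task-positive mean ROI response;
  regions with balanced positive/negative patterns carry little delay
  information.
- `winning_model_map` masks on the group-mean evidence curve; per-subject
  masking variants are not implemented.
- NIfTI ingestion is read-only and flattens masked voxels in C order;
  surface formats (GIFTI/CIFTI) are out of scope.
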