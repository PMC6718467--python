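# Methods

This note documents the models, the synthetic-data assumptions and the
numerical choices behind `restvs`.

## Task model and VS measures

The MID session is modelled at the event level. Each non-neutral trial
contributes an anticipation event spanning the cue-to-target interval and a
feedback event; neutral trials contribute a neutral-cue and a neutral-feedback
event. Two design schemes are supported:

* `two_run_gain_loss` — two concatenated runs of 90 trials (40 gain, 40 loss,
  10 neutral; amounts ±0/20/100/500 yen). The first-level model has 24
  condition regressors: 8 anticipation conditions, 2 control events, and 14
  outcome regressors (gain/loss × 20/100/500 × hit/miss plus one common
  feedback per ±0 yen).
* `one_run_gain` — a single run with 62 win and 18 neutral trials and 14
  condition regressors (4 anticipation, 8 feedback with hit/miss for every
  amount, 2 control events). Note the win/neutral counts sum to 80 trials.

Feedback outcomes are Bernoulli with the staircase-calibrated hit rate of
0.66. Exact per-event second timings are not part of the paradigm definition
used here, so they are configuration parameters with defaults: cue 0.5 s,
anticipation 2.0–2.5 s (uniform jitter), target 0.5 s, feedback 1.65 s,
inter-trial interval 2.5–3.5 s. The anticipation regressor models the
cue-to-target epoch rather than a punctate event (configurable through the
event table).

Boxcars are convolved with the canonical double-gamma HRF (peak delay 6 s,
undershoot delay 16 s, unit dispersions, peak:undershoot 6, unit peak) on a
16× oversampled grid and sampled at volume times. Run concatenation is
handled with per-run intercepts; no additional high-pass filter is applied.
Estimation is OLS through the pseudoinverse; exactly rank-deficient designs
(e.g. a subject who never misses in one condition, leaving an all-zero
column) fall back to the minimum-norm solution with a warning — the gain
contrasts are unaffected because the anticipation regressors are always
populated.

Reward sensitivity regresses the three gain contrasts on reward *rank*
(1, 2, 3) rather than yen amount; the rank relationship is the more linear
parameterisation, and a yen-based slope is available behind a flag for
sensitivity analyses. For equally spaced ranks the slope is identically
`(maximal − small)/2`, which the tests assert against the OLS output.

## Resting-state cleaning and connectivity

Cleaning is a single OLS regression per ROI on: intercept, six motion
parameters, the top-3 principal components of the white-matter pool and of
the CSF pool (3 per tissue, 6 in total; the count is configurable since
"first three components of WM and CSF" is ambiguous between per-tissue and
total), and sine/cosine regressors at every discrete Fourier frequency
`m/(T·tr)` strictly outside the 0.01–0.1 Hz passband. Filtering by
regression keeps the temporal filter and the nuisance projection in one
idempotent projector; the all-zero sine column at the Nyquist frequency is
dropped. Connectivity is plain Pearson correlation of the residuals — no
Fisher transform (raw r is what the predictive model consumes; a Fisher-z
option exists for the group test only) and no thresholding or sign removal.

Group inference on the mean FC matrix tests the elementwise null of zero
connectivity with random sign flips of each subject's matrix. Sign-flipping
is the standard exact test under elementwise sign symmetry; the family-wise
error is controlled with the permutation distribution of the maximum
absolute mean over edges, `p = (1 + #{perm max ≥ observed})/(1 + n_perm)`,
two-sided.

## Relevance vector regression

The learner is a sparse Bayesian linear model in kernel space with design
`Φ = [1 | K]`, `K` a linear kernel over vectorised FC edges, centred with
training-set means only. Hyperparameters follow the classic fixed-point
updates (see module docstring). Choices:

* Initialisation `α = 1/n²`, `σ² = 0.1·var(y)` — common stable defaults.
* The bias carries its own `α` like any basis function and may be pruned.
* Pruning threshold `α > 1e12`; at least one basis function is always kept.
* `σ²` floored at `1e-12·var(y)` to keep updates finite on noiseless data.
* Stopping: `max |Δ log α| < tol` (default `1e-6`, `max_iter = 1000`). The
  cross-validation and permutation loops use `tol = 1e-3`, `max_iter = 300`:
  predictions and p-values are indistinguishable from the tight setting on
  test instances while thousands of refits stay fast.

The log marginal likelihood is tracked every iteration. These fixed-point
updates are not an EM scheme: the evidence is monotone in the well-posed
regime (verified to 1e-8 over seeded instances at n = 25, d = 10, unit
noise) but can dip when `σ²` collapses toward interpolation (near-noiseless
targets or very small n) or when a basis function is pruned at a finite
`α`. This is a known property of the update rule, not a solver defect; the
independent explicit-inversion oracle in the test suite reproduces the fast
path to 1e-6 either way.

For the linear kernel the kernel-space posterior mean folds back to feature
space, `w = Σ_i μ_i (x_i − x̄)`, with the bias adjusted for centring so that
`predict(x) ≡ w·x + b` exactly; the identity is asserted numerically.

## Prediction pipeline

The 45 subjects are split once into estimation (30) and held-out (15)
samples, allocated per recruitment cohort by largest-remainder rounding
(14/15/16 → 5/5/5 held out). Ten folds of three are drawn inside the
estimation set. Per measure:

* **Estimation performance** is computed on the concatenated out-of-fold
  predictions (the per-fold points themselves are kept in the subject
  table). The affine scaling regression (actual on raw, estimation set only)
  is applied before the MSE; Pearson r is affine-invariant.
* **Held-out performance** applies the predictor obtained by averaging the
  primal weight vectors (and biases) of the ten fold models and the
  complete-estimation-set model, then the same scaling regression.
* **Significance** permutes targets within the estimation set only and
  reruns the full CV + scaling + evaluation with the identical fold
  structure (fold kernels are reused — features are unchanged under target
  permutation). `p = (1 + #{perm ≥ obs})/(1 + n_perm)` for r, with ≤ for
  MSE. Held-out p-values use the permuted-model averaged-weight predictor
  against the untouched held-out targets and are labelled as such.
  Because the scaling regression makes the out-of-fold MSE a deterministic
  decreasing function of r² under target permutation, the training-run
  `p_mse` equals a two-sided version of `p_r` and the two often coincide.
* **Information hygiene**: held-out subjects never enter kernel centring,
  fold models or the scaling regression (asserted by corrupting held-out
  rows and checking estimation-side invariance).

Default `n_perm` is 1000 for desk-scale runs; 10 000 reproduces the original
setting.

## Synthetic cohorts

The generator produces the structures the analysis assumes, with recorded
ground truth:

* **Rest.** Per subject, innovations `z_t ~ N(0, Σ_i)` filtered by
  `x_t = a·x_{t−1} + √(1−a²)·z_t` (a = 0.3), which preserves the spatial
  covariance exactly. `Σ_i` is the group block-correlation matrix (0.5
  within network, 0.1 between, nine networks) plus subject-specific
  structure, clipped to ±0.9 and repaired to the nearest positive-definite
  correlation by eigenvalue clipping. Acquisition mirrors the three sites:
  TR/volumes of 2.5 s × 120, 2.0 s × 143 and 2.7 s × 107.
* **Between-subject structure.** Individual FC differences are dominated by
  a handful of latent connectivity modes rather than independent edge noise:
  each subject expresses K = 5 modes with standard-normal amplitudes
  (clipped at ±2.5). One mode is sign-aligned with the true weight support;
  the rest are distractors on other networks' edges. A small iid edge jitter
  (sd 0.03) is added. This low-rank structure is what makes FC-based
  prediction possible at n ≪ edges; with independent edge noise instead, a
  kernel learner's ceiling is r ≈ √(n/d) regardless of target noise. The
  iid regime remains available (`mode_strength = 0`) and is the regime in
  which the edge-weight vector is identifiable, so weight-recovery
  consistency (recovery improving with cohort size) is demonstrated there;
  under low-rank variation many weight vectors yield identical predictions
  and recovery plateaus by construction.
* **Confounds.** Motion is a six-column random walk; WM/CSF pools are
  exactly rank-2 smooth latent signals with random loadings. All three are
  mixed linearly into the ROI series with recorded coefficients, so the
  combined nuisance regression removes them exactly (tested at 1e-8).
* **Ground truth and targets.** True edge weights are equal-magnitude
  (±0.07) on a sparse support: the within-network pairs of the default-mode
  group plus five edges from it into every other network. The three
  measures share the support with overlapping sign patterns
  (maximal = 0.8·base + 0.2·alt, average = 0.6·base + 0.4·alt), so
  sensitivity and maximal targets correlate positively as they do
  empirically. Targets are `F·w + ε`, where `F` are the FC features
  computed by the package's own cleaning + Pearson path — with zero target
  noise the feature-to-target map is exactly linear in what the pipeline
  observes. Default target noise sd 0.5 puts the default cohort in the
  moderate-accuracy regime (r ≈ 0.4–0.6) typical of connectome-based
  prediction.
* **Task.** Per-subject anticipation amplitudes are derived by inverting
  the measure definitions (`c_x = maximal`, `c_s = maximal − 2·sensitivity`,
  `c_m = 3·average − c_s − c_x`), so the GLM path reproduces the linked
  targets; remaining regressors get small random amplitudes. The VS series
  is simulated as a single ROI column. Gaussian task noise sd 1.0 by
  default.

What the generator does **not** emulate: voxel-level imaging, scanner drift
and spike artifacts, motion-BOLD interactions, non-Gaussian heavy-tailed
noise, distance-dependent artifact structure, and site differences beyond
TR/duration. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated assumptions, not robustness to every
property of real fMRI.

## Numerical choices and degenerate inputs

* Sphere-ROI membership is inclusive (distance ≤ radius); bilateral spheres
  are unioned before averaging so overlapping voxels count once.
* `fc_matrix` fails loudly on zero-variance columns, naming the ROI.
* Rank ties in node/edge rankings break by ROI index; node sums and network
  aggregation use |weight| by default (the weight sign does not say whether
  a connection increases or decreases with the target), signed variants
  behind a flag.
* Fold sizes differ by at most one when the estimation count is not
  divisible by k (warned); constant targets in a fold are warned and fit
  anyway; constant raw scores make the scaling regression fail explicitly.
* The block-correlation builder repairs non-PD matrices by eigenvalue
  clipping with a warning and fails if repair is insufficient.
* Whether the rest-ROI "10 mm sphere" specification denotes a radius or a
  diameter is left as an explicit configuration choice (`radius_mm`,
  default 6 mm spheres for ROI definitions) rather than decided silently.

## Problem sizes

Default analyses run 45 subjects × 40 ROIs (780 edges), 10 + 1 RVR fits per
measure and 199–1000 permutations; the calibration experiments in the test
suite use 50 replicates at 199 permutations and 20 replicates at 499
permutations. These sizes were chosen so the entire validation cycle runs
on a laptop-class single core in minutes while keeping every structural
constant of the study design (cohort sizes 14/15/16, 30/15 split, folds of
three) intact. The published ROI count is much larger; only the ROI count
is scaled down.

## Known limitations

* Real-data headline values are not reproducible here: the original cohort
  is private, so all quantitative results refer to synthetic data.
* The RVR evidence can decrease in degenerate regimes (see above).
* The permutation test reports training-run significance in the toolbox
  sense; held-out p-values are a package addition and labelled as such.
* With the scaling regression fitted and evaluated on the same estimation
  scores, training-run MSE carries no information beyond r²; both are
  reported for completeness.
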