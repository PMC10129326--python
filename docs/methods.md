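# Methods

## The encoding model and its assumptions

Every model in this package is a multivariate linear encoding model
`Y = XW + E` mapping T×Q cortical parcel time series onto T×P cerebellar
voxel time series. The assumptions that matter:

* **Directionality is a modelling choice, not a causal claim.** Predicting
  cerebellum from cortex is motivated by the physiology of the cerebellar
  BOLD signal (dominated by pontine input), but the regression itself is
  symmetric-agnostic.
* **Task-evoked signal only.** Both sides are *fitted* time series, the
  first-level design matrix multiplied by run-averaged condition betas
  (Z b̄). This removes all noise uncorrelated with the task and reweights
  each condition by its duration through Zᵀ Z: a 5 s instruction regressor
  contributes a sixth of the leverage of a 30 s condition block. Since no
  information survives beyond the K condition estimates, the fitted series
  live in a K-dimensional subspace; T counts timepoints but the effective
  degrees of freedom are ≈ K.
* **Stationary weights.** One W per participant is assumed to hold across
  sessions and task sets; generalization to a held-out task set is exactly
  the test of this assumption.

### Normalization conventions

Fitted series are divided by the per-channel GLM residual SD (emphasizing
high-SNR channels), cortical series are averaged within parcels, and the
cortical matrix is z-standardized column-wise with the population
convention (divisor T). The cerebellar side is not centered; because
z-scored predictors are orthogonal to the constant vector, the uncentered
mean of Y is simply not absorbed by the fit and Pearson-r evaluation is
invariant to it. Inside cross-validation, each fold's reconstructed series
is treated as its own training set: X is re-standardized with the training
fold's moments (applied unchanged to the held-out fold) and Y is centered
with training-fold means. Without this, the interaction of global
centering with row-subsetting distorts fold fits even on noiseless data.

### Crossed session pairs

A crossed pair combines cortical data from session j with cerebellar data
from session j′ ≠ j of the same task set, both reconstructed on one
canonical design matrix (blocks in task order, regressors aligned by
label). Any noise process shared between cortex and cerebellum *within* a
session — head motion, physiological artifacts, especially problematic
where the superior cerebellum abuts occipital cortex — is independent
between the two members of a pair and therefore cannot inflate
connectivity estimates. The package enforces crossing at evaluation time;
uncrossed evaluation requires an explicit override.

## Estimators

* **WTA**: per voxel, the winner is the parcel with the highest *signed*
  correlation (ties go to the lowest parcel index); the winning weight is
  the univariate least-squares slope so predictions live on the response
  scale.
* **Ridge**: `(XᵀX + λI)⁻¹XᵀY` via one Cholesky factorization shared by
  all voxels; λ = 0 on rank-deficient X falls back to the minimum-norm
  solution with a warning.
* **Lasso**: coordinate descent (scikit-learn's solver) wrapped so the
  solution minimizes `‖Y−XW‖² + λ‖W‖₁` with no 1/2 or 1/n prefactor;
  the solver's per-sample penalty is α = λ/(2T). Non-converged voxels are
  flagged, never silently accepted.

λ is always carried on the natural-log scale. One λ is shared across all
voxels of a participant/method/parcel-set combination, chosen by grid
search (default 17 points, log λ ∈ {−8 … 8}) with fourfold
cross-validation over *tasks*: each task's conditions and its instruction
regressor stay in the same fold, folds are a seeded random partition, and
the chosen λ maximizes mean held-out per-voxel r (ties to the smaller λ).
During grid search the solver runs with a relaxed tolerance (1e-4, 300
iterations, warm-started along the descending λ path); final fits use the
tight tolerance (1e-6).

## Noise ceilings

Writing a session's cerebellar series as Y = Y* + ε and the prediction's
session-to-session variability as σ²_XW, the split-half reliabilities
r(Y₁,Y₂) = σ²_Y/(σ²_Y+σ²_ε) and r(X₁W,X₂W) = σ²_Y/(σ²_Y+σ²_XW) combine
into the expected correlation of the true model,

    r_ceil = σ²_Y / sqrt((σ²_Y+σ²_XW)(σ²_Y+σ²_ε)) = sqrt(r(Y₁,Y₂)·r(X₁W,X₂W)).

The square root is forced by the variance decomposition. The ceiling is
*model dependent* through r(X₁W,X₂W): weight vectors concentrated on a
single parcel replicate the cortical measurement noise of that parcel and
ceiling lower; averaging weight vectors replicate better and ceiling
higher. In population terms a model's ceiling-normalized accuracy equals
the correlation between its noise-free prediction and the true signal, so
it cannot systematically exceed 1 — per-voxel estimates are however noisy
ratios (effective df ≈ K), so single-voxel values above 1 occur and small
upward bias of the mean ratio at very low reliability is expected. Voxels
with non-positive reliabilities have no defined ceiling and are excluded
from normalized summaries (counted separately).

For datasets evaluated session by session (e.g. new participants scored
with group-averaged weights), the same construction runs on odd/even run
splits within each session, with observed accuracy crossed across the run
halves, and per-session normalized accuracies averaged.

## Convergence metrics

* **Input area** — fraction of parcels with retained weights. Lasso/WTA
  count exact non-zeros (negative non-zeros are still inputs); ridge
  retains weights above mean + 1 SD of the entire weight matrix (a
  per-voxel threshold variant is available).
* **Spherical dispersion** — negative weights are zeroed, each
  hemisphere's weights are normalized to unit sum, and
  var_h = 1 − ‖Σ ŵᵢ vᵢ‖ over the parcel-center unit vectors; hemispheres
  combine weighted by their summed non-negative weight. The unit-sum
  normalization keeps the metric scale-invariant and inside [0, 1]; a
  literal 1/Q_h averaging variant is exposed via `normalization="literal"`
  for comparison, with the caveat that it is not scale-invariant.

## The synthetic-data generator

The generator emulates a multi-domain task battery: two task sets of 17
tasks (35 s blocks: 5 s instruction + conditions splitting the remaining
30 s), giving 46 regressors (set A, 29 conditions) or 49 (set B, 32
conditions); two sessions per set; 8 runs per session with block order
permuted per run; TR 1 s, 600 timepoints per run. Cortical parcels are
Fibonacci-lattice points on per-hemisphere unit spheres at any even count
(80–1848 in the studies this mirrors).

Cortical condition profiles follow a Gaussian-process factor model: a
share c² of each parcel's variance (collinearity knob c, default 0.9)
comes from a latent condition-profile field varying smoothly over the
cortical sphere (squared-exponential loadings, chord length scale 0.8),
the rest is parcel-specific. The defaults give neighboring parcels signal
correlations around 0.7–0.8, the strongly collinear, spatially smooth
regime characteristic of task-evoked cortical maps; profile variance
defaults to 1, mirroring z-standardized cortical features. Each session
observes the set's true profiles plus independent Gaussian session noise
(variance 0.1). Cerebellar run-level betas are X W_true + E with per-run
noise variance 8 × 0.25 so the 8-run session average carries the nominal
noise variance 0.25; sessions are independent. Residual SDs are log-normal
around 1 (σ_log = 0.2), multiplied into the raw betas and reported, so the
SNR-normalization stage is exercised non-trivially. An optional
within-session artifact adds the same noise series to a cortical parcel
and to the cerebellar voxels anatomically linked to it (links fixed across
sessions, values redrawn per session), creating exactly the leakage
structure that crossed training must reject.

Ground truths: `one_to_one` (one random parcel per voxel, weight 1 — the
constant is irrelevant under Pearson evaluation), `convergent` (i.i.d.
N(0, 0.2) weights), and `regional` (per-region input-area fractions with
N(0, 0.2) values on a random support).

What the generator does **not** emulate: hemodynamic convolution (boxcars
suffice because all estimator contracts operate on Z b̄, where the HRF
shape cancels), spatial autocorrelation within the cerebellum,
physiological noise spectra, and real cortical topography. Passing tests
therefore validate the estimators, the crossing logic, the ceiling
algebra, and the convergence metrics — not claims about any particular
real dataset.

## Simulation experiments

**Model recovery** trains on a simulated task-set-A pair and evaluates
crossed on a task-set-B pair generated from the same ground truth, for
both scenarios and all three estimators, with full λ tuning. Under
one-to-one truth WTA wins on mean normalized accuracy (lasso close behind
— it must pay for any spurious support; ridge far lower); under convergent
truth ridge wins with lasso intermediate. The test-scale configuration
(Q = 80, 200 voxels, 20 seeds) reproduces the ordering in 20/20
replicates; the package default is 2000 voxels.

**Collinearity control** asks whether regional input-area differences
could be artifacts of cortical collinearity: every voxel of a region is
made to copy the profile of the region's most similar parcel (highest
mean lasso coefficient in a preliminary CV-tuned fit), plus noise at the
standard 0.25 variance, and lasso is refit at a *fixed* penalty of −3 on
the per-sample log scale (the scale tuned penalties are reported on;
internally λ = 2T·e⁻³). Because all voxels of a region copy one parcel,
voxels are not exchangeable within a seed — the null that matters is
*consistency across replicates*, so the test statistic is the variance
across regions of replicate-averaged region means, against a null that
permutes region labels independently within each replicate. Region
differences driven by parcel luck stay inside the null band; only effects
aligned across replicates could exceed it, and none do.

## Numerical choices and degenerate inputs

* Channels with non-positive residual SD, zero-variance columns before
  z-scoring, and empty parcels are dropped with warnings and recorded, so
  downstream maps keep aligned indices.
* Zero-variance cerebellar voxels get zero WTA weights and NaN
  correlations; NaNs are excluded from all summaries and counted.
* CV candidate λs whose fits produce constant predictions everywhere
  (e.g. lasso at full shrinkage) score −∞ rather than propagating NaN.
* All randomness flows through named substreams of a single seed per call
  (`numpy.random.SeedSequence`); every simulation is bit-reproducible.
* Interchange tables are TSV with shortest round-trip float formatting and
  are re-read with round-trip parsing, so load/save cycles are
  byte-identical and manifests carry SHA-256 content hashes.

## Known limitations

* Lasso and ridge recover different absolute input areas on identical
  data (sparsity-inducing vs spreading priors); the regional *ranking* is
  the robust quantity, and tests assert only rankings.
* The mean of per-voxel normalized accuracies is a noisy-ratio average
  and can sit a fraction of a percent above 1 for near-true models.
* The factor-model cortex is statistically homogeneous across the sphere;
  region-specific cortical topography (e.g. contralateral organization)
  is out of scope.
* At fine parcellations (Q ≫ K) the cortical matrix is necessarily
  rank-deficient; estimators handle this (ridge regularizes, lasso
  selects, WTA ignores it), but parameter recovery in the strict sense is
  only identifiable at Q below the regressor count.
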