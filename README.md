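# cerebconn

Task-general cortico-cerebellar connectivity models from task-evoked fMRI.

Nearly all of the cerebellar BOLD signal reflects input from the neocortex
(via the pons), which makes directional encoding models — predict each
cerebellar voxel from cortical activity — a natural probe of
cortico-cerebellar connectivity. The scientific question these models
address is *convergence*: does a cerebellar region receive input from a
single cortical area (a one-to-one architecture) or integrate input from
many (a convergent architecture)? `cerebconn` implements the full modelling
pipeline for researchers who work with multi-session task-battery designs:
fitted-time-series reconstruction, crossed-session training, three
estimator families spanning the sparsity spectrum, model-dependent noise
ceilings, and per-voxel convergence metrics — together with a synthetic
data generator so every stage can be validated against known ground truth
without any imaging data.

## The model

Each cerebellar voxel's task-evoked time series is a linear combination of
Q cortical parcel time series,

    Y = X W + E,           X: T x Q,  Y: T x P,  W: Q x P,

where X and Y are *fitted* time series: the first-level design matrix Z
multiplied by run-averaged condition betas (Z b̄), divided by the GLM
residual SD, with the cortical side parcel-averaged and z-standardized.
Working on Z b̄ rather than b̄ reweights every condition by its duration
through Zᵀ Z and removes noise uncorrelated with the task.

Three estimators place different priors on each voxel's weight column:

* **WTA** (winner-take-all) — one non-zero weight: the parcel with the
  highest correlation with the voxel;
* **Lasso** — `argmin ‖Y − XW‖² + λ‖W‖₁` (sparse support);
* **Ridge** — `argmin ‖Y − XW‖² + λ‖W‖₂²` (broad, shrunk support);

with λ tuned by grid search under fourfold condition-wise cross-validation.
Training and evaluation are *crossed*: cortical data from one session are
paired with cerebellar data from the other session of the same task set, so
noise shared within a session (motion, physiology) cannot masquerade as
connectivity.

Observed accuracy (per-voxel Pearson r between predicted and held-out
series, averaged over the two crossed directions) is normalized by the
model-dependent noise ceiling

    r_ceil = sqrt( r(Y₁, Y₂) · r(X₁W, X₂W) ),

the correlation the model would achieve if its weights were the true ones,
given the measured split-half reliabilities of the cerebellar data and of
the model predictions.

Convergence is quantified two ways per voxel: **input area** — the fraction
of parcels with retained weights (exact non-zeros for lasso/WTA; above
mean + 1 SD of the weight matrix for ridge) — and **spherical dispersion**
`1 − ‖Σ ŵᵢ vᵢ‖` of the non-negative weights over the parcel-center unit
vectors of each cortical hemisphere.

## Worked example

```python
import cerebconn as cc

parcels = cc.make_parcel_set(80, seed=1)
truth   = cc.make_ground_truth(parcels, n_voxels=200, scenario="convergent", seed=1)
train   = cc.simulate_study("A", parcels, truth, seed=3)   # 2 sessions, 46 regressors
test    = cc.simulate_study("B", parcels, truth, seed=4)   # 2 sessions, 49 regressors

tr = [cc.reconstruct_session(s) for s in train.sessions]
te = [cc.reconstruct_session(s) for s in test.sessions]
pairs = cc.make_crossed_pairs(*tr)

grid = cc.tune_lambda(pairs, "ridge", seed=1)
weights = cc.fit_ridge(pairs, grid.chosen)
result = cc.evaluate_model(weights, te[0], te[1])
print(grid.chosen, result.summary())
```

prints (numbers from this exact invocation):

```
7.0 {'mean_r_obs': 0.7852, 'mean_r_ceiling': 0.9287, 'mean_R_norm': 0.8432,
     'n_voxels': 200, 'n_undefined': 0}
```

The tuned ridge model predicts held-out task-set-B activity at mean r =
0.79 per voxel; relative to what the true weights could achieve given the
measurement noise (ceiling 0.93), it recovers 84% of the explainable
signal. Convergence metrics for the same fit:

```python
metrics = cc.convergence_metrics(weights, parcels)
print(round(metrics.input_area.mean(), 3))   # 0.157 — ~16% of parcels above mean+1SD
```

A `cerebconn` command-line tool exposes the same stages
(`simulate`, `fit`, `evaluate`, `converge`, `recover`, `all`) over a
TSV/JSON interchange layout; `cerebconn --help` lists them.

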