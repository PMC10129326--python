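"""Model-recovery and collinearity-control simulation studies.

Two experiments validate the whole pipeline end to end:

* model recovery — generate data under a known connectivity scenario
  (one-to-one: each voxel driven by a single random parcel; convergent:
  dense Gaussian weights), run the full train-on-set-A / test-on-set-B
  procedure including lambda tuning, and check which estimator family wins
  on ceiling-normalized accuracy.  WTA should win under one-to-one truth
  and ridge under convergent truth, with lasso intermediate.

* collinearity control — replace each cerebellar region's activity by the
  profile of its most similar cortical parcel (the parcel with the highest
  average lasso coefficient for that region in a preliminary fit), refit
  lasso at a fixed log-lambda of -3, and verify by permutation test that
  the estimated input area shows no systematic region differences: any
  apparent regional convergence structure under this one-to-one truth would
  be a collinearity artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .convergence import aggregate_by_region, input_area
from .estimators import fit_lasso, fit_ridge, fit_wta, tune_lambda
from .evaluation import evaluate_model
from .reconstruction import make_crossed_pairs, reconstruct_session
from .synthetic_data import (
    GroundTruth,
    RegionMap,
    make_ground_truth,
    make_parcel_set,
    make_region_map,
    make_regional_truth,
    simulate_dataset,
    simulate_study,
)

__all__ = [
    "RecoveryConfig",
    "RecoveryReport",
    "CollinearityConfig",
    "CollinearityResult",
    "run_model_recovery",
    "run_collinearity_control",
    "region_permutation_test",
    "region_consistency_test",
]

METHODS = ("wta", "lasso", "ridge")
SCENARIOS = ("one_to_one", "convergent")


@dataclass
class RecoveryConfig:
    """Study conditions for the model-recovery experiment.

    Defaults reproduce the simulated conditions end to end: 2000 voxels,
    session-level cerebellar noise variance 0.25, convergent weight variance
    0.2, both scenarios, all three estimators.
    """

    parcel_counts: tuple = (80,)
    n_voxels: int = 2000
    scenarios: tuple = SCENARIOS
    methods: tuple = METHODS
    noise_variance: float = 0.25
    weight_variance: float = 0.2
    collinearity: float = 0.9
    cortical_noise_variance: float = 0.1
    signal_variance: float = 1.0
    grid: np.ndarray | None = None
    n_folds: int = 4
    seeds: tuple = (0,)
    tr: float = 1.0


@dataclass
class RecoveryReport:
    """Per-cell results plus per-scenario winners."""

    table: pd.DataFrame             # one row per seed x scenario x Q x method
    winners: pd.DataFrame           # one row per seed x scenario x Q
    config: RecoveryConfig

    def winner_by_scenario(self) -> dict:
        """Overall winner per scenario by mean normalized accuracy."""
        means = (
            self.table.groupby(["scenario", "method"])["mean_R_norm"]
            .mean()
            .reset_index()
        )
        return {
            s: grp.loc[grp["mean_R_norm"].idxmax(), "method"]
            for s, grp in means.groupby("scenario")
        }


def _fit_method(method, pairs, lambda_grids):
    if method == "wta":
        return fit_wta(pairs)
    if method == "ridge":
        return fit_ridge(pairs, lambda_grids["ridge"].chosen)
    if method == "lasso":
        return fit_lasso(pairs, lambda_grids["lasso"].chosen)
    raise ValueError(f"unknown method {method!r}")


def run_model_recovery(config: RecoveryConfig | None = None) -> RecoveryReport:
    """Run the full model-recovery experiment defined by ``config``.

    For every (seed, scenario, parcel count): simulate a two-session
    training set (task set A structure) and a two-session test set (task
    set B structure) from one ground-truth weight matrix, tune lambda by
    condition-wise CV on the crossed training pairs, fit every requested
    estimator, and evaluate crossed on the test set with model-dependent
    noise ceilings.  Deterministic given the seeds in the config.
    """
    config = config or RecoveryConfig()
    for s in config.scenarios:
        if s not in SCENARIOS:
            raise ValueError(f"unknown scenario {s!r}")
    rows = []
    for seed in config.seeds:
        for Q in config.parcel_counts:
            parcels = make_parcel_set(Q, seed=seed)
            for scenario in config.scenarios:
                truth = make_ground_truth(
                    parcels,
                    config.n_voxels,
                    scenario,
                    seed=seed,
                    noise_variance=config.noise_variance,
                    weight_variance=config.weight_variance,
                )
                sim_kw = dict(
                    collinearity=config.collinearity,
                    cortical_noise_variance=config.cortical_noise_variance,
                    signal_variance=config.signal_variance,
                    tr=config.tr,
                )
                train = simulate_study(
                    "A", parcels, truth, seed=2 * seed + 1, **sim_kw
                )
                test = simulate_study(
                    "B", parcels, truth, seed=2 * seed + 2, **sim_kw
                )
                tr_fit = [reconstruct_session(s) for s in train.sessions]
                te_fit = [reconstruct_session(s) for s in test.sessions]
                train_pairs = make_crossed_pairs(*tr_fit)
                grids = {}
                for m in ("lasso", "ridge"):
                    if m in config.methods:
                        grids[m] = tune_lambda(
                            train_pairs, m, grid=config.grid,
                            n_folds=config.n_folds, seed=seed,
                        )
                for method in config.methods:
                    weights = _fit_method(method, train_pairs, grids)
                    result = evaluate_model(weights, te_fit[0], te_fit[1])
                    summ = result.summary()
                    rows.append(
                        {
                            "seed": seed,
                            "scenario": scenario,
                            "Q": Q,
                            "n_voxels": config.n_voxels,
                            "method": method,
                            "mean_r_obs": summ["mean_r_obs"],
                            "mean_R_norm": summ["mean_R_norm"],
                            "mean_r_ceiling": summ["mean_r_ceiling"],
                            "log_lambda": weights.log_lambda,
                            "n_undefined": summ["n_undefined"],
                        }
                    )
    table = pd.DataFrame(rows)
    win_rows = []
    for (seed, scenario, Q), grp in table.groupby(["seed", "scenario", "Q"]):
        best = grp.loc[grp["mean_R_norm"].idxmax()]
        win_rows.append(
            {"seed": seed, "scenario": scenario, "Q": Q, "winner": best["method"]}
        )
    return RecoveryReport(
        table=table, winners=pd.DataFrame(win_rows), config=config
    )


def region_permutation_test(
    values: np.ndarray,
    region_labels: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
):
    """Permutation test for systematic between-region differences.

    The statistic is the variance of region means of ``values``; the null
    distribution shuffles region labels across voxels.  Returns a dict with
    the observed statistic, the permutation p-value, and the null 95%
    quantile.
    """
    values = np.asarray(values, dtype=float)
    region_labels = np.asarray(region_labels)
    ok = ~np.isnan(values)
    values, region_labels = values[ok], region_labels[ok]
    regions = np.unique(region_labels)

    def stat(labels):
        means = np.array(
            [values[labels == r].mean() for r in regions]
        )
        return means.var()

    observed = stat(region_labels)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 607]))
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = stat(rng.permutation(region_labels))
    p_value = (1 + np.sum(null >= observed)) / (1 + n_permutations)
    return {
        "observed": float(observed),
        "p_value": float(p_value),
        "null_q95": float(np.quantile(null, 0.95)),
        "null": null,
    }


def region_consistency_test(
    region_means: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
):
    """Permutation test for region differences consistent across replicates.

    ``region_means`` is an (n_replicates, n_regions) array of per-replicate
    region means.  The statistic is the variance across regions of the
    replicate-averaged means; the null permutes region labels independently
    within each replicate, so replicate-specific fluctuations (e.g. which
    parcel a region happened to copy) remain under the null and only
    region effects that are consistent across replicates can exceed it.
    """
    M = np.asarray(region_means, dtype=float)
    if M.ndim != 2:
        raise ValueError("region_means must be (n_replicates, n_regions)")
    observed = M.mean(axis=0).var()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 709]))
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = np.array([rng.permutation(row) for row in M])
        null[i] = perm.mean(axis=0).var()
    p_value = (1 + np.sum(null >= observed)) / (1 + n_permutations)
    return {
        "observed": float(observed),
        "p_value": float(p_value),
        "null_q95": float(np.quantile(null, 0.95)),
    }


@dataclass
class CollinearityResult:
    """Output of the collinearity-control simulation."""

    region_table: pd.DataFrame      # per seed x region input-area summaries
    per_seed: list                  # per-seed voxel-level permutation diagnostics
    across_seed: dict               # consistency test across seeded replicates
    config: "CollinearityConfig"


@dataclass
class CollinearityConfig:
    """Study conditions for the collinearity-control simulation."""

    n_parcels: int = 80
    n_voxels: int = 2000
    n_regions: int = 10
    base_input_areas: tuple | None = None   # defaults to linspace(0.05, 0.10)
    control_noise_variance: float = 0.25
    # fixed L1 penalty of the control fit, on the per-sample (solver alpha)
    # scale: alpha = exp(control_log_lambda); converted internally to the
    # sum-of-squares objective's lambda = 2 T alpha
    control_log_lambda: float = -3.0
    noise_variance: float = 0.25
    weight_variance: float = 0.2
    collinearity: float = 0.9
    grid: np.ndarray | None = None
    n_folds: int = 4
    seeds: tuple = (0,)
    n_permutations: int = 500
    tr: float = 1.0


def run_collinearity_control(config: CollinearityConfig | None = None):
    """Run the collinearity-control simulation.

    Per seed: (1) simulate a base dataset with regionally varying true input
    area and fit lasso at the CV-tuned lambda; (2) find, per region, the
    cortical parcel with the highest average lasso coefficient; (3) simulate
    control data in which every voxel of a region copies that parcel's
    profile plus small noise (one-to-one truth); (4) fit lasso at the fixed
    control log-lambda and compute per-region input areas; (5) test whether
    region differences are consistent across the seeded replicates (the
    systematic effect the control is designed to exclude); per-seed
    voxel-level permutation diagnostics are also reported.  Returns a
    ``CollinearityResult``.
    """
    config = config or CollinearityConfig()
    R = config.n_regions
    if config.n_parcels < R:
        raise ValueError("need at least as many parcels as regions")
    if R < 2:
        raise ValueError("need at least 2 regions")
    areas = (
        tuple(np.linspace(0.05, 0.10, R))
        if config.base_input_areas is None
        else tuple(config.base_input_areas)
    )
    region_rows = []
    perm_results = []
    for seed in config.seeds:
        parcels = make_parcel_set(config.n_parcels, seed=seed)
        region_map = make_region_map(config.n_voxels, R)
        base_truth = make_regional_truth(
            parcels, region_map, list(areas), seed=seed,
            noise_variance=config.noise_variance,
            weight_variance=config.weight_variance,
        )
        base = simulate_study(
            "A", parcels, base_truth, seed=3 * seed + 1,
            collinearity=config.collinearity, tr=config.tr,
        )
        base_fit = [reconstruct_session(s) for s in base.sessions]
        base_pairs = make_crossed_pairs(*base_fit)
        grid = tune_lambda(
            base_pairs, "lasso", grid=config.grid,
            n_folds=config.n_folds, seed=seed,
        )
        prelim = fit_lasso(base_pairs, grid.chosen)
        # most similar parcel per region: highest average lasso coefficient
        best_parcel = {}
        for r in region_map.regions:
            mean_coef = prelim.W[:, region_map.voxel_regions == r].mean(axis=1)
            best_parcel[int(r)] = int(np.argmax(mean_coef))
        W_ctrl = np.zeros((config.n_parcels, config.n_voxels))
        for p in range(config.n_voxels):
            W_ctrl[best_parcel[int(region_map.voxel_regions[p])], p] = 1.0
        ctrl_truth = GroundTruth(
            W_true=W_ctrl,
            scenario="one_to_one",
            noise_variance=config.control_noise_variance,
            weight_variance=config.weight_variance,
            seed=seed,
        )
        # same simulation seed as the base study -> identical cortical data
        ctrl = simulate_dataset(
            [s.schedule for s in base.sessions], parcels, ctrl_truth,
            seed=3 * seed + 1, collinearity=config.collinearity,
        )
        ctrl_fit = [reconstruct_session(s) for s in ctrl.sessions]
        ctrl_pairs = make_crossed_pairs(*ctrl_fit)
        T_rows = sum(p.X.shape[0] for p in ctrl_pairs)
        log_lambda_obj = config.control_log_lambda + np.log(2.0 * T_rows)
        weights = fit_lasso(ctrl_pairs, log_lambda_obj)
        area = input_area(weights)
        summary = aggregate_by_region(area, region_map)
        summary.insert(0, "seed", seed)
        region_rows.append(summary)
        perm = region_permutation_test(
            area, region_map.voxel_regions,
            n_permutations=config.n_permutations, seed=seed,
        )
        perm.pop("null")
        perm["seed"] = seed
        perm["log_lambda"] = config.control_log_lambda
        perm["n_parcels"] = config.n_parcels
        perm_results.append(perm)
    region_table = pd.concat(region_rows, ignore_index=True)
    M = region_table.pivot(index="seed", columns="region", values="mean")
    across = region_consistency_test(
        M.to_numpy(), n_permutations=config.n_permutations,
        seed=min(config.seeds),
    )
    return CollinearityResult(
        region_table=region_table,
        per_seed=perm_results,
        across_seed=across,
        config=config,
    )
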