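"""Synthetic multi-session task-fMRI data with known cortico-cerebellar connectivity.

Emulates the structure of a multi-domain task battery: two task sets of 17
task blocks each (35 s blocks, 5 s instruction + condition periods), two
sessions per set, 8 runs per session, cortical activity summarised in
parcels on spherical hemisphere surfaces, and cerebellar voxel activity
generated as a linear combination of cortical parcel activity plus Gaussian
measurement noise.  Everything downstream (reconstruction, estimation,
evaluation, convergence) can therefore be tested against a known ground
truth without any imaging data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParcelSet",
    "TaskSchedule",
    "TaskDesign",
    "GroundTruth",
    "RegionMap",
    "SessionRecording",
    "SimulatedStudy",
    "make_parcel_set",
    "make_schedule",
    "make_ground_truth",
    "make_regional_truth",
    "make_region_map",
    "simulate_dataset",
    "simulate_study",
]

# Block layout: 17 tasks per set, 35 s blocks with a 5 s instruction period.
N_TASKS = 17
BLOCK_SECONDS = 35.0
INSTRUCTION_SECONDS = 5.0

# Conditions per task, summing to 29 (set A) and 32 (set B); together with
# one instruction regressor per task this yields 46 and 49 regressors.
_CONDITIONS_PER_TASK = {
    "A": [2] * 12 + [1] * 5,
    "B": [2] * 15 + [1] * 2,
}


@dataclass(frozen=True)
class ParcelSet:
    """Cortical parcels as unit vectors on per-hemisphere spheres."""

    parcel_ids: np.ndarray          # (Q,) int
    hemisphere: np.ndarray          # (Q,) 'L' or 'R'
    centers: np.ndarray             # (Q, 3) unit norm

    @property
    def Q(self) -> int:
        return len(self.parcel_ids)

    def hemisphere_counts(self) -> dict:
        return {h: int(np.sum(self.hemisphere == h)) for h in ("L", "R")}


@dataclass(frozen=True)
class TaskDesign:
    """A boxcar design matrix with its regressor metadata."""

    matrix: np.ndarray              # (T, K)
    labels: tuple                   # (K,) regressor labels
    kinds: tuple                    # (K,) 'instruction' | 'condition'
    task_ids: tuple                 # (K,) owning task label
    timepoint_regressor: np.ndarray  # (T,) index of active regressor, -1 = rest

    @property
    def T(self) -> int:
        return self.matrix.shape[0]

    @property
    def K(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class TaskSchedule:
    """Block schedule of one session: regressors, onsets, per-run block order."""

    session_id: str
    task_set: str                   # 'A' or 'B'
    labels: tuple                   # (K,) regressor labels, canonical order
    kinds: tuple                    # (K,)
    task_ids: tuple                 # (K,)
    run_count: int
    timepoints_per_run: int
    tr: float                       # seconds per timepoint
    block_orders: tuple             # run_count tuples of task indices
    onsets: dict                    # run -> {label: onset seconds}
    durations: dict                 # label -> duration seconds

    @property
    def K(self) -> int:
        return len(self.labels)

    def design(self, run: int | None = None) -> TaskDesign:
        """Boxcar design matrix; ``run=None`` gives the canonical task order."""
        order = (
            tuple(range(N_TASKS)) if run is None else self.block_orders[run]
        )
        T, K = self.timepoints_per_run, self.K
        Z = np.zeros((T, K))
        tp_reg = np.full(T, -1, dtype=int)
        label_index = {lab: k for k, lab in enumerate(self.labels)}
        t_block = 0.0
        for task_idx in order:
            task = _task_label(self.task_set, task_idx)
            for lab in self.labels:
                if self.task_ids[label_index[lab]] != task:
                    continue
                onset = t_block + self._offset_within_block(lab)
                dur = self.durations[lab]
                a = int(round(onset / self.tr))
                b = int(round((onset + dur) / self.tr))
                Z[a:b, label_index[lab]] = 1.0
                tp_reg[a:b] = label_index[lab]
            t_block += BLOCK_SECONDS
        return TaskDesign(
            matrix=Z,
            labels=self.labels,
            kinds=self.kinds,
            task_ids=self.task_ids,
            timepoint_regressor=tp_reg,
        )

    def _offset_within_block(self, label: str) -> float:
        k = self.labels.index(label)
        if self.kinds[k] == "instruction":
            return 0.0
        task = self.task_ids[k]
        conds = [
            lab
            for lab, kind, tid in zip(self.labels, self.kinds, self.task_ids)
            if tid == task and kind == "condition"
        ]
        pos = conds.index(label)
        cond_dur = (BLOCK_SECONDS - INSTRUCTION_SECONDS) / len(conds)
        return INSTRUCTION_SECONDS + pos * cond_dur


@dataclass(frozen=True)
class GroundTruth:
    """True connectivity weights and the noise model used to generate data."""

    W_true: np.ndarray              # (Q, P)
    scenario: str                   # 'one_to_one' | 'convergent' | 'regional'
    noise_variance: float           # session-level cerebellar noise variance
    weight_variance: float
    seed: int

    @property
    def Q(self) -> int:
        return self.W_true.shape[0]

    @property
    def P(self) -> int:
        return self.W_true.shape[1]


@dataclass(frozen=True)
class RegionMap:
    """Assignment of each cerebellar voxel to exactly one labelled region."""

    voxel_regions: np.ndarray       # (P,) int region labels, 1..R
    region_names: tuple

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_regions)

    @property
    def regions(self) -> np.ndarray:
        return np.unique(self.voxel_regions)


@dataclass
class SessionRecording:
    """Raw per-session GLM-style outputs for one simulated session."""

    session_id: str
    schedule: TaskSchedule
    X_betas: np.ndarray             # (K, Q) run-averaged cortical betas, raw scale
    Y_betas: np.ndarray             # (K, P) run-averaged cerebellar betas, raw scale
    X_run_betas: np.ndarray         # (R, K, Q)
    Y_run_betas: np.ndarray         # (R, K, P)
    residual_sd_cortex: np.ndarray  # (Q,)
    residual_sd_cerebellum: np.ndarray  # (P,)


@dataclass
class SimulatedStudy:
    """All sessions of one task set plus the generating ground truth."""

    task_set: str
    sessions: list
    parcels: ParcelSet
    truth: GroundTruth
    region_map: RegionMap | None = None
    params: dict = field(default_factory=dict)


def _task_label(task_set: str, idx: int) -> str:
    return f"{task_set.lower()}{idx + 1:02d}"


def _hemisphere_lattice(n: int, axis_sign: float, phase: float) -> np.ndarray:
    """Fibonacci lattice of n approximately uniform points on a hemisphere.

    The hemisphere axis is +/- x so left/right parcels occupy disjoint
    half-spheres; ``phase`` rotates the lattice azimuthally.
    """
    i = np.arange(n)
    # uniform in the axial coordinate over (0, 1]
    c = (i + 0.5) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i + phase
    r = np.sqrt(1.0 - c**2)
    pts = np.column_stack([axis_sign * c, r * np.cos(theta), r * np.sin(theta)])
    return pts


def make_parcel_set(n_parcels: int, seed: int = 0) -> ParcelSet:
    """Build a parcel set of ``n_parcels`` split evenly between hemispheres.

    Centers are Fibonacci-lattice points on each hemisphere's unit sphere,
    deterministic given ``seed`` (which only sets the azimuthal phase).
    """
    if n_parcels < 2 or n_parcels % 2 != 0:
        raise ValueError(f"n_parcels must be even and >= 2, got {n_parcels}")
    n_h = n_parcels // 2
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 911]))
    phase = rng.uniform(0, 2 * np.pi)
    left = _hemisphere_lattice(n_h, -1.0, phase)
    right = _hemisphere_lattice(n_h, +1.0, phase)
    centers = np.vstack([left, right])
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    hemisphere = np.array(["L"] * n_h + ["R"] * n_h)
    return ParcelSet(
        parcel_ids=np.arange(n_parcels),
        hemisphere=hemisphere,
        centers=centers,
    )


def make_schedule(
    task_set: str,
    timepoints_per_run: int | None = None,
    seed: int = 0,
    session_id: str | None = None,
    run_count: int = 8,
    tr: float = 1.0,
) -> TaskSchedule:
    """Build a session schedule for task set 'A' (46 regressors) or 'B' (49).

    Each of the 17 tasks occupies one 35 s block per run: a 5 s instruction
    period followed by the task's conditions splitting the remaining 30 s
    equally.  Block order is permuted independently per run from ``seed``.
    """
    task_set = task_set.upper()
    if task_set not in _CONDITIONS_PER_TASK:
        raise ValueError(f"task_set must be 'A' or 'B', got {task_set!r}")
    needed = int(np.ceil(N_TASKS * BLOCK_SECONDS / tr))
    if timepoints_per_run is None:
        timepoints_per_run = needed + int(round(5 / tr))
    if timepoints_per_run < needed:
        raise ValueError(
            f"timepoints_per_run={timepoints_per_run} cannot hold "
            f"{N_TASKS} blocks of {BLOCK_SECONDS}s at tr={tr} (need {needed})"
        )
    labels, kinds, task_ids, durations = [], [], [], {}
    for t_idx, n_cond in enumerate(_CONDITIONS_PER_TASK[task_set]):
        task = _task_label(task_set, t_idx)
        instr = f"instr_{task}"
        labels.append(instr)
        kinds.append("instruction")
        task_ids.append(task)
        durations[instr] = INSTRUCTION_SECONDS
        cond_dur = (BLOCK_SECONDS - INSTRUCTION_SECONDS) / n_cond
        for c in range(n_cond):
            lab = f"{task}_c{c + 1}"
            labels.append(lab)
            kinds.append("condition")
            task_ids.append(task)
            durations[lab] = cond_dur
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 417]))
    block_orders = tuple(
        tuple(rng.permutation(N_TASKS).tolist()) for _ in range(run_count)
    )
    schedule = TaskSchedule(
        session_id=session_id or f"{task_set}1",
        task_set=task_set,
        labels=tuple(labels),
        kinds=tuple(kinds),
        task_ids=tuple(task_ids),
        run_count=run_count,
        timepoints_per_run=timepoints_per_run,
        tr=tr,
        block_orders=block_orders,
        onsets={},
        durations=durations,
    )
    onsets = {}
    for r in range(run_count):
        run_onsets = {}
        t_block = 0.0
        for task_idx in schedule.block_orders[r]:
            task = _task_label(task_set, task_idx)
            for lab, kind, tid in zip(labels, kinds, task_ids):
                if tid == task:
                    run_onsets[lab] = t_block + schedule._offset_within_block(lab)
            t_block += BLOCK_SECONDS
        onsets[r] = run_onsets
    return dataclasses.replace(schedule, onsets=onsets)


def make_ground_truth(
    parcels: ParcelSet,
    n_voxels: int,
    scenario: str,
    seed: int = 0,
    noise_variance: float = 0.25,
    weight_variance: float = 0.2,
) -> GroundTruth:
    """Draw a true weight matrix under the one-to-one or convergent scenario.

    one_to_one: each voxel is connected to exactly one random parcel with
    weight 1.  convergent: all Q x P entries are i.i.d. N(0, weight_variance).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    Q = parcels.Q
    if scenario == "one_to_one":
        W = np.zeros((Q, n_voxels))
        winners = rng.integers(0, Q, size=n_voxels)
        W[winners, np.arange(n_voxels)] = 1.0
    elif scenario == "convergent":
        W = rng.normal(0.0, np.sqrt(weight_variance), size=(Q, n_voxels))
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return GroundTruth(
        W_true=W,
        scenario=scenario,
        noise_variance=noise_variance,
        weight_variance=weight_variance,
        seed=int(seed),
    )


def make_region_map(
    n_voxels: int, n_regions: int, region_names: tuple | None = None
) -> RegionMap:
    """Split voxels into ``n_regions`` contiguous, near-equal regions."""
    if n_regions < 1 or n_regions > n_voxels:
        raise ValueError("need 1 <= n_regions <= n_voxels")
    labels = 1 + (np.arange(n_voxels) * n_regions) // n_voxels
    names = region_names or tuple(f"region{r}" for r in range(1, n_regions + 1))
    return RegionMap(voxel_regions=labels.astype(int), region_names=names)


def make_regional_truth(
    parcels: ParcelSet,
    region_map: RegionMap,
    input_area_per_region: dict | list,
    seed: int = 0,
    noise_variance: float = 0.25,
    weight_variance: float = 0.2,
) -> GroundTruth:
    """Ground truth whose true input area varies by cerebellar region.

    Voxels in region r get non-zero weights on exactly
    ``round(fraction_r * Q)`` randomly chosen parcels, values drawn
    N(0, weight_variance).
    """
    Q = parcels.Q
    regions = region_map.regions
    if not isinstance(input_area_per_region, dict):
        input_area_per_region = dict(zip(regions, input_area_per_region))
    for r in regions:
        frac = input_area_per_region[r]
        if not (0 < frac <= 1):
            raise ValueError(f"input-area fraction for region {r} not in (0,1]")
        if round(frac * Q) < 1:
            raise ValueError(
                f"fraction {frac} yields 0 parcels at Q={Q} for region {r}"
            )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    P = region_map.n_voxels
    W = np.zeros((Q, P))
    for p in range(P):
        frac = input_area_per_region[region_map.voxel_regions[p]]
        k = int(round(frac * Q))
        support = rng.choice(Q, size=k, replace=False)
        W[support, p] = rng.normal(0.0, np.sqrt(weight_variance), size=k)
    return GroundTruth(
        W_true=W,
        scenario="regional",
        noise_variance=noise_variance,
        weight_variance=weight_variance,
        seed=int(seed),
    )


def _factor_model_betas(
    rng: np.random.Generator,
    K: int,
    centers: np.ndarray,
    collinearity: float,
    length_scale: float,
) -> np.ndarray:
    """Condition-by-parcel signal with tunable, spatially structured collinearity.

    A share ``collinearity**2`` of each parcel's variance comes from a
    latent condition-profile field that varies smoothly over the cortical
    sphere (a Gaussian-process factor model: the latent factors have
    squared-exponential spatial loadings with chord length scale
    ``length_scale``); the rest is parcel specific.  Nearby parcels thus
    share signal the way neighbouring cortical regions do, with
    correlation ~ collinearity**2 * exp(-d^2 / (2 length_scale^2)).
    collinearity=0 gives i.i.d. parcel profiles; values near 1 give a
    strongly collinear cortical pattern matrix.
    """
    if not (0 <= collinearity < 1):
        raise ValueError("collinearity must be in [0, 1)")
    Q = centers.shape[0]
    d2 = np.sum(
        (centers[:, None, :] - centers[None, :, :]) ** 2, axis=-1
    )
    Kmat = np.exp(-d2 / (2.0 * length_scale**2)) + 1e-8 * np.eye(Q)
    L = np.linalg.cholesky(Kmat)
    S = rng.normal(size=(K, Q)) @ L.T       # smooth field, unit marginal var
    U = rng.normal(size=(K, Q))
    return collinearity * S + np.sqrt(1.0 - collinearity**2) * U


def simulate_dataset(
    schedules,
    parcels: ParcelSet,
    truth: GroundTruth,
    n_voxels: int | None = None,
    seed: int = 0,
    collinearity: float = 0.9,
    length_scale: float = 0.8,
    signal_variance: float = 1.0,
    cortical_noise_variance: float = 0.1,
    shared_noise_variance: float = 0.0,
    residual_sd_log_sigma: float = 0.2,
) -> SimulatedStudy:
    """Simulate all sessions of one task set from a ground-truth weight matrix.

    The task set has one true cortical condition pattern (factor model);
    each session observes it plus independent Gaussian session noise.  A
    session's cerebellar betas follow Y = X W_true + E using that session's
    *observed* cortical betas, with E independent across sessions (variance
    ``truth.noise_variance`` at the run-averaged session level).  An optional
    session-shared artifact, added to both X and Y of the same session,
    creates the within-session noise correlation that crossed training is
    designed to remove.  Raw betas are scaled by per-channel residual SDs
    (log-normal around 1) which are also reported, so the reconstruction
    stage's SNR normalization recovers the model-scale quantities.
    """
    schedules = list(schedules)
    if n_voxels is None:
        n_voxels = truth.P
    Q, P, K = parcels.Q, n_voxels, schedules[0].K
    if truth.W_true.shape != (Q, P):
        raise ValueError(
            f"truth.W_true has shape {truth.W_true.shape}, expected {(Q, P)}"
        )
    for s in schedules[1:]:
        if s.K != K or s.task_set != schedules[0].task_set:
            raise ValueError("all schedules must share one task set")
    root = np.random.SeedSequence([int(seed), 303])
    streams = root.spawn(2 + 4 * len(schedules))
    rng_signal = np.random.default_rng(streams[0])
    # voxel -> parcel adjacency used by the shared-artifact model; fixed
    # across sessions the way anatomical adjacency is
    rng_link = np.random.default_rng(streams[1])
    artifact_link = rng_link.integers(0, Q, size=P)
    # signal_variance sets the per-parcel condition-profile variance; the
    # default of 1 mirrors z-standardized cortical features
    B_star = np.sqrt(signal_variance) * _factor_model_betas(
        rng_signal, K, parcels.centers, collinearity, length_scale
    )

    run_count = schedules[0].run_count
    sessions = []
    for j, sched in enumerate(schedules):
        rng_x = np.random.default_rng(streams[2 + 4 * j])
        rng_y = np.random.default_rng(streams[3 + 4 * j])
        rng_sd = np.random.default_rng(streams[4 + 4 * j])
        rng_art = np.random.default_rng(streams[5 + 4 * j])
        # per-run noise variance run_count * v makes the run average have
        # variance exactly v
        x_run_sd = np.sqrt(run_count * cortical_noise_variance)
        y_run_sd = np.sqrt(run_count * truth.noise_variance)
        X_runs = B_star[None] + rng_x.normal(0, x_run_sd, size=(run_count, K, Q))
        Y_runs = X_runs @ truth.W_true + rng_y.normal(
            0, y_run_sd, size=(run_count, K, P)
        )
        if shared_noise_variance > 0:
            # within-session artifact correlating cortical and cerebellar
            # noise: each voxel shares the artifact of one random parcel
            # (kept per-channel so that, across voxels, crossed-evaluation
            # correlations stay independent and average to zero)
            art = rng_art.normal(
                0, np.sqrt(shared_noise_variance), size=(K, Q)
            )
            X_runs = X_runs + art[None]
            Y_runs = Y_runs + art[:, artifact_link][None]
        X_bar = X_runs.mean(axis=0)
        Y_bar = Y_runs.mean(axis=0)
        sd_x = np.exp(rng_sd.normal(0, residual_sd_log_sigma, size=Q))
        sd_y = np.exp(rng_sd.normal(0, residual_sd_log_sigma, size=P))
        sessions.append(
            SessionRecording(
                session_id=sched.session_id,
                schedule=sched,
                X_betas=X_bar * sd_x[None, :],
                Y_betas=Y_bar * sd_y[None, :],
                X_run_betas=X_runs * sd_x[None, None, :],
                Y_run_betas=Y_runs * sd_y[None, None, :],
                residual_sd_cortex=sd_x,
                residual_sd_cerebellum=sd_y,
            )
        )
    return SimulatedStudy(
        task_set=schedules[0].task_set,
        sessions=sessions,
        parcels=parcels,
        truth=truth,
        params={
            "seed": int(seed),
            "collinearity": collinearity,
            "length_scale": length_scale,
            "signal_variance": signal_variance,
            "cortical_noise_variance": cortical_noise_variance,
            "shared_noise_variance": shared_noise_variance,
            "residual_sd_log_sigma": residual_sd_log_sigma,
        },
    )


def simulate_study(
    task_set: str,
    parcels: ParcelSet,
    truth: GroundTruth,
    seed: int = 0,
    n_sessions: int = 2,
    tr: float = 1.0,
    **kwargs,
) -> SimulatedStudy:
    """Convenience wrapper: schedules for ``n_sessions`` sessions + simulate."""
    schedules = [
        make_schedule(
            task_set,
            seed=int(seed) * 97 + j,
            session_id=f"{task_set}{j + 1}",
            tr=tr,
        )
        for j in range(n_sessions)
    ]
    return simulate_dataset(schedules, parcels, truth, seed=seed, **kwargs)
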