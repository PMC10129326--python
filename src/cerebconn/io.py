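"""TSV + JSON interchange layout for simulated or user-supplied GLM outputs.

A *bundle* is a directory holding one task set's data: per-session tables
(``design_<id>.tsv``, ``betas_cortex_<id>.tsv``, ``betas_cerebellum_<id>.tsv``,
``residual_sd_<id>.tsv`` and the run-resolved beta tables), the parcel
geometry (``parcels.tsv``), optional region map (``regions.tsv``), the
generating ground truth for simulated data (``truth.json``), and a
``manifest.json`` recording every table's shape and SHA-256 content hash.
Tables are tab-delimited with a header row; floats use Python's shortest
round-trip representation, so a load/save cycle is byte identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import (
    GroundTruth,
    ParcelSet,
    RegionMap,
    SessionRecording,
    SimulatedStudy,
    TaskSchedule,
)

__all__ = ["write_bundle", "read_bundle", "write_table", "read_table"]

FORMAT_VERSION = 1


class CorruptBundleError(RuntimeError):
    """A bundle table does not match its manifest (hash or shape)."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_table(array, path: Path, columns=None) -> None:
    arr = np.asarray(array)
    if arr.ndim == 1:
        arr = arr[:, None]
    cols = columns or [f"c{i}" for i in range(arr.shape[1])]
    pd.DataFrame(arr, columns=cols).to_csv(path, sep="\t", index=False)


def read_table(path: Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", float_precision="round_trip").to_numpy()


def _schedule_to_json(s: TaskSchedule) -> dict:
    return {
        "session_id": s.session_id,
        "task_set": s.task_set,
        "labels": list(s.labels),
        "kinds": list(s.kinds),
        "task_ids": list(s.task_ids),
        "run_count": s.run_count,
        "timepoints_per_run": s.timepoints_per_run,
        "tr": s.tr,
        "block_orders": [list(b) for b in s.block_orders],
        "durations": s.durations,
    }


def _schedule_from_json(d: dict) -> TaskSchedule:
    return TaskSchedule(
        session_id=d["session_id"],
        task_set=d["task_set"],
        labels=tuple(d["labels"]),
        kinds=tuple(d["kinds"]),
        task_ids=tuple(d["task_ids"]),
        run_count=d["run_count"],
        timepoints_per_run=d["timepoints_per_run"],
        tr=d["tr"],
        block_orders=tuple(tuple(b) for b in d["block_orders"]),
        onsets={},
        durations={k: float(v) for k, v in d["durations"].items()},
    )


def write_bundle(study: SimulatedStudy, path) -> Path:
    """Write a study to ``path`` as the TSV/JSON interchange layout."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    tables = {}

    def put(name, array, columns=None):
        write_table(array, root / name, columns=columns)
        arr = np.asarray(array)
        shape = list(arr.shape if arr.ndim > 1 else (arr.shape[0], 1))
        tables[name] = {"shape": shape, "sha256": _sha256(root / name)}

    p = study.parcels
    parcel_df = pd.DataFrame(
        {
            "parcel_id": p.parcel_ids,
            "hemisphere": p.hemisphere,
            "x": p.centers[:, 0],
            "y": p.centers[:, 1],
            "z": p.centers[:, 2],
        }
    )
    parcel_df.to_csv(root / "parcels.tsv", sep="\t", index=False)
    tables["parcels.tsv"] = {
        "shape": list(parcel_df.shape),
        "sha256": _sha256(root / "parcels.tsv"),
    }
    if study.region_map is not None:
        rm = study.region_map
        rdf = pd.DataFrame(
            {"voxel": np.arange(rm.n_voxels), "region": rm.voxel_regions}
        )
        rdf.to_csv(root / "regions.tsv", sep="\t", index=False)
        tables["regions.tsv"] = {
            "shape": list(rdf.shape),
            "sha256": _sha256(root / "regions.tsv"),
        }
        (root / "region_names.json").write_text(
            json.dumps(list(rm.region_names))
        )
    sessions_meta = []
    for rec in study.sessions:
        sid = rec.session_id
        put(f"design_{sid}.tsv", rec.schedule.design(run=None).matrix,
            columns=list(rec.schedule.labels))
        put(f"betas_cortex_{sid}.tsv", rec.X_betas)
        put(f"betas_cerebellum_{sid}.tsv", rec.Y_betas)
        R, K, Q = rec.X_run_betas.shape
        put(f"betas_cortex_runs_{sid}.tsv", rec.X_run_betas.reshape(R * K, Q))
        put(
            f"betas_cerebellum_runs_{sid}.tsv",
            rec.Y_run_betas.reshape(R * K, -1),
        )
        put(
            f"residual_sd_{sid}.tsv",
            np.concatenate([rec.residual_sd_cortex, rec.residual_sd_cerebellum]),
        )
        sessions_meta.append(
            {
                "session_id": sid,
                "schedule": _schedule_to_json(rec.schedule),
                "n_parcels": Q,
                "n_voxels": rec.Y_betas.shape[1],
            }
        )
    t = study.truth
    (root / "truth.json").write_text(
        json.dumps(
            {
                "scenario": t.scenario,
                "noise_variance": t.noise_variance,
                "weight_variance": t.weight_variance,
                "seed": t.seed,
                "W_true_file": "W_true.tsv",
            },
            indent=2,
        )
    )
    put("W_true.tsv", t.W_true)
    manifest = {
        "format_version": FORMAT_VERSION,
        "task_set": study.task_set,
        "sessions": sessions_meta,
        "n_parcels": p.Q,
        "n_voxels": t.P,
        "params": study.params,
        "tables": tables,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return root


def read_bundle(path, verify: bool = True) -> SimulatedStudy:
    """Load a bundle, checking shapes and content hashes against the manifest."""
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {root}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format_version", 0) > FORMAT_VERSION:
        warnings.warn(
            "bundle was written by a newer format version; loading best-effort",
            stacklevel=2,
        )
    if verify:
        for name, info in manifest["tables"].items():
            fp = root / name
            if not fp.exists():
                raise CorruptBundleError(
                    f"missing table {name!r} (produced by the simulate/fit stage)"
                )
            if _sha256(fp) != info["sha256"]:
                raise CorruptBundleError(f"content hash mismatch for {name!r}")
    parcel_df = pd.read_csv(
        root / "parcels.tsv", sep="\t", float_precision="round_trip"
    )
    parcels = ParcelSet(
        parcel_ids=parcel_df["parcel_id"].to_numpy(),
        hemisphere=parcel_df["hemisphere"].to_numpy(),
        centers=parcel_df[["x", "y", "z"]].to_numpy(),
    )
    truth_meta = json.loads((root / "truth.json").read_text())
    truth = GroundTruth(
        W_true=read_table(root / "W_true.tsv"),
        scenario=truth_meta["scenario"],
        noise_variance=truth_meta["noise_variance"],
        weight_variance=truth_meta["weight_variance"],
        seed=truth_meta["seed"],
    )
    region_map = None
    if (root / "regions.tsv").exists():
        rdf = pd.read_csv(root / "regions.tsv", sep="\t")
        names_file = root / "region_names.json"
        names = (
            tuple(json.loads(names_file.read_text()))
            if names_file.exists()
            else tuple(
                f"region{r}" for r in sorted(rdf["region"].unique())
            )
        )
        region_map = RegionMap(
            voxel_regions=rdf["region"].to_numpy(), region_names=names
        )
    sessions = []
    for meta in manifest["sessions"]:
        sid = meta["session_id"]
        schedule = _schedule_from_json(meta["schedule"])

        def load(name, expected_shape=None):
            arr = read_table(root / name)
            info = manifest["tables"][name]
            if list(arr.shape) != info["shape"]:
                raise CorruptBundleError(
                    f"table {name!r} has shape {list(arr.shape)}, "
                    f"manifest says {info['shape']}"
                )
            return arr

        Xb = load(f"betas_cortex_{sid}.tsv")
        Yb = load(f"betas_cerebellum_{sid}.tsv")
        sd = load(f"residual_sd_{sid}.tsv").ravel()
        Q, P = Xb.shape[1], Yb.shape[1]
        R = schedule.run_count
        Xr = load(f"betas_cortex_runs_{sid}.tsv").reshape(R, -1, Q)
        Yr = load(f"betas_cerebellum_runs_{sid}.tsv").reshape(R, -1, P)
        sessions.append(
            SessionRecording(
                session_id=sid,
                schedule=schedule,
                X_betas=Xb,
                Y_betas=Yb,
                X_run_betas=Xr,
                Y_run_betas=Yr,
                residual_sd_cortex=sd[:Q],
                residual_sd_cerebellum=sd[Q:],
            )
        )
    return SimulatedStudy(
        task_set=manifest["task_set"],
        sessions=sessions,
        parcels=parcels,
        truth=truth,
        region_map=region_map,
        params=manifest.get("params", {}),
    )
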