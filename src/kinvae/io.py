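"""Text-based serialization: trajectory CSV, feature CSV, model bundles, reports.

All artifacts are plain text. Model bundles are JSON with weight arrays as
nested lists (Python's JSON float repr round-trips float64 exactly).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import NetworkConfig
from .exceptions import SchemaError
from .features import FEATURE_NAMES, META_COLUMNS, FeatureDataset
from .model import TrainedModel
from .trajectory import Trajectory

TRAJ_COLUMNS = ["participant_id", "group", "task_id", "difficulty",
                "trajectory_index", "t", "x", "y"]


# ------------------------------------------------------------- trajectories

def write_trajectories_csv(frame_or_cohort, path: str | Path) -> None:
    from .cohort import CohortData, cohort_to_frame

    frame = (cohort_to_frame(frame_or_cohort)
             if isinstance(frame_or_cohort, CohortData) else frame_or_cohort)
    missing = [c for c in TRAJ_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trajectory frame missing column(s): {missing}")
    frame.to_csv(path, index=False)


def read_trajectories_csv(path: str | Path):
    """Read a trajectory CSV back into a CohortData (correctness flags all True)."""
    from .cohort import CohortData

    frame = pd.read_csv(path)
    missing = [c for c in TRAJ_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trajectory file {path} missing column(s): {missing}")
    for col in ("t", "x", "y"):
        if not np.issubdtype(frame[col].dtype, np.number):
            raise SchemaError(f"non-numeric values in column {col!r} of {path}")
    trajectories, labels = [], {}
    keys = ["participant_id", "task_id", "trajectory_index"]
    for (pid, task, idx), g in frame.groupby(keys, sort=True):
        g = g.sort_values("t")
        steps = np.diff(g["t"].to_numpy())
        if steps.size and (np.any(steps <= 0)
                           or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9)):
            raise SchemaError(
                f"nonuniform time steps for {pid}/task{task}/#{idx} in {path}"
            )
        trajectories.append(Trajectory(
            participant_id=str(pid), task_id=int(task), trajectory_index=int(idx),
            t=g["t"].to_numpy(), x=g["x"].to_numpy(), y=g["y"].to_numpy(),
        ))
        labels[str(pid)] = int(g["group"].iloc[0])
    task_correct = {(tr.participant_id, tr.task_id): True for tr in trajectories}
    return CohortData(trajectories, labels, task_correct)


# ----------------------------------------------------------------- features

def write_features_csv(dataset: FeatureDataset, path: str | Path) -> None:
    dataset.frame.to_csv(path, index=False)


def read_features_csv(path: str | Path) -> FeatureDataset:
    frame = pd.read_csv(path)
    missing = [c for c in META_COLUMNS + FEATURE_NAMES if c not in frame.columns]
    if missing:
        raise SchemaError(f"feature file {path} missing column(s): {missing}")
    for col in FEATURE_NAMES:
        if not np.issubdtype(frame[col].dtype, np.number):
            raise SchemaError(f"non-numeric values in feature column {col!r} of {path}")
    dup = frame.duplicated(subset=["participant_id", "task_id"])
    if dup.any():
        first = frame.loc[dup, ["participant_id", "task_id"]].iloc[0]
        raise SchemaError(
            f"duplicate (participant, task) key "
            f"({first['participant_id']}, {first['task_id']}) in {path}"
        )
    return FeatureDataset(frame)


# ------------------------------------------------------------- model bundle

def save_model_bundle(model: TrainedModel, path: str | Path) -> None:
    bundle = {
        "format": "kinvae-model-bundle-v1",
        "config": {**model.config.__dict__,
                   "encoder_hidden": list(model.config.encoder_hidden)},
        "feature_names": model.feature_names,
        "stats": {
            "mean": model.stats["mean"].tolist(),
            "sd": model.stats["sd"].tolist(),
            "index": list(model.stats.index),
        },
        "params": {k: v.tolist() for k, v in model.params.items()},
        "history": model.history.to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(bundle))


def load_model_bundle(path: str | Path) -> TrainedModel:
    try:
        bundle = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed model bundle {path}: {exc}") from exc
    if bundle.get("format") != "kinvae-model-bundle-v1":
        raise SchemaError(f"{path} is not a kinvae model bundle")
    cfg = dict(bundle["config"])
    cfg["encoder_hidden"] = tuple(cfg["encoder_hidden"])
    config = NetworkConfig(**cfg).validate()
    stats = pd.DataFrame(
        {"mean": bundle["stats"]["mean"], "sd": bundle["stats"]["sd"]},
        index=bundle["stats"]["index"],
    )
    params = {k: np.asarray(v, dtype=float) for k, v in bundle["params"].items()}
    history = pd.DataFrame(bundle["history"])
    return TrainedModel(params=params, config=config, stats=stats,
                        history=history, feature_names=bundle["feature_names"])


def write_json(obj, path: str | Path) -> None:
    def default(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        raise TypeError(f"not JSON-serializable: {type(x)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
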