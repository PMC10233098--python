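"""Kinematic feature extraction: trajectories -> per-task 12-feature dataset.

The 12 features summarize each drag trajectory's speed profile, acceleration
profile, path geometry (straightness, directional change) and length; they
are averaged over a task's trajectories into one row per (participant, task).

Conventions
-----------
* Speeds are forward differences of position over the fixed sampling step
  (no smoothing).
* Acceleration is the signed derivative of scalar speed, so deceleration is
  negative and "MinAcceleration" is informative.
* "Max/Min peaks" are the mean of interior local extrema of the series,
  falling back to the global extremum when the series is monotone
  (``peaks="global"`` switches to plain global extrema).
* Directional change (DC) is the absolute turning angle between successive
  displacement vectors per unit time, in rad/s; zero-length displacements
  are skipped.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateTrajectoryError,
    SchemaError,
    ZeroVarianceFeatureError,
)
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

#: Canonical feature order; column names used verbatim in CSV files.
FEATURE_NAMES: list[str] = [
    "MeanSpeed",
    "MaxSpeed",
    "MinSpeed",
    "sdSpeed",
    "MeanAcceleration",
    "MaxAcceleration",
    "MinAcceleration",
    "sdAcceleration",
    "STH",
    "DC",
    "sdDC",
    "MeanLength",
]

META_COLUMNS = ["participant_id", "group", "task_id", "difficulty"]


# ---------------------------------------------------------------- series ops

def speed_series(trajectory: Trajectory) -> np.ndarray:
    """Instantaneous speeds: Euclidean step length / dt, length n-1."""
    if trajectory.n_samples < 2:
        raise DegenerateTrajectoryError("speed series needs >= 2 samples")
    steps = np.diff(trajectory.positions, axis=0)
    return np.linalg.norm(steps, axis=1) / trajectory.dt


def acceleration_series(speeds: np.ndarray, dt: float) -> np.ndarray:
    """Signed scalar acceleration: forward difference of speed / dt."""
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size < 2:
        raise DegenerateTrajectoryError("acceleration series needs >= 2 speeds")
    return np.diff(speeds) / dt


def directional_change_series(trajectory: Trajectory) -> np.ndarray:
    """Absolute turning angle between successive displacements per unit time.

    Angles are in [0, pi] radians; division by dt gives rad/s. Zero-length
    displacements carry no direction and are skipped.
    """
    if trajectory.n_samples < 3:
        raise DegenerateTrajectoryError("directional change needs >= 3 samples")
    steps = np.diff(trajectory.positions, axis=0)
    lengths = np.linalg.norm(steps, axis=1)
    nz = steps[lengths > 0]
    if nz.shape[0] < 2:
        raise DegenerateTrajectoryError("all displacements are zero-length")
    a, b = nz[:-1], nz[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.sum(a * b, axis=1)
    return np.arctan2(np.abs(cross), dot) / trajectory.dt  # exact 0 when collinear


def path_length(trajectory: Trajectory) -> float:
    steps = np.diff(trajectory.positions, axis=0)
    return float(np.linalg.norm(steps, axis=1).sum())


def straightness(trajectory: Trajectory) -> float:
    """Chord length / path length, in [0, 1]; 1 for a perfectly straight drag."""
    length = path_length(trajectory)
    if length <= 0:
        raise DegenerateTrajectoryError("zero path length")
    chord = float(np.linalg.norm(trajectory.positions[-1] - trajectory.positions[0]))
    return min(chord / length, 1.0)


def _local_maxima(series: np.ndarray) -> np.ndarray:
    s = np.asarray(series, dtype=float)
    interior = (s[1:-1] > s[:-2]) & (s[1:-1] > s[2:])
    return s[1:-1][interior]


def _local_minima(series: np.ndarray) -> np.ndarray:
    return -_local_maxima(-np.asarray(series, dtype=float))


def _peak_stat(series: np.ndarray, kind: str, peaks: str) -> float:
    """Mean of interior local extrema, global extremum as fallback."""
    series = np.asarray(series, dtype=float)
    if peaks == "global":
        return float(series.max() if kind == "max" else series.min())
    ext = _local_maxima(series) if kind == "max" else _local_minima(series)
    if ext.size == 0:
        return float(series.max() if kind == "max" else series.min())
    return float(ext.mean())


def trajectory_features(trajectory: Trajectory, peaks: str = "local") -> dict[str, float]:
    """The 12 kinematic features of a single trajectory.

    ``peaks`` selects the reading of the Max/Min speed and acceleration
    statistics: "local" (default) averages interior local extrema with a
    global fallback; "global" uses the global max/min.
    """
    if peaks not in ("local", "global"):
        raise ValueError("peaks must be 'local' or 'global'")
    v = speed_series(trajectory)
    a = acceleration_series(v, trajectory.dt)
    dc = directional_change_series(trajectory)
    sd = lambda arr: float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return {
        "MeanSpeed": float(v.mean()),
        "MaxSpeed": _peak_stat(v, "max", peaks),
        "MinSpeed": _peak_stat(v, "min", peaks),
        "sdSpeed": sd(v),
        "MeanAcceleration": float(a.mean()),
        "MaxAcceleration": _peak_stat(a, "max", peaks),
        "MinAcceleration": _peak_stat(a, "min", peaks),
        "sdAcceleration": sd(a),
        "STH": straightness(trajectory),
        "DC": float(dc.mean()),
        "sdDC": sd(dc),
        "MeanLength": path_length(trajectory),
    }


# ------------------------------------------------------------ FeatureDataset

@dataclass
class FeatureDataset:
    """Per-task feature matrix with metadata and optional z-scoring stats.

    ``frame`` holds one row per retained (participant, task) with columns
    ``participant_id, group, task_id, difficulty`` followed by the 12
    features. ``stats`` (per-feature mean/SD) is set once the columns have
    been standardized and is reused, unchanged, on held-out data.
    """

    frame: pd.DataFrame
    stats: pd.DataFrame | None = None
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        missing = [c for c in META_COLUMNS + FEATURE_NAMES if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"feature frame missing column(s): {missing}")
        if self.frame[FEATURE_NAMES].isna().any().any():
            raise SchemaError("feature frame contains missing values")

    # -- convenience accessors
    @property
    def X(self) -> np.ndarray:
        return self.frame[FEATURE_NAMES].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["group"].to_numpy(dtype=int)

    @property
    def participants(self) -> np.ndarray:
        return self.frame["participant_id"].to_numpy()

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def subset(self, index) -> "FeatureDataset":
        return FeatureDataset(
            self.frame.iloc[index].reset_index(drop=True), stats=self.stats
        )

    def copy(self) -> "FeatureDataset":
        return FeatureDataset(self.frame.copy(), stats=None if self.stats is None else self.stats.copy())

    def standardize(self, stats: pd.DataFrame | None = None) -> "FeatureDataset":
        """Z-score the feature columns.

        With ``stats=None`` the column means/SDs are computed from this
        dataset; passing training-fold stats applies them unchanged (no
        leakage onto held-out folds). The stats used are stored on the
        returned dataset.
        """
        if stats is None:
            mean = self.frame[FEATURE_NAMES].mean()
            sd = self.frame[FEATURE_NAMES].std(ddof=1)
            zero = sd[sd <= 0]
            if len(zero):
                raise ZeroVarianceFeatureError(zero.index[0])
            stats = pd.DataFrame({"mean": mean, "sd": sd})
        else:
            missing = [f for f in FEATURE_NAMES if f not in stats.index]
            if missing:
                raise SchemaError(f"standardization stats missing feature(s): {missing}")
            if (stats.loc[FEATURE_NAMES, "sd"] <= 0).any():
                raise ZeroVarianceFeatureError(
                    stats.loc[FEATURE_NAMES][stats.loc[FEATURE_NAMES, "sd"] <= 0].index[0]
                )
        out = self.frame.copy()
        out[FEATURE_NAMES] = (
            out[FEATURE_NAMES] - stats.loc[FEATURE_NAMES, "mean"]
        ) / stats.loc[FEATURE_NAMES, "sd"]
        return FeatureDataset(out, stats=stats.loc[FEATURE_NAMES].copy())


def build_dataset(cohort, peaks: str = "local") -> FeatureDataset:
    """Aggregate a cohort's trajectories into the per-task feature dataset.

    Tasks flagged not-correctly-performed are dropped before extraction;
    degenerate trajectories are excluded with a warning; the surviving
    trajectories' features are arithmetically averaged into one row per
    (participant, task). The number of trajectories per task is recorded in
    the companion ``extra`` frame (``nTrajectories``) but is not a model
    feature.
    """
    if not cohort.trajectories:
        raise SchemaError("cohort has no trajectories")
    records: dict[tuple, list[dict]] = {}
    for traj in cohort.trajectories:
        key = (traj.participant_id, traj.task_id)
        if not cohort.task_correct.get(key, True):
            continue
        try:
            feats = trajectory_features(traj, peaks=peaks)
        except DegenerateTrajectoryError as exc:
            logger.warning(
                "excluding degenerate trajectory %s/task%s/#%s: %s",
                traj.participant_id, traj.task_id, traj.trajectory_index, exc,
            )
            continue
        records.setdefault(key, []).append(feats)

    rows, extra_rows = [], []
    participants_seen = sorted({t.participant_id for t in cohort.trajectories})
    retained_participants = {pid for (pid, _task) in records}
    for pid in participants_seen:
        if pid not in retained_participants:
            logger.warning("participant %s has no retained tasks; dropped", pid)
    for (pid, task), feats_list in sorted(records.items()):
        mean_feats = {
            name: float(np.mean([f[name] for f in feats_list])) for name in FEATURE_NAMES
        }
        rows.append(
            {
                "participant_id": pid,
                "group": cohort.labels[pid],
                "task_id": task,
                "difficulty": task // 5 + 1,
                **mean_feats,
            }
        )
        extra_rows.append(
            {"participant_id": pid, "task_id": task, "nTrajectories": len(feats_list)}
        )
    frame = pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_NAMES)
    return FeatureDataset(frame, extra=pd.DataFrame(extra_rows))
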