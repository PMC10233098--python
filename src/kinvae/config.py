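"""Configuration objects for cohort simulation, network training and pipeline runs.

All configs are plain dataclasses with an explicit ``validate()`` that raises
:class:`~kinvae.exceptions.InvalidConfigError`, and YAML/JSON round-trip
helpers so a run can be re-executed from its serialized snapshot.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .exceptions import InvalidConfigError
from .features import FEATURE_NAMES

#: Default standardized between-group mean differences (ASD-like minus
#: TD-like, in pooled-SD units). Signs follow the discriminative pattern of
#: the study population: more variable speed/acceleration and harder
#: decelerations, but lower peak speed, in the ASD-like group.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "sdSpeed": 1.5,
    "MaxAcceleration": 1.5,
    "sdAcceleration": 1.5,
    "MaxSpeed": -1.5,
    "MinAcceleration": -1.5,
}

#: Tablet canvas, abstract screen units, origin bottom-left.
CANVAS_WIDTH = 1280.0
CANVAS_HEIGHT = 800.0


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic two-group drag-task cohort.

    Defaults reproduce the study design: 30 participants per group, 25 tasks
    per participant organized as 5 difficulty levels x 5 tasks, 5 drag
    trajectories per task, finger position sampled at 40 Hz.
    """

    n_per_group: int = 30
    n_tasks: int = 25
    n_traj_per_task: int = 5
    sample_rate: float = 40.0
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    noise_scale: float = 1.0
    incorrect_task_rate: float = 0.0
    #: When set, class-conditional variation in the sampled feature table is
    #: confined to this many latent directions (low-rank covariance plus
    #: small isotropic noise). ``None`` = full-rank independent features.
    latent_rank: int | None = None
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if self.n_per_group < 1:
            raise InvalidConfigError("n_per_group must be >= 1")
        if self.n_tasks < 1 or self.n_tasks % 5 != 0:
            raise InvalidConfigError("n_tasks must be a positive multiple of 5")
        if self.n_traj_per_task < 1:
            raise InvalidConfigError("n_traj_per_task must be >= 1")
        if self.sample_rate <= 0:
            raise InvalidConfigError("sample_rate must be > 0")
        if not 0.0 <= self.incorrect_task_rate <= 1.0:
            raise InvalidConfigError("incorrect_task_rate must be in [0, 1]")
        if self.noise_scale <= 0:
            raise InvalidConfigError("noise_scale must be > 0")
        unknown = set(self.effect_sizes) - set(FEATURE_NAMES)
        if unknown:
            raise InvalidConfigError(f"unknown feature(s) in effect_sizes: {sorted(unknown)}")
        if self.latent_rank is not None and not 1 <= self.latent_rank <= len(FEATURE_NAMES):
            raise InvalidConfigError("latent_rank must be in [1, 12]")
        return self

    @property
    def n_difficulty_levels(self) -> int:
        return 5

    def effect_vector(self) -> "list[float]":
        return [float(self.effect_sizes.get(name, 0.0)) for name in FEATURE_NAMES]


@dataclass
class NetworkConfig:
    """Architecture and optimization settings of the VAE with predictor head.

    The encoder maps the 12 standardized features through tanh hidden layers
    to a latent mean and log-variance; the decoder mirrors the encoder with a
    linear output; the predictor maps latent variables through one tanh layer
    (``predictor_hidden`` units) to a 2-unit softmax.
    """

    latent_dim: int = 2
    encoder_hidden: tuple[int, ...] = (32,)
    predictor_hidden: int = 16
    activation: str = "tanh"
    #: "softmax" = two-unit softmax head (default); "sigmoid" = single
    #: sigmoid unit. Both are trained with binary cross-entropy.
    predictor_head: str = "softmax"
    epochs: int = 500
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0

    def validate(self) -> "NetworkConfig":
        if self.latent_dim < 1:
            raise InvalidConfigError("latent_dim must be >= 1")
        if any(h < 1 for h in self.encoder_hidden) or not self.encoder_hidden:
            raise InvalidConfigError("encoder_hidden sizes must all be >= 1")
        if self.predictor_hidden < 1:
            raise InvalidConfigError("predictor_hidden must be >= 1")
        if self.activation not in ("tanh", "relu"):
            raise InvalidConfigError("activation must be 'tanh' or 'relu'")
        if self.predictor_head not in ("softmax", "sigmoid"):
            raise InvalidConfigError("predictor_head must be 'softmax' or 'sigmoid'")
        if self.epochs < 1 or self.batch_size < 1:
            raise InvalidConfigError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise InvalidConfigError("learning_rate must be > 0")
        if self.optimizer not in ("adam", "sgd"):
            raise InvalidConfigError("optimizer must be 'adam' or 'sgd'")
        return self


@dataclass
class RunConfig:
    """End-to-end pipeline settings: simulate -> extract -> CV -> latent analysis."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    #: "trajectories" simulates raw paths and runs the extractor;
    #: "features" samples the feature table directly.
    data_mode: str = "trajectories"
    k_folds: int = 10
    selection_latent_dim: int = 10
    pca_threshold: float = 0.95
    perturb_n: int = 100
    perturb_scope: str = "dataset"
    curve_points: int = 50
    curve_span: float = 3.0
    make_plots: bool = True
    outdir: str = "kinvae_run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        self.cohort.validate()
        self.network.validate()
        if self.data_mode not in ("trajectories", "features"):
            raise InvalidConfigError("data_mode must be 'trajectories' or 'features'")
        if self.k_folds < 2:
            raise InvalidConfigError("k_folds must be >= 2")
        if not 0 < self.pca_threshold <= 1:
            raise InvalidConfigError("pca_threshold must be in (0, 1]")
        if self.perturb_n < 1 or self.curve_points < 1:
            raise InvalidConfigError("perturb_n and curve_points must be >= 1")
        if self.perturb_scope not in ("dataset", "group", "participant"):
            raise InvalidConfigError("perturb_scope must be dataset|group|participant")
        return self


def _to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def conv(x):
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, tuple):
            return list(x)
        return x

    return conv(d)


def config_to_yaml(cfg, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def config_to_json(cfg) -> str:
    return json.dumps(_to_dict(cfg), indent=2)


def _build(cls, data: Mapping):
    kwargs = dict(data)
    if cls is RunConfig:
        kwargs["cohort"] = CohortConfig(**kwargs.get("cohort", {}))
        kwargs["network"] = _network_from_dict(kwargs.get("network", {}))
    elif cls is NetworkConfig:
        return _network_from_dict(kwargs)
    return cls(**kwargs).validate()


def _network_from_dict(data: Mapping) -> NetworkConfig:
    kwargs = dict(data)
    if "encoder_hidden" in kwargs:
        kwargs["encoder_hidden"] = tuple(kwargs["encoder_hidden"])
    return NetworkConfig(**kwargs).validate()


def load_config(path: str | Path, kind: str = "run"):
    """Load a YAML/JSON config file. ``kind`` is 'run', 'cohort' or 'network'."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    cls = {"run": RunConfig, "cohort": CohortConfig, "network": NetworkConfig}[kind]
    return _build(cls, data)
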