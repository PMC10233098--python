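"""Latent-space analysis of a trained supervised VAE.

Everything downstream of training: projecting tasks and participants to the
latent space (encoder means, no sampling noise), PCA-based latent-dimension
selection, per-class diagonal-Gaussian fitting, density-ratio class
assignment, Monte-Carlo single-feature perturbation, per-feature
assignment-probability response curves, perturbation density maps, and
orthogonal-Procrustes alignment for cross-seed consistency checks.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.special import logsumexp
from sklearn.decomposition import PCA

from .exceptions import (
    FeatureNameError,
    FitError,
    InvalidConfigError,
    PairingError,
    ShapeError,
)
from .features import FEATURE_NAMES, FeatureDataset
from .model import TrainedModel, VAEClassifierResults
from . import nn

VARIANCE_FLOOR = 1e-6


def _unpack(model) -> TrainedModel:
    return model.trained if isinstance(model, VAEClassifierResults) else model


# ------------------------------------------------------------- projection

@dataclass
class LatentProjection:
    """Task- and participant-level latent positions (encoder means)."""

    task_points: pd.DataFrame      # participant_id, task_id, group, z0..z{d-1}
    participant_points: pd.DataFrame  # participant_id, group, z0..z{d-1}

    @property
    def latent_dim(self) -> int:
        return sum(c.startswith("z") for c in self.task_points.columns)

    def task_array(self) -> np.ndarray:
        cols = [f"z{i}" for i in range(self.latent_dim)]
        return self.task_points[cols].to_numpy()

    def participant_array(self) -> np.ndarray:
        cols = [f"z{i}" for i in range(self.latent_dim)]
        return self.participant_points[cols].to_numpy()


def project_latent(model, dataset: FeatureDataset) -> LatentProjection:
    """Encoder-mean latent positions per task row, and their per-participant
    means (the mean being the standard representation of a participant)."""
    trained = _unpack(model)
    ds = dataset if dataset.stats is not None else dataset.standardize(trained.stats)
    enc = nn.encode(trained.params, ds.X, trained.config)
    mu = np.atleast_2d(enc.mu)
    d = mu.shape[1]
    zcols = [f"z{i}" for i in range(d)]
    task_points = ds.frame[["participant_id", "group", "task_id"]].copy()
    task_points[zcols] = mu
    participant_points = (
        task_points.groupby("participant_id", sort=True)
        .agg({"group": "first", **{c: "mean" for c in zcols}})
        .reset_index()
    )
    return LatentProjection(task_points=task_points, participant_points=participant_points)


# ------------------------------------------------------------------- PCA

@dataclass
class PCAResult:
    explained_variance_ratios: np.ndarray  # descending, sums to 1
    components: np.ndarray                 # loadings, rows = components

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratios)

    def n_components_for(self, threshold: float = 0.95) -> int:
        """Smallest m whose cumulative explained-variance ratio >= threshold."""
        return int(np.searchsorted(self.cumulative(), threshold - 1e-12) + 1)


def pca_explained_variance(points: np.ndarray) -> PCAResult:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise FitError("PCA needs at least 2 points in a 2-D array")
    pca = PCA()
    pca.fit(points)
    return PCAResult(
        explained_variance_ratios=pca.explained_variance_ratio_,
        components=pca.components_,
    )


# ------------------------------------------------------- class Gaussians

@dataclass
class ClassGaussian:
    """Diagonal multivariate normal fitted to one group's latent points."""

    label: int
    mean: np.ndarray
    variances: np.ndarray  # per-dimension, floored at VARIANCE_FLOOR

    @property
    def dim(self) -> int:
        return self.mean.size

    def logpdf(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[1] != self.dim:
            raise ShapeError(f"expected dimension {self.dim}, got {points.shape[1]}")
        diff = points - self.mean
        return -0.5 * (
            np.sum(diff**2 / self.variances, axis=1)
            + np.sum(np.log(2.0 * np.pi * self.variances))
        )


def fit_class_gaussian(points: np.ndarray, label: int = 0) -> ClassGaussian:
    """Maximum-likelihood diagonal Gaussian (divide-by-n variances, floored)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        raise FitError("need at least 2 points to fit a class Gaussian")
    return ClassGaussian(
        label=label,
        mean=points.mean(axis=0),
        variances=np.maximum(points.var(axis=0, ddof=0), VARIANCE_FLOOR),
    )


def fit_class_gaussians(projection: LatentProjection,
                        level: str = "task") -> tuple[ClassGaussian, ClassGaussian]:
    """Fit the TD (label 0) and ASD (label 1) Gaussians to latent points.

    ``level`` chooses between task-level points (default; the distributions
    the latent regularization acts on) and participant means.
    """
    frame = projection.task_points if level == "task" else projection.participant_points
    zcols = [f"z{i}" for i in range(projection.latent_dim)]
    out = []
    for label in (0, 1):
        pts = frame.loc[frame["group"] == label, zcols].to_numpy()
        out.append(fit_class_gaussian(pts, label=label))
    return out[0], out[1]


def assignment_posterior(point: np.ndarray, g_td: ClassGaussian,
                         g_asd: ClassGaussian) -> tuple[float, float]:
    """Equal-prior posterior (p_TD, p_ASD) from the two class densities,
    computed in log space."""
    p = np.atleast_2d(np.asarray(point, dtype=float))
    logd = np.column_stack([g_td.logpdf(p), g_asd.logpdf(p)])
    post = np.exp(logd - logsumexp(logd, axis=1, keepdims=True))
    return (float(post[0, 0]), float(post[0, 1])) if p.shape[0] == 1 else post


def assignment_posteriors(points: np.ndarray, g_td: ClassGaussian,
                          g_asd: ClassGaussian) -> np.ndarray:
    logd = np.column_stack([g_td.logpdf(points), g_asd.logpdf(points)])
    return np.exp(logd - logsumexp(logd, axis=1, keepdims=True))


# ----------------------------------------------------------- perturbation

@dataclass
class PerturbationTrace:
    """Latent positions of one participant under n resamplings of one feature."""

    participant_id: str
    feature_name: str
    sampled_values: np.ndarray          # (n,)
    latent_positions: np.ndarray        # (n, d) participant-mean encoder mus
    posterior_per_sample: np.ndarray    # (n, 2) = (p_TD, p_ASD)
    origin: np.ndarray                  # unperturbed participant latent mean

    @property
    def n(self) -> int:
        return self.sampled_values.size

    def mean_displacement(self) -> float:
        """Mean Euclidean distance of the perturbed positions from the origin."""
        return float(np.linalg.norm(self.latent_positions - self.origin, axis=1).mean())


def _feature_moments(dataset: FeatureDataset, feature_name: str,
                     participant_id: str, scope: str) -> tuple[float, float]:
    frame = dataset.frame
    if scope == "dataset":
        col = frame[feature_name]
    elif scope == "group":
        g = int(frame.loc[frame["participant_id"] == participant_id, "group"].iloc[0])
        col = frame.loc[frame["group"] == g, feature_name]
    elif scope == "participant":
        col = frame.loc[frame["participant_id"] == participant_id, feature_name]
    else:
        raise InvalidConfigError("stats_scope must be dataset|group|participant")
    return float(col.mean()), float(col.std(ddof=1))


def perturb_feature(model, dataset: FeatureDataset, participant_id: str,
                    feature_name: str, n: int = 100, stats_scope: str = "dataset",
                    seed: int | np.random.Generator | None = None,
                    gaussians: tuple[ClassGaussian, ClassGaussian] | None = None,
                    ) -> PerturbationTrace:
    """Monte-Carlo resampling of one feature of one participant.

    Draws ``n`` values of the feature from a normal with the empirical mean
    and SD of the chosen scope (whole dataset by default), overwrites the
    feature in all the participant's task rows, re-standardizes with the
    model's stats, encodes, and records the participant's mean latent
    position with its class-assignment posterior. ``dataset`` must hold raw
    (unstandardized) feature values.
    """
    trained = _unpack(model)
    if feature_name not in FEATURE_NAMES:
        raise FeatureNameError(feature_name)
    frame = dataset.frame
    mask = frame["participant_id"] == participant_id
    if not mask.any():
        raise KeyError(f"unknown participant {participant_id!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mu_f, sd_f = _feature_moments(dataset, feature_name, participant_id, stats_scope)
    if sd_f < 1e-12:
        import logging
        logging.getLogger(__name__).warning(
            "feature %s has ~zero SD in scope %s; perturbation draws are constant",
            feature_name, stats_scope,
        )
        draws = np.full(n, mu_f)
    else:
        draws = rng.normal(mu_f, sd_f, size=n)

    if gaussians is None:
        projection = project_latent(trained, dataset)
        gaussians = fit_class_gaussians(projection)
    g_td, g_asd = gaussians

    rows = frame.loc[mask].copy()
    origin = _encode_participant_mean(trained, rows, dataset)
    positions = np.empty((n, trained.config.latent_dim))
    for i, v in enumerate(draws):
        rows[feature_name] = v
        positions[i] = _encode_participant_mean(trained, rows, dataset)
    posteriors = assignment_posteriors(positions, g_td, g_asd)
    return PerturbationTrace(
        participant_id=participant_id, feature_name=feature_name,
        sampled_values=draws, latent_positions=positions,
        posterior_per_sample=posteriors, origin=origin,
    )


def _encode_participant_mean(trained: TrainedModel, rows: pd.DataFrame,
                             dataset: FeatureDataset) -> np.ndarray:
    X = rows[FEATURE_NAMES].to_numpy(dtype=float)
    Xz = (X - trained.stats["mean"].to_numpy()) / trained.stats["sd"].to_numpy()
    enc = nn.encode(trained.params, Xz, trained.config)
    return np.atleast_2d(enc.mu).mean(axis=0)


def perturbation_displacements(model, dataset: FeatureDataset, n: int = 100,
                               stats_scope: str = "dataset", seed: int = 0,
                               features: list[str] | None = None,
                               participants: list[str] | None = None,
                               ) -> pd.DataFrame:
    """Mean latent displacement per (participant, feature) under perturbation."""
    trained = _unpack(model)
    projection = project_latent(trained, dataset)
    gaussians = fit_class_gaussians(projection)
    features = features or FEATURE_NAMES
    participants = participants or sorted(dataset.frame["participant_id"].unique())
    rng = np.random.default_rng(seed)
    rows = []
    for pid in participants:
        for feat in features:
            trace = perturb_feature(trained, dataset, pid, feat, n=n,
                                    stats_scope=stats_scope, seed=rng,
                                    gaussians=gaussians)
            rows.append((pid, feat, trace.mean_displacement()))
    return pd.DataFrame(rows, columns=["participant_id", "feature", "displacement"])


# -------------------------------------------------------- response curves

@dataclass
class FeatureResponseCurve:
    """Mean class-assignment probability as a function of one feature's value."""

    feature_name: str
    grid: np.ndarray
    p_td: np.ndarray
    p_asd: np.ndarray
    sd_td: np.ndarray
    sd_asd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_name,
                "value": self.grid,
                "p_TD_mean": self.p_td,
                "p_TD_sd": self.sd_td,
                "p_ASD_mean": self.p_asd,
                "p_ASD_sd": self.sd_asd,
            }
        )


def feature_response_curve(model, dataset: FeatureDataset, g_td: ClassGaussian,
                           g_asd: ClassGaussian, feature_name: str,
                           grid: np.ndarray | None = None, n_points: int = 50,
                           span: float = 3.0) -> FeatureResponseCurve:
    """Sweep one feature over a grid (default: its mean +/- span*SD), set it
    in every participant's rows, and average each participant's assignment
    posterior at the grid value; the spread across participants gives the
    per-point SD."""
    trained = _unpack(model)
    if feature_name not in FEATURE_NAMES:
        raise FeatureNameError(feature_name)
    if grid is None:
        mu_f, sd_f = _feature_moments(dataset, feature_name, "", "dataset")
        grid = np.linspace(mu_f - span * sd_f, mu_f + span * sd_f, n_points)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidConfigError("empty response-curve grid")

    participants = sorted(dataset.frame["participant_id"].unique())
    post = np.empty((grid.size, len(participants), 2))
    frames = {pid: dataset.frame.loc[dataset.frame["participant_id"] == pid].copy()
              for pid in participants}
    for gi, v in enumerate(grid):
        pts = np.empty((len(participants), trained.config.latent_dim))
        for pi, pid in enumerate(participants):
            rows = frames[pid]
            rows[feature_name] = v
            pts[pi] = _encode_participant_mean(trained, rows, dataset)
        post[gi] = assignment_posteriors(pts, g_td, g_asd)
    return FeatureResponseCurve(
        feature_name=feature_name, grid=grid,
        p_td=post[:, :, 0].mean(axis=1), p_asd=post[:, :, 1].mean(axis=1),
        sd_td=post[:, :, 0].std(axis=1, ddof=1), sd_asd=post[:, :, 1].std(axis=1, ddof=1),
    )


# ------------------------------------------------------------ density map

def feature_density_map(traces: list[PerturbationTrace], bins: int = 40,
                        extent: tuple[float, float, float, float] | None = None):
    """2-D histogram density of perturbed latent positions (latent dim 2).

    Returns (density, x_edges, y_edges); density integrates to 1 over the
    grid (sum * cell area = 1).
    """
    pts = np.vstack([t.latent_positions for t in traces])
    if pts.shape[1] != 2:
        raise ShapeError("density maps require a 2-D latent space")
    rng_arg = None
    if extent is not None:
        rng_arg = [[extent[0], extent[1]], [extent[2], extent[3]]]
    H, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins, range=rng_arg,
                               density=True)
    return H, xe, ye


# --------------------------------------------------------------- alignment

@dataclass
class LatentAlignment:
    rotation: np.ndarray        # orthogonal d x d matrix
    residual_rms: float         # RMS distance after alignment
    reference_rms: float        # RMS radius of the centered reference

    @property
    def relative_residual(self) -> float:
        return self.residual_rms / self.reference_rms if self.reference_rms > 0 else np.inf


def latent_alignment(reference_points: np.ndarray,
                     comparison_points: np.ndarray) -> LatentAlignment:
    """Least-squares orthogonal (rotation/reflection) alignment of matched
    latent configurations from two training runs; both sets are centered
    first. Used to test that the learned latent structure is consistent
    across seeds up to a rotation factor."""
    ref = np.atleast_2d(np.asarray(reference_points, dtype=float))
    comp = np.atleast_2d(np.asarray(comparison_points, dtype=float))
    if ref.shape != comp.shape:
        raise PairingError(f"point sets differ in shape: {ref.shape} vs {comp.shape}")
    ref_c = ref - ref.mean(axis=0)
    comp_c = comp - comp.mean(axis=0)
    R, _ = orthogonal_procrustes(comp_c, ref_c)
    resid = comp_c @ R - ref_c
    return LatentAlignment(
        rotation=R,
        residual_rms=float(np.sqrt(np.mean(np.sum(resid**2, axis=1)))),
        reference_rms=float(np.sqrt(np.mean(np.sum(ref_c**2, axis=1)))),
    )
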