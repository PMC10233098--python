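"""Model/Results interface to the supervised VAE.

`VAEClassifier` is built from a :class:`~kinvae.features.FeatureDataset`
(or a plain dataframe) and a :class:`~kinvae.config.NetworkConfig`;
``fit()`` standardizes the features, trains encoder, decoder and predictor
jointly on the equally weighted three-term loss, and returns a
`VAEClassifierResults` carrying the trained weights, the standardization
statistics, the per-epoch loss history and prediction/projection methods.
``cross_validate`` runs stratified (optionally participant-grouped) k-fold
cross-validation with per-fold standardization.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold

from . import nn
from .config import NetworkConfig
from .exceptions import FoldError, TrainingDivergedError, TrainingError
from .features import FEATURE_NAMES, FeatureDataset


@dataclass
class TrainedModel:
    """Trained weights plus everything needed to reuse them: the network
    config, the feature standardization stats and the loss history."""

    params: dict[str, np.ndarray]
    config: NetworkConfig
    stats: pd.DataFrame
    history: pd.DataFrame
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim


def train(dataset: FeatureDataset, config: NetworkConfig | None = None,
          seed: int | None = None) -> TrainedModel:
    """Mini-batch gradient training of the full model on a standardized dataset.

    If the dataset carries no standardization stats they are computed here.
    Weights are initialized from the seeded generator; batch order and the
    reparameterization draws come from the same stream, so a fixed seed
    reproduces the final weights bit-for-bit.
    """
    config = (config or NetworkConfig()).validate()
    if seed is None:
        seed = config.seed
    if dataset.stats is None:
        dataset = dataset.standardize()
    X = dataset.X
    y = dataset.y
    if len(np.unique(y)) < 2:
        raise TrainingError("training requires both classes present")

    rng = np.random.default_rng(seed)
    params = nn.init_params(X.shape[1], config, rng)
    opt = (nn.Adam if config.optimizer == "adam" else nn.SGD)(params, config.learning_rate)
    n = X.shape[0]
    hist = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        sums = np.zeros(3)
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            eps = rng.standard_normal((idx.size, config.latent_dim))
            loss, grads = nn.loss_and_grads(params, X[idx], y[idx], eps, config)
            if not np.isfinite(loss.total):
                raise TrainingDivergedError(epoch)
            opt.step(params, grads)
            sums += np.array([loss.recon, loss.kl, loss.pred]) * idx.size
        recon, kl, pred = sums / n
        hist.append((epoch, recon, kl, pred, recon + kl + pred))
    history = pd.DataFrame(hist, columns=["epoch", "recon", "kl", "pred", "total"])
    return TrainedModel(params=params, config=config, stats=dataset.stats, history=history)


@dataclass
class CVResult:
    """Fold-level accuracies of k-fold cross-validation."""

    fold_accuracies: list[float]
    fold_test_indices: list[np.ndarray] = field(default_factory=list)
    models: list[TrainedModel] | None = None

    @property
    def k(self) -> int:
        return len(self.fold_accuracies)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    def summary(self) -> str:
        lines = ["k-fold cross-validation", "-" * 34]
        lines += [f"fold {i + 1:2d}: accuracy = {a:.4f}"
                  for i, a in enumerate(self.fold_accuracies)]
        lines.append("-" * 34)
        lines.append(
            f"mean = {self.mean_accuracy:.4f}  sd = {self.sd_accuracy:.4f}  (k = {self.k})"
        )
        return "\n".join(lines)


def kfold_cv(dataset: FeatureDataset, config: NetworkConfig | None = None,
             k: int = 10, seed: int = 0, by_participant: bool = False,
             keep_models: bool = False) -> CVResult:
    """Stratified k-fold cross-validation of the full model.

    Each fold standardizes on its training rows only, trains from scratch,
    and scores held-out rows by arg-max of the predictor output evaluated at
    the encoder mean. ``by_participant=True`` keeps each participant's rows
    in a single fold (no identity leakage across folds).
    """
    config = (config or NetworkConfig()).validate()
    if k < 2:
        raise FoldError("k must be >= 2")
    y = dataset.y
    counts = np.bincount(y)
    if counts.size < 2 or counts.min() < k:
        raise FoldError(f"each class needs >= k={k} rows (counts={counts.tolist()})")
    raw = dataset if dataset.stats is None else dataset  # folds re-standardize from raw values
    if by_participant:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(raw.X, y, groups=raw.participants)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(raw.X, y)

    accs, models, fold_idx = [], [], []
    for fold, (tr_idx, te_idx) in enumerate(splits):
        train_ds = raw.subset(tr_idx)
        train_ds = FeatureDataset(train_ds.frame).standardize()
        model = train(train_ds, config, seed=(seed * 1009 + fold) & 0x7FFFFFFF)
        test_ds = FeatureDataset(raw.subset(te_idx).frame).standardize(model.stats)
        pred = nn.predict_proba(model.params, test_ds.X, config).argmax(axis=1)
        accs.append(float(np.mean(pred == test_ds.y)))
        fold_idx.append(np.asarray(te_idx))
        if keep_models:
            models.append(model)
    return CVResult(fold_accuracies=accs, fold_test_indices=fold_idx,
                    models=models if keep_models else None)


class VAEClassifier:
    """Supervised-VAE model object (statsmodels-style).

    Parameters
    ----------
    dataset : FeatureDataset
        Per-task feature rows with binary group labels.
    config : NetworkConfig, optional
        Architecture / optimization settings.
    """

    def __init__(self, dataset: FeatureDataset, config: NetworkConfig | None = None):
        self.dataset = dataset
        self.config = (config or NetworkConfig()).validate()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       config: NetworkConfig | None = None) -> "VAEClassifier":
        return cls(FeatureDataset(frame), config)

    def fit(self, seed: int | None = None) -> "VAEClassifierResults":
        ds = self.dataset if self.dataset.stats is not None else self.dataset.standardize()
        model = train(ds, self.config, seed=seed)
        return VAEClassifierResults(self, model, ds)

    def cross_validate(self, k: int = 10, seed: int = 0,
                       by_participant: bool = False,
                       keep_models: bool = False) -> CVResult:
        return kfold_cv(self.dataset, self.config, k=k, seed=seed,
                        by_participant=by_participant, keep_models=keep_models)


class VAEClassifierResults:
    """Fitted-model results: weights, loss history, prediction and encoding."""

    def __init__(self, model_obj: VAEClassifier, trained: TrainedModel,
                 dataset: FeatureDataset):
        self.model = model_obj
        self.trained = trained
        self.dataset = dataset  # standardized training data

    @property
    def config(self) -> NetworkConfig:
        return self.trained.config

    @property
    def loss_history(self) -> pd.DataFrame:
        return self.trained.history

    def _standardize_raw(self, dataset: FeatureDataset) -> FeatureDataset:
        if dataset.stats is not None:
            return dataset
        return dataset.standardize(self.trained.stats)

    def encode(self, X: np.ndarray) -> nn.EncoderOutput:
        """Encoder posterior for already-standardized feature vectors."""
        return nn.encode(self.trained.params, X, self.config)

    def encode_dataset(self, dataset: FeatureDataset | None = None) -> nn.EncoderOutput:
        ds = self._standardize_raw(dataset or self.dataset)
        return self.encode(ds.X)

    def predict_proba(self, dataset: FeatureDataset | None = None) -> np.ndarray:
        ds = self._standardize_raw(dataset or self.dataset)
        return nn.predict_proba(self.trained.params, ds.X, self.config)

    def predict(self, dataset: FeatureDataset | None = None) -> np.ndarray:
        return self.predict_proba(dataset).argmax(axis=1)

    def accuracy(self, dataset: FeatureDataset | None = None) -> float:
        ds = dataset or self.dataset
        return float(np.mean(self.predict(ds) == ds.y))

    def reconstruct(self, dataset: FeatureDataset | None = None) -> np.ndarray:
        ds = self._standardize_raw(dataset or self.dataset)
        return nn.reconstruct(self.trained.params, ds.X, self.config)

    def summary(self) -> str:
        h = self.loss_history
        cfg = self.config
        rows = [
            ("latent dim", cfg.latent_dim),
            ("encoder hidden", list(cfg.encoder_hidden)),
            ("predictor hidden", cfg.predictor_hidden),
            ("epochs", cfg.epochs),
            ("batch size", cfg.batch_size),
            ("learning rate", cfg.learning_rate),
            ("n rows", self.dataset.n_rows),
            ("final recon loss", round(float(h["recon"].iloc[-1]), 5)),
            ("final KL loss", round(float(h["kl"].iloc[-1]), 5)),
            ("final predictor loss", round(float(h["pred"].iloc[-1]), 5)),
            ("final total loss", round(float(h["total"].iloc[-1]), 5)),
            ("training accuracy", round(self.accuracy(), 4)),
        ]
        width = max(len(str(k)) for k, _ in rows)
        body = "\n".join(f"{k:<{width}}  {v}" for k, v in rows)
        head = "Supervised VAE results\n" + "=" * (width + 24)
        return f"{head}\n{body}"
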