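"""Exception hierarchy for kinvae."""


class KinvaeError(Exception):
    """Base class for all kinvae errors."""


class InvalidConfigError(KinvaeError, ValueError):
    """A configuration object violates its invariants."""


class DegenerateTrajectoryError(KinvaeError, ValueError):
    """Trajectory too short / stationary for the requested kinematic series."""


class ZeroVarianceFeatureError(KinvaeError, ValueError):
    """A feature column has zero variance and cannot be z-scored."""

    def __init__(self, feature: str):
        self.feature = feature
        super().__init__(f"feature column {feature!r} has zero variance")


class SchemaError(KinvaeError, ValueError):
    """A file is missing required columns or contains malformed values."""


class ShapeError(KinvaeError, ValueError):
    """Array dimensionality does not match the model/operation contract."""


class TrainingError(KinvaeError, RuntimeError):
    """Training cannot proceed (e.g. a single-class dataset)."""


class TrainingDivergedError(TrainingError):
    """Loss became non-finite during training."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")


class FoldError(KinvaeError, ValueError):
    """Cross-validation folds cannot be built from the data."""


class FitError(KinvaeError, ValueError):
    """Too few points to fit a class Gaussian."""


class FeatureNameError(KinvaeError, KeyError):
    """Unknown kinematic feature name."""


class PairingError(KinvaeError, ValueError):
    """Point sets passed to latent alignment cannot be paired."""
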