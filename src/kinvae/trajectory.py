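"""Single drag-trajectory representation and the synthetic movement generator.

A trajectory is one tap-to-lift finger path: (t, x, y) samples at a fixed
rate. The generator superimposes class-dependent noise on a minimum-jerk
reach — the standard smoothness-optimal model of goal-directed human
movement, whose bell-shaped speed profile gives the kinematic features
(speed/acceleration peaks, straightness, directional change) realistic
structure to respond to.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .exceptions import DegenerateTrajectoryError, InvalidConfigError


@dataclass
class Trajectory:
    """One tap-to-lift finger path sampled at a constant rate."""

    participant_id: str
    task_id: int
    trajectory_index: int
    t: np.ndarray  # seconds, strictly increasing, constant step
    x: np.ndarray  # screen units
    y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise DegenerateTrajectoryError("t, x, y must be 1-D arrays of equal length")
        if self.n_samples < 3:
            raise DegenerateTrajectoryError("a trajectory needs at least 3 samples")
        steps = np.diff(self.t)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise DegenerateTrajectoryError("time steps must be positive and constant")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of xy positions."""
        return np.column_stack([self.x, self.y])


@dataclass
class KinematicParams:
    """Noise parameters controlling how a simulated drag deviates from the
    ideal minimum-jerk reach.

    duration_scale
        Multiplier on movement duration (slower drags lower speed peaks).
    speed_jitter
        Log-SD of the multiplicative noise on the speed profile; raises speed
        variability and sharpens acceleration extremes.
    jitter_corr
        Correlation length of the speed jitter, as a fraction of the
        trajectory's samples; shorter correlation = higher-frequency jitter,
        hitting acceleration features harder than speed features.
    tremor
        Amplitude (screen units) of smooth lateral displacement noise
        orthogonal to the chord; lowers straightness, raises directional
        change.
    profile_flat
        Flatness of the base speed profile: the position profile blends the
        minimum-jerk curve with a constant-velocity ramp at weight
        ``profile_flat / (1 + profile_flat)``. Flatter profiles lower the
        peak speed for a fixed duration without suppressing jitter-driven
        acceleration extremes.
    """

    duration_scale: float = 1.0
    speed_jitter: float = 0.12
    jitter_corr: float = 0.06
    tremor: float = 3.0
    profile_flat: float = 0.35

    def scaled(self, log_shifts: np.ndarray) -> "KinematicParams":
        """Return params with each field multiplied by exp(shift)."""
        s = np.exp(np.asarray(log_shifts, dtype=float))
        return KinematicParams(
            duration_scale=self.duration_scale * s[0],
            speed_jitter=self.speed_jitter * s[1],
            jitter_corr=self.jitter_corr * s[2],
            tremor=self.tremor * s[3],
            profile_flat=self.profile_flat * (s[4] if s.size > 4 else 1.0),
        )


def minimum_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile s(tau) = 10t^3 - 15t^4 + 6t^5."""
    tau = np.asarray(tau, dtype=float)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau * tau)


def _smooth_noise(n: int, corr_frac: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance smooth Gaussian noise with correlation length corr_frac*n."""
    raw = rng.standard_normal(n)
    sigma = max(corr_frac * n, 1e-9)
    if sigma < 0.3:  # effectively white
        return raw
    sm = gaussian_filter1d(raw, sigma=sigma, mode="nearest")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_trajectory(
    start,
    target,
    duration: float,
    class_params: KinematicParams | None = None,
    sample_rate: float = 40.0,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Simulate one drag from ``start`` to ``target``.

    The base path is a minimum-jerk profile along the chord. Class-dependent
    noise enters twice: multiplicative jitter on the speed profile (the path
    increments are rescaled by a smooth log-normal factor and renormalized so
    the finger still reaches the target), and additive lateral tremor
    orthogonal to the chord, pinned to zero at both endpoints.

    With ``speed_jitter = tremor = 0`` the samples are exactly collinear.
    """
    if duration <= 0:
        raise InvalidConfigError("duration must be > 0")
    if sample_rate <= 0:
        raise InvalidConfigError("sample_rate must be > 0")
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.allclose(start, target):
        raise InvalidConfigError("start and target must differ")
    params = class_params or KinematicParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    n = int(round(duration * sample_rate)) + 1
    if n < 3:
        raise InvalidConfigError("duration*sample_rate too small: need >= 3 samples")
    tau = np.linspace(0.0, 1.0, n)
    w = params.profile_flat / (1.0 + params.profile_flat)
    s = (1.0 - w) * minimum_jerk_profile(tau) + w * tau

    ds = np.diff(s)
    if params.speed_jitter > 0:
        jitter = np.exp(params.speed_jitter * _smooth_noise(n - 1, params.jitter_corr, rng))
        ds = ds * jitter
        ds = ds / ds.sum()  # endpoint stays exactly on target
    s_jittered = np.concatenate([[0.0], np.cumsum(ds)])

    chord = target - start
    pos = start[None, :] + s_jittered[:, None] * chord[None, :]

    if params.tremor > 0:
        normal = np.array([-chord[1], chord[0]]) / np.linalg.norm(chord)
        lateral = params.tremor * _smooth_noise(n, 2 * params.jitter_corr, rng)
        lateral = lateral * np.sin(np.pi * tau)  # pinned at tap and lift
        pos = pos + lateral[:, None] * normal[None, :]

    t = np.arange(n) / sample_rate
    return Trajectory(
        participant_id="", task_id=-1, trajectory_index=-1,
        t=t, x=pos[:, 0], y=pos[:, 1],
    )
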