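"""Shared domain types: angles, noise specification, trajectories, RNG streams.

Conventions used throughout the package:

* Angles are in radians, wrapped to the half-open interval ``(-pi, pi]``.
* The allocentric zero direction lies along +X (the intended/straight-walk
  axis); counterclockwise rotations are positive.
* The egocentric frame has +U' rostral (forward) and +V' to the animal's
  left; negative V' is rightward.
* All lengths are in abstract "length units"; the scaling between physical
  and representational space is taken as unity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TWO_PI",
    "DEFAULT_SD",
    "wrap_angle",
    "make_rng",
    "NoiseSpec",
    "StepInput",
    "RealTrajectory",
]

TWO_PI = 2.0 * math.pi

#: Default noise standard deviation: pi/36 (5 degrees for angular quantities,
#: the same numeric value in length units for linear quantities).
DEFAULT_SD = math.pi / 36.0

INPUT_MODES = ("compass", "direct_rotation", "compass_differenced")


def wrap_angle(a):
    """Wrap angle(s) to the half-open interval ``(-pi, pi]``.

    Parameters
    ----------
    a : float or array_like
        Angle(s) in radians. Must be finite.

    Returns
    -------
    float or ndarray
        Value(s) congruent to ``a`` modulo 2*pi, in ``(-pi, pi]``.
    """
    arr = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wrap_angle requires finite input")
    # np.mod maps to [0, 2pi); negate twice to land in (-pi, pi].
    wrapped = -(np.mod(-arr + math.pi, TWO_PI) - math.pi)
    if np.ndim(a) == 0:
        return float(wrapped)
    return wrapped


def make_rng(seed: int, stream_id: str) -> np.random.Generator:
    """Create a named, reproducible random stream.

    The (seed, stream_id) pair maps deterministically to a
    :class:`numpy.random.SeedSequence` whose entropy is the seed followed by
    the UTF-8 bytes of the stream label, so distinct labels yield
    statistically independent streams while the same pair always reproduces
    the identical draw sequence.
    """
    if seed < 0:
        raise ValueError("seed must be >= 0")
    entropy = [int(seed)] + list(str(stream_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class NoiseSpec:
    """Noise configuration for a PI run.

    Attributes
    ----------
    delta_sd : float
        SD of the input noise delta (radians), applied to every measured
        heading or rotation.
    eps_angular_sd : float
        SD of the update noise epsilon applied to angular state parameters
        (radians).
    eps_linear_sd : float
        SD of the update noise epsilon applied to linear state parameters
        (length units).
    distribution : str
        Noise distribution; only ``"gaussian"`` is supported.
    input_mode : str
        ``"compass"`` (allocentric heading input), ``"direct_rotation"``
        (fresh rotation measurement each step) or ``"compass_differenced"``
        (rotation estimated from successive compass readings; errors
        telescope).
    """

    delta_sd: float = 0.0
    eps_angular_sd: float = 0.0
    eps_linear_sd: float = 0.0
    distribution: str = "gaussian"
    input_mode: str = "compass"

    def __post_init__(self):
        for name in ("delta_sd", "eps_angular_sd", "eps_linear_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.distribution != "gaussian":
            raise ValueError("only gaussian noise is supported")
        if self.input_mode not in INPUT_MODES:
            raise ValueError(
                f"input_mode must be one of {INPUT_MODES}, got {self.input_mode!r}"
            )

    def replace(self, **kw) -> "NoiseSpec":
        return replace(self, **kw)

    @property
    def noiseless(self) -> bool:
        return (
            self.delta_sd == 0.0
            and self.eps_angular_sd == 0.0
            and self.eps_linear_sd == 0.0
        )


@dataclass(frozen=True)
class StepInput:
    """Measured inputs for a single PI update.

    Exactly the fields required by the target model class must be present:
    allocentric-input models consume ``measured_heading``, egocentric-input
    models consume ``measured_rotation``.
    """

    step_length: float
    measured_heading: float | None = None
    measured_rotation: float | None = None


@dataclass
class RealTrajectory:
    """A physical-space walk of ``n_steps`` discrete steps.

    ``positions`` has shape (n_steps + 1, 2) and includes the home/origin
    row.  ``headings``, ``turns`` and ``step_lengths`` have length
    ``n_steps``; ``turns[k]`` is the heading change preceding step ``k+1``
    (with the initial reference heading taken as 0, so
    ``turns[0] == headings[0]``).
    """

    positions: np.ndarray
    headings: np.ndarray
    turns: np.ndarray
    step_lengths: np.ndarray

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.headings = np.asarray(self.headings, dtype=float)
        self.turns = np.asarray(self.turns, dtype=float)
        self.step_lengths = np.asarray(self.step_lengths, dtype=float)
        n = self.n_steps
        if self.positions.shape != (n + 1, 2):
            raise ValueError("positions must have shape (n_steps + 1, 2)")
        if not (len(self.turns) == len(self.step_lengths) == n):
            raise ValueError("headings, turns, step_lengths must have equal length")

    @property
    def n_steps(self) -> int:
        return len(self.headings)

    @classmethod
    def from_headings(cls, headings, step_lengths) -> "RealTrajectory":
        """Build a trajectory from per-step headings and lengths."""
        headings = wrap_angle(np.atleast_1d(np.asarray(headings, dtype=float)))
        step_lengths = np.broadcast_to(
            np.asarray(step_lengths, dtype=float), headings.shape
        ).copy()
        if headings.size:
            prev = np.concatenate(([0.0], headings[:-1]))
            turns = wrap_angle(headings - prev)
        else:
            turns = np.empty(0)
        steps = step_lengths[:, None] * np.column_stack(
            (np.cos(headings), np.sin(headings))
        )
        positions = np.vstack((np.zeros((1, 2)), np.cumsum(steps, axis=0)))
        return cls(positions, headings, turns, step_lengths)

    @property
    def endpoint(self) -> np.ndarray:
        return self.positions[-1]

    def radial_distances(self) -> np.ndarray:
        """Euclidean distance from home at every step (length n_steps + 1)."""
        return np.hypot(self.positions[:, 0], self.positions[:, 1])

    # ------------------------------------------------------------------ CSV
    # Dialect: header `step,x,y,heading,turn,step_length`; the step-0 row is
    # home, carrying the heading of the first step's frame and zero
    # turn/length; steps are 1-based thereafter.

    def to_csv(self, path) -> None:
        n = self.n_steps
        first_heading = float(self.headings[0]) if n else 0.0
        df = pd.DataFrame(
            {
                "step": np.arange(n + 1),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "heading": np.concatenate(([first_heading], self.headings)),
                "turn": np.concatenate(([0.0], self.turns)),
                "step_length": np.concatenate(([0.0], self.step_lengths)),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RealTrajectory":
        df = pd.read_csv(path)
        required = {"step", "x", "y", "heading", "turn", "step_length"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
        df = df.sort_values("step").reset_index(drop=True)
        positions = df[["x", "y"]].to_numpy()
        return cls(
            positions,
            df["heading"].to_numpy()[1:],
            df["turn"].to_numpy()[1:],
            df["step_length"].to_numpy()[1:],
        )
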