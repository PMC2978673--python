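"""Physical-space walk generators.

Two elementary directed-walk (DW) types are provided, differing only in
whether per-step angular errors accumulate:

* **ADW** (allothetic): each step's heading carries a fresh, independent
  error -- the agent reorients from an external compass after every step.
* **IDW** (idiothetic): heading errors are the running sum of all turn
  errors so far -- the agent integrates rotations and cannot reorient.

A random *turning walk* (the ground-truth locomotion used in the ensemble
experiments) is structurally an IDW: intended Gaussian turns between
successive steps accumulate into the heading.

Convention: the first step already carries a turn/heading error (the turn
precedes the step).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RealTrajectory, wrap_angle

__all__ = [
    "StepModel",
    "straight_walk",
    "adw",
    "idw",
    "turning_walk",
    "biased_step_walk",
    "headings_from_turn_errors",
]


def headings_from_turn_errors(errors: np.ndarray, accumulate: bool) -> np.ndarray:
    """Map per-step angular errors to per-step headings.

    ``accumulate=False`` gives ADW headings (each step's heading is its own
    error); ``accumulate=True`` gives IDW headings (running sum along the
    first axis).  Works on 1-D (one path) or 2-D ``(n_steps, n_paths)``
    arrays.
    """
    errors = np.asarray(errors, dtype=float)
    if accumulate:
        return np.cumsum(errors, axis=0)
    return errors.copy()


def _walk(n, L, delta_sd, rng, accumulate) -> RealTrajectory:
    if n < 0:
        raise ValueError("n must be >= 0")
    errors = rng.normal(0.0, delta_sd, size=n) if delta_sd > 0 else np.zeros(n)
    headings = headings_from_turn_errors(errors, accumulate=accumulate)
    return RealTrajectory.from_headings(headings, np.full(n, float(L)))


def straight_walk(n: int, L: float = 1.0) -> RealTrajectory:
    """Ideal noise-free walk: ``n`` steps of length ``L`` along +X."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > 0 and L <= 0:
        raise ValueError("L must be > 0")
    return RealTrajectory.from_headings(np.zeros(n), np.full(n, float(L)))


def adw(n: int, L: float, delta_sd: float, rng: np.random.Generator) -> RealTrajectory:
    """Allothetic directed walk: fresh independent heading error each step."""
    return _walk(n, L, delta_sd, rng, accumulate=False)


def idw(n: int, L: float, delta_sd: float, rng: np.random.Generator) -> RealTrajectory:
    """Idiothetic directed walk: heading errors accumulate across steps."""
    return _walk(n, L, delta_sd, rng, accumulate=True)


def turning_walk(
    n: int, L: float, turn_sd: float, rng: np.random.Generator
) -> RealTrajectory:
    """Random turning walk: Gaussian turns between successive steps.

    Same generator as :func:`idw`, in a different role: here the cumulative
    turns are the *true* locomotion a PI system must track, not errors.
    """
    return _walk(n, L, turn_sd, rng, accumulate=True)


@dataclass(frozen=True)
class StepModel:
    """General biased elementary step.

    Turns and step lengths are drawn jointly Gaussian with the given
    correlation; lengths are truncated at zero (negative draws rejected and
    redrawn), since linear errors are secondary to angular ones.
    """

    mean_turn: float = 0.0
    turn_sd: float = 0.0
    mean_length: float = 1.0
    length_sd: float = 0.0
    turn_length_correlation: float = 0.0

    def __post_init__(self):
        if self.turn_sd < 0 or self.length_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not -1.0 <= self.turn_length_correlation <= 1.0:
            raise ValueError("turn_length_correlation must lie in [-1, 1]")


def biased_step_walk(
    n: int,
    model: StepModel,
    rng: np.random.Generator,
    mode: str = "idw",
) -> RealTrajectory:
    """Walk built from general biased elementary steps.

    ``mode`` controls whether turn draws accumulate into the heading
    (``"idw"``) or act as fresh per-step headings (``"adw"``).
    """
    if mode not in ("adw", "idw"):
        raise ValueError("mode must be 'adw' or 'idw'")
    if n < 0:
        raise ValueError("n must be >= 0")
    rho = model.turn_length_correlation
    # Gaussian copula via correlated standard normals.
    z1 = rng.normal(size=n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal(size=n)
    turns = model.mean_turn + model.turn_sd * z1
    lengths = model.mean_length + model.length_sd * z2
    if model.length_sd > 0:
        bad = lengths < 0
        while np.any(bad):
            k = int(bad.sum())
            z1b = rng.normal(size=k)
            z2b = rho * z1b + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal(size=k)
            turns[bad] = model.mean_turn + model.turn_sd * z1b
            lengths[bad] = model.mean_length + model.length_sd * z2b
            bad = lengths < 0
    headings = wrap_angle(headings_from_turn_errors(turns, accumulate=(mode == "idw")))
    return RealTrajectory.from_headings(headings, lengths)
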