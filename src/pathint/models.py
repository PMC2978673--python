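"""Discrete-time home-vector (HV) update models for the four representation
classes, plus an N-basis ring variant.

Classes and their state:

* ``ac`` -- allocentric Cartesian ``(u, v)``: animal's position relative to
  home along fixed allocentric axes.
* ``ap`` -- allocentric polar ``(r, phi)``: distance and allocentric
  direction of the animal from home.
* ``ec`` -- egocentric Cartesian ``(u', v')``: home's position in the
  animal's body frame (+U' forward, +V' left).
* ``ep`` -- egocentric polar ``(r', phi')``: distance and egocentric bearing
  of home.
* ``ring`` -- N fixed, evenly spaced preferred directions with signed
  accumulated moduli (an allocentric static vectorial code with N >= 2
  basis vectors).

Noise contract: every measured heading or rotation carries a fresh input
error ``delta``; every state parameter written during an update carries a
fresh update error ``eps`` (angular SD for angles, linear SD for lengths).

Update bookkeeping for egocentric models: each update first records the
step (home shifts backward by the step length in the body frame) and then
incorporates the rotation measured at the end of that step, rotating the
entire representation -- newest step included.  The rotation error of step
``k`` therefore corrupts the records of steps 1..k, which is exactly the
reverse-order error accumulation that makes these models idiothetic
directed walks in representational space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import NoiseSpec, RealTrajectory, StepInput, wrap_angle

__all__ = [
    "ACState",
    "APState",
    "ECState",
    "EPState",
    "RingState",
    "HVTrace",
    "MODEL_NAMES",
    "sense_heading",
    "RotationSensor",
    "sense_rotation",
    "ac_step",
    "ap_step",
    "ec_step",
    "ep_step",
    "ring_step",
    "update_ac",
    "update_ap",
    "update_ec",
    "update_ep",
    "update_ring",
    "decode_hv",
    "make_state",
    "ring_decode_matrix",
    "run_pi",
]

MODEL_NAMES = ("ac", "ap", "ec", "ep", "ring")

_HEADING_INPUT = {"ac", "ap", "ring"}  # 'ac' also accepts rotation input modes


# --------------------------------------------------------------------------
# States
# --------------------------------------------------------------------------


@dataclass
class ACState:
    u: float | np.ndarray = 0.0
    v: float | np.ndarray = 0.0


@dataclass
class APState:
    r: float | np.ndarray = 0.0
    phi: float | np.ndarray = 0.0


@dataclass
class ECState:
    u_prime: float | np.ndarray = 0.0
    v_prime: float | np.ndarray = 0.0


@dataclass
class EPState:
    r_prime: float | np.ndarray = 0.0
    phi_prime: float | np.ndarray = 0.0


@dataclass
class RingState:
    """Evenly spaced preferred directions with signed moduli.

    ``preferred_dirs`` is fixed at construction; ``moduli`` may be shape
    ``(n_units,)`` or ``(n_units, n_paths)`` for batched simulation.
    """

    preferred_dirs: np.ndarray
    moduli: np.ndarray

    def __post_init__(self):
        self.preferred_dirs = np.asarray(self.preferred_dirs, dtype=float)
        self.moduli = np.asarray(self.moduli, dtype=float)
        if self.n_units < 2:
            raise ValueError("ring model requires at least 2 units")
        self.preferred_dirs.setflags(write=False)

    @property
    def n_units(self) -> int:
        return len(self.preferred_dirs)

    @classmethod
    def zeros(cls, n_units: int = 16, n_paths: int | None = None) -> "RingState":
        dirs = 2.0 * np.pi * np.arange(n_units) / n_units
        shape = (n_units,) if n_paths is None else (n_units, n_paths)
        return cls(wrap_angle(dirs), np.zeros(shape))


def make_state(model: str, n_units: int = 16, n_paths: int | None = None):
    """Zero-initialised (at-home) state for a model class."""
    if model == "ring":
        return RingState.zeros(n_units, n_paths)
    z = 0.0 if n_paths is None else np.zeros(n_paths)
    if model == "ac":
        return ACState(z, z)
    if model == "ap":
        return APState(z, z)
    if model == "ec":
        return ECState(z, z)
    if model == "ep":
        return EPState(z, z)
    raise ValueError(f"unknown model {model!r}; valid: {MODEL_NAMES}")


# --------------------------------------------------------------------------
# Sensing
# --------------------------------------------------------------------------


def sense_heading(true_heading, spec: NoiseSpec, rng: np.random.Generator):
    """Measured allocentric heading: true heading plus fresh compass error."""
    if spec.input_mode != "compass":
        raise ValueError("sense_heading requires input_mode='compass'")
    if spec.delta_sd == 0:
        return wrap_angle(true_heading)
    delta = rng.normal(0.0, spec.delta_sd, size=np.shape(true_heading) or None)
    return wrap_angle(np.asarray(true_heading) + delta) if np.ndim(true_heading) else wrap_angle(true_heading + delta)


class RotationSensor:
    """Stateful rotation measurement.

    ``direct_rotation``: each measured rotation is the true rotation plus a
    fresh error.  ``compass_differenced``: rotations are estimated as the
    difference of successive compass readings, so per-reading errors
    telescope across steps and the cumulative rotation error after n steps
    is exactly (last reading error - first reading error).
    """

    def __init__(self, spec: NoiseSpec, rng: np.random.Generator):
        if spec.input_mode not in ("direct_rotation", "compass_differenced"):
            raise ValueError(
                "RotationSensor requires input_mode 'direct_rotation' or "
                "'compass_differenced'"
            )
        self.spec = spec
        self.rng = rng
        self._prev_reading = None

    def _noise(self, shape):
        if self.spec.delta_sd == 0:
            return np.zeros(shape) if shape else 0.0
        return self.rng.normal(0.0, self.spec.delta_sd, size=shape or None)

    def measure(self, true_rotation, new_true_heading=None):
        """Measured rotation for one step.

        ``new_true_heading`` (the orientation after the rotation) is needed
        in compass-differenced mode; on the first call the previous reading
        is initialised from ``new_true_heading - true_rotation`` with its
        own fresh error.
        """
        shape = np.shape(true_rotation)
        if self.spec.input_mode == "direct_rotation":
            return wrap_angle(true_rotation + self._noise(shape))
        if new_true_heading is None:
            raise ValueError("compass_differenced mode requires new_true_heading")
        if self._prev_reading is None:
            prev_true = np.asarray(new_true_heading, dtype=float) - np.asarray(
                true_rotation, dtype=float
            )
            self._prev_reading = prev_true + self._noise(np.shape(prev_true))
        reading = np.asarray(new_true_heading, dtype=float) + self._noise(shape)
        measured = reading - self._prev_reading
        self._prev_reading = reading
        return wrap_angle(measured)


def sense_rotation(
    true_rotation,
    prev_true_heading,
    spec: NoiseSpec,
    rng: np.random.Generator,
    sensor: RotationSensor | None = None,
):
    """Measured rotation; convenience wrapper over :class:`RotationSensor`.

    For ``compass_differenced`` mode a persistent ``sensor`` must be passed
    so that the previous compass error is carried between calls.
    """
    if sensor is None:
        sensor = RotationSensor(spec, rng)
    new_heading = np.asarray(prev_true_heading, dtype=float) + np.asarray(
        true_rotation, dtype=float
    )
    if np.ndim(true_rotation) == 0:
        new_heading = float(new_heading)
    return sensor.measure(true_rotation, new_true_heading=new_heading)


# --------------------------------------------------------------------------
# Pure update kernels (explicit noise arguments; vectorized over paths)
# --------------------------------------------------------------------------


def ac_step(u, v, step_length, measured_heading, eps_u=0.0, eps_v=0.0):
    """AC update: add the measured step displacement, then linear update noise."""
    return (
        u + step_length * np.cos(measured_heading) + eps_u,
        v + step_length * np.sin(measured_heading) + eps_v,
    )


def ap_step(r, phi, step_length, measured_heading, eps_r=0.0, eps_phi=0.0):
    """AP update: exact polar incorporation of the measured step, then
    ``eps_r`` on the modulus (clipped at 0) and ``eps_phi`` on the direction.

    The ``eps_phi`` term rotates the entire accumulated representation.
    Returns ``(r, phi, n_clipped)``.
    """
    x = r * np.cos(phi) + step_length * np.cos(measured_heading)
    y = r * np.sin(phi) + step_length * np.sin(measured_heading)
    r_new = np.hypot(x, y) + eps_r
    clipped = r_new < 0
    n_clipped = int(np.count_nonzero(clipped))
    r_new = np.maximum(r_new, 0.0)
    phi_new = wrap_angle(np.arctan2(y, x) + eps_phi)
    return r_new, phi_new, n_clipped


def ec_step(u_prime, v_prime, step_length, measured_rotation, eps_u=0.0, eps_v=0.0):
    """EC update: home shifts backward by the step length, then the whole
    representation counter-rotates by the measured rotation, then linear
    update noise is added."""
    u1 = u_prime - step_length
    c = np.cos(measured_rotation)
    s = np.sin(measured_rotation)
    # rotate home vector by -measured_rotation (animal turns CCW => home
    # turns CW in the body frame)
    u2 = c * u1 + s * v_prime
    v2 = -s * u1 + c * v_prime
    return u2 + eps_u, v2 + eps_v


def ep_step(
    r_prime, phi_prime, step_length, measured_rotation, eps_r=0.0, eps_phi=0.0
):
    """EP update: exact polar incorporation of the backward home shift, then
    the measured counter-rotation and the angular update error are applied
    to the bearing (both rotate the entire representation), then ``eps_r``
    on the modulus (clipped at 0).  Returns ``(r', phi', n_clipped)``."""
    x = r_prime * np.cos(phi_prime) - step_length
    y = r_prime * np.sin(phi_prime)
    r_new = np.hypot(x, y) + eps_r
    clipped = r_new < 0
    n_clipped = int(np.count_nonzero(clipped))
    r_new = np.maximum(r_new, 0.0)
    phi_new = wrap_angle(np.arctan2(y, x) - measured_rotation + eps_phi)
    return r_new, phi_new, n_clipped


def ring_step(moduli, preferred_dirs, step_length, measured_heading, eps=0.0):
    """Ring update: every unit integrates the projection of the measured
    step onto its preferred direction, plus its own update noise."""
    dirs = np.asarray(preferred_dirs, dtype=float)
    if np.ndim(moduli) == 2:
        dirs = dirs[:, None]
    proj = step_length * np.cos(np.asarray(measured_heading) - dirs)
    return moduli + proj + eps


# --------------------------------------------------------------------------
# Spec-level update operations (draw their own update noise)
# --------------------------------------------------------------------------


def _lin_noise(spec, rng, shape, k=1):
    if spec.eps_linear_sd == 0:
        return [np.zeros(shape) if shape else 0.0] * k
    return [rng.normal(0.0, spec.eps_linear_sd, size=shape or None) for _ in range(k)]


def _ang_noise(spec, rng, shape):
    if spec.eps_angular_sd == 0:
        return np.zeros(shape) if shape else 0.0
    return rng.normal(0.0, spec.eps_angular_sd, size=shape or None)


def update_ac(state: ACState, inp: StepInput, spec: NoiseSpec, rng) -> ACState:
    if inp.measured_heading is None:
        raise ValueError("AC update requires a measured heading")
    eps_u, eps_v = _lin_noise(spec, rng, np.shape(state.u), 2)
    u, v = ac_step(state.u, state.v, inp.step_length, inp.measured_heading, eps_u, eps_v)
    return ACState(u, v)


def update_ap(state: APState, inp: StepInput, spec: NoiseSpec, rng) -> APState:
    if inp.measured_heading is None:
        raise ValueError("AP update requires a measured heading")
    (eps_r,) = _lin_noise(spec, rng, np.shape(state.r), 1)
    eps_phi = _ang_noise(spec, rng, np.shape(state.r))
    r, phi, _ = ap_step(
        state.r, state.phi, inp.step_length, inp.measured_heading, eps_r, eps_phi
    )
    return APState(r, phi)


def update_ec(state: ECState, inp: StepInput, spec: NoiseSpec, rng) -> ECState:
    if inp.measured_rotation is None:
        raise ValueError("EC update requires a measured rotation")
    eps_u, eps_v = _lin_noise(spec, rng, np.shape(state.u_prime), 2)
    u, v = ec_step(
        state.u_prime, state.v_prime, inp.step_length, inp.measured_rotation,
        eps_u, eps_v,
    )
    return ECState(u, v)


def update_ep(state: EPState, inp: StepInput, spec: NoiseSpec, rng) -> EPState:
    if inp.measured_rotation is None:
        raise ValueError("EP update requires a measured rotation")
    (eps_r,) = _lin_noise(spec, rng, np.shape(state.r_prime), 1)
    eps_phi = _ang_noise(spec, rng, np.shape(state.r_prime))
    r, phi, _ = ep_step(
        state.r_prime, state.phi_prime, inp.step_length, inp.measured_rotation,
        eps_r, eps_phi,
    )
    return EPState(r, phi)


def update_ring(state: RingState, inp: StepInput, spec: NoiseSpec, rng) -> RingState:
    if inp.measured_heading is None:
        raise ValueError("ring update requires a measured heading")
    shape = state.moduli.shape
    if spec.eps_linear_sd > 0:
        eps = rng.normal(0.0, spec.eps_linear_sd, size=shape)
    else:
        eps = 0.0
    moduli = ring_step(
        state.moduli, state.preferred_dirs, inp.step_length, inp.measured_heading, eps
    )
    return RingState(state.preferred_dirs, moduli)


# --------------------------------------------------------------------------
# Decoding
# --------------------------------------------------------------------------


def ring_decode_matrix(preferred_dirs: np.ndarray) -> np.ndarray:
    """Least-squares decoder (2 x N): projects moduli onto the first
    Fourier components of the preferred directions.  Exact inverse of the
    noise-free encoding."""
    dirs = np.asarray(preferred_dirs, dtype=float)
    A = np.column_stack((np.cos(dirs), np.sin(dirs)))
    return np.linalg.pinv(A)


def decode_hv(state, true_heading=0.0, _ring_decoder=None):
    """Allocentric estimate of the animal's position relative to home.

    Egocentric states store home-relative-to-animal in the body frame; they
    are mapped through the (true) frame heading into allocentric
    coordinates and negated.  The frame heading is only used by the error
    metric's frame alignment, never by the model update itself.
    """
    if isinstance(state, ACState):
        return state.u, state.v
    if isinstance(state, APState):
        return state.r * np.cos(state.phi), state.r * np.sin(state.phi)
    if isinstance(state, RingState):
        dec = _ring_decoder
        if dec is None:
            dec = ring_decode_matrix(state.preferred_dirs)
        xy = dec @ state.moduli
        return xy[0], xy[1]
    if isinstance(state, ECState):
        hx, hy = state.u_prime, state.v_prime
    elif isinstance(state, EPState):
        hx = state.r_prime * np.cos(state.phi_prime)
        hy = state.r_prime * np.sin(state.phi_prime)
    else:
        raise TypeError(f"cannot decode state of type {type(state).__name__}")
    c, s = np.cos(true_heading), np.sin(true_heading)
    # home vector in allocentric frame, then negate: animal relative to home
    return -(c * hx - s * hy), -(s * hx + c * hy)


# --------------------------------------------------------------------------
# Sequential simulation
# --------------------------------------------------------------------------


@dataclass
class HVTrace:
    """Per-step record of one PI run (length ``n_steps + 1`` incl. start)."""

    model: str
    state_columns: tuple
    states: np.ndarray  # (n_steps + 1, n_state_params)
    x_hat: np.ndarray
    y_hat: np.ndarray
    pos_error: np.ndarray
    n_clipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.state_columns))
        df.insert(0, "step", np.arange(len(self.x_hat)))
        df["x_hat"] = self.x_hat
        df["y_hat"] = self.y_hat
        df["pos_error"] = self.pos_error
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _state_vector(state) -> np.ndarray:
    if isinstance(state, ACState):
        return np.array([state.u, state.v], dtype=float)
    if isinstance(state, APState):
        return np.array([state.r, state.phi], dtype=float)
    if isinstance(state, ECState):
        return np.array([state.u_prime, state.v_prime], dtype=float)
    if isinstance(state, EPState):
        return np.array([state.r_prime, state.phi_prime], dtype=float)
    return np.asarray(state.moduli, dtype=float).copy()


_STATE_COLUMNS = {
    "ac": ("u", "v"),
    "ap": ("r", "phi"),
    "ec": ("u_prime", "v_prime"),
    "ep": ("r_prime", "phi_prime"),
}


def ego_rotation_schedule(traj: RealTrajectory) -> np.ndarray:
    """True rotations fed to egocentric models, one per step.

    The rotation associated with step ``k`` is the reorientation made at the
    end of that step, toward the next step's heading (zero after the final
    step).  Under this bookkeeping the body frame when taking step ``k``
    equals the true heading of step ``k``.
    """
    n = traj.n_steps
    rot = np.zeros(n)
    if n > 1:
        rot[:-1] = wrap_angle(traj.headings[1:] - traj.headings[:-1])
    return rot


def ego_frame_headings(traj: RealTrajectory) -> np.ndarray:
    """True body-frame heading after each step (length n_steps + 1)."""
    n = traj.n_steps
    if n == 0:
        return np.zeros(1)
    frames = np.empty(n + 1)
    frames[0] = traj.headings[0]
    frames[1:n] = traj.headings[1:]
    frames[n] = traj.headings[-1]
    return frames


def run_pi(
    traj: RealTrajectory,
    model: str,
    spec: NoiseSpec,
    rng: np.random.Generator,
    n_units: int = 16,
) -> HVTrace:
    """Run one PI model along a true trajectory and trace the decoded HV.

    Positional error at each step is the Euclidean distance between the
    decoded allocentric position estimate and the true position.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; valid: {MODEL_NAMES}")
    rotation_input = spec.input_mode in ("direct_rotation", "compass_differenced")
    if model in ("ap", "ring") and rotation_input:
        raise ValueError(f"model {model!r} requires input_mode='compass'")
    if model in ("ec", "ep") and not rotation_input:
        raise ValueError(
            f"model {model!r} requires a rotation input mode, not 'compass'"
        )

    n = traj.n_steps
    state = make_state(model, n_units=n_units)
    decoder = ring_decode_matrix(state.preferred_dirs) if model == "ring" else None
    columns = (
        tuple(f"m{i}" for i in range(n_units))
        if model == "ring"
        else _STATE_COLUMNS[model]
    )

    states = np.empty((n + 1, len(columns)))
    x_hat = np.empty(n + 1)
    y_hat = np.empty(n + 1)
    states[0] = _state_vector(state)

    egocentric = model in ("ec", "ep")
    if egocentric:
        rotations = ego_rotation_schedule(traj)
        frames = ego_frame_headings(traj)
        sensor = RotationSensor(spec, rng)
    elif model == "ac" and rotation_input:
        sensor = RotationSensor(spec, rng)
        heading_estimate = 0.0

    n_clipped = 0
    x0, y0 = decode_hv(state, traj.headings[0] if n else 0.0, decoder)
    x_hat[0], y_hat[0] = x0, y0

    for j in range(n):
        lam = traj.step_lengths[j]
        if egocentric:
            meas_rot = sensor.measure(rotations[j], new_true_heading=frames[j + 1])
            inp = StepInput(step_length=lam, measured_rotation=float(meas_rot))
        elif model == "ac" and rotation_input:
            meas_rot = sensor.measure(traj.turns[j], new_true_heading=traj.headings[j])
            heading_estimate = heading_estimate + float(meas_rot)
            inp = StepInput(step_length=lam, measured_heading=heading_estimate)
        else:
            meas = sense_heading(traj.headings[j], spec, rng)
            inp = StepInput(step_length=lam, measured_heading=float(meas))

        if model == "ac":
            state = update_ac(state, inp, spec, rng)
        elif model == "ap":
            (eps_r,) = _lin_noise(spec, rng, (), 1)
            eps_phi = _ang_noise(spec, rng, ())
            r, phi, nc = ap_step(
                state.r, state.phi, inp.step_length, inp.measured_heading,
                eps_r, eps_phi,
            )
            state = APState(r, phi)
            n_clipped += nc
        elif model == "ec":
            state = update_ec(state, inp, spec, rng)
        elif model == "ep":
            (eps_r,) = _lin_noise(spec, rng, (), 1)
            eps_phi = _ang_noise(spec, rng, ())
            r, phi, nc = ep_step(
                state.r_prime, state.phi_prime, inp.step_length,
                inp.measured_rotation, eps_r, eps_phi,
            )
            state = EPState(r, phi)
            n_clipped += nc
        else:
            state = update_ring(state, inp, spec, rng)

        states[j + 1] = _state_vector(state)
        frame = frames[j + 1] if egocentric else traj.headings[j]
        x, y = decode_hv(state, frame, decoder)
        x_hat[j + 1], y_hat[j + 1] = x, y

    err = np.hypot(x_hat - traj.positions[:, 0], y_hat - traj.positions[:, 1])
    return HVTrace(
        model=model,
        state_columns=columns,
        states=states,
        x_hat=x_hat,
        y_hat=y_hat,
        pos_error=err,
        n_clipped=n_clipped,
    )
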