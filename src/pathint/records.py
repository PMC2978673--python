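"""Closed-form per-step "neural records" of a PI run.

The record of step ``m`` (out of ``n``) is the final represented
displacement attributable to that step, expressed in the frame whose +U
axis is the true step direction.  Writing ``alpha(m, n)`` for the record's
angular error, the five classes are:

===================  ==========================================  ==========
class                alpha(m, n)                                 behaviour
===================  ==========================================  ==========
``esvr``             ``-(delta_m + ... + delta_n)``              IDW(-delta)
``advr``             ``eps_m + ... + eps_n``                     IDW(eps)
``edvr``             ``sum_{k=m..n} (eps_k - delta_k)``          IDW(eps-delta)
``asvr``             ``delta_m``                                 ADW(delta)
``asvr_idiothetic``  ``delta_1 + ... + delta_m``                 IDW(delta)
===================  ==========================================  ==========

The record vector is ``Lambda_m * (cos alpha, sin alpha)``; for the ASVR
classes, per-step linear update-noise components may additionally be
configured, in which case they add directly to the vector.

The sum of all records equals the represented home-vector endpoint, and --
with linear update noise off -- matches the sequential model updates of
:mod:`pathint.models` pathwise for the identical noise realisation
(:func:`simulate_endpoint` provides that independent route).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models

__all__ = [
    "RECORD_CLASSES",
    "ErrorSequences",
    "RecordStep",
    "record_angle",
    "record",
    "all_records",
    "reconstruct_endpoint",
    "renumber_reversed",
    "simulate_endpoint",
]

RECORD_CLASSES = ("esvr", "advr", "edvr", "asvr", "asvr_idiothetic")


@dataclass(frozen=True)
class ErrorSequences:
    """One realisation of the per-step noise driving a PI run.

    ``delta`` are input errors, ``eps_angular`` angular update errors,
    ``step_lengths`` the representational step lengths Lambda.  Optional
    ``eps_linear_u``/``eps_linear_v`` hold linear update-noise components
    (used by the ASVR classes only).
    """

    delta: np.ndarray
    eps_angular: np.ndarray
    step_lengths: np.ndarray
    eps_linear_u: np.ndarray | None = None
    eps_linear_v: np.ndarray | None = None

    def __post_init__(self):
        for name in ("delta", "eps_angular", "step_lengths"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        for name in ("eps_linear_u", "eps_linear_v"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, np.asarray(val, float))
        n = len(self.delta)
        for name in ("eps_angular", "step_lengths", "eps_linear_u", "eps_linear_v"):
            val = getattr(self, name)
            if val is not None and len(val) != n:
                raise ValueError("all error sequences must have equal length")

    @property
    def n(self) -> int:
        return len(self.delta)

    @classmethod
    def draw(
        cls,
        n: int,
        delta_sd: float,
        eps_angular_sd: float,
        rng: np.random.Generator,
        step_lengths=1.0,
        eps_linear_sd: float = 0.0,
    ) -> "ErrorSequences":
        lin_u = lin_v = None
        if eps_linear_sd > 0:
            lin_u = rng.normal(0.0, eps_linear_sd, size=n)
            lin_v = rng.normal(0.0, eps_linear_sd, size=n)
        return cls(
            delta=rng.normal(0.0, delta_sd, size=n) if delta_sd > 0 else np.zeros(n),
            eps_angular=(
                rng.normal(0.0, eps_angular_sd, size=n)
                if eps_angular_sd > 0
                else np.zeros(n)
            ),
            step_lengths=np.broadcast_to(np.asarray(step_lengths, float), (n,)).copy(),
            eps_linear_u=lin_u,
            eps_linear_v=lin_v,
        )


@dataclass(frozen=True)
class RecordStep:
    m: int
    angle: float
    u: float
    v: float

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.u, self.v])


def record_angle(cls_name: str, seqs: ErrorSequences, m: int, n: int) -> float:
    """Angular error of the record of step ``m`` after ``n`` steps."""
    if cls_name not in RECORD_CLASSES:
        raise ValueError(f"unknown record class {cls_name!r}; valid: {RECORD_CLASSES}")
    if not 1 <= m <= n <= seqs.n:
        raise IndexError(f"require 1 <= m <= n <= {seqs.n}, got m={m}, n={n}")
    i = m - 1
    if cls_name == "esvr":
        return float(-np.sum(seqs.delta[i:n]))
    if cls_name == "advr":
        return float(np.sum(seqs.eps_angular[i:n]))
    if cls_name == "edvr":
        return float(np.sum(seqs.eps_angular[i:n] - seqs.delta[i:n]))
    if cls_name == "asvr":
        return float(seqs.delta[i])
    # asvr_idiothetic: the heading estimate integrates all rotation errors
    # up to and including the step itself
    return float(np.sum(seqs.delta[:m]))


def record(cls_name: str, seqs: ErrorSequences, m: int, n: int) -> RecordStep:
    """Neural record of step ``m`` after a journey of ``n`` steps."""
    alpha = record_angle(cls_name, seqs, m, n)
    lam = seqs.step_lengths[m - 1]
    u = lam * np.cos(alpha)
    v = lam * np.sin(alpha)
    if cls_name in ("asvr", "asvr_idiothetic"):
        if seqs.eps_linear_u is not None:
            u += seqs.eps_linear_u[m - 1]
        if seqs.eps_linear_v is not None:
            v += seqs.eps_linear_v[m - 1]
    return RecordStep(m=m, angle=alpha, u=float(u), v=float(v))


def all_records(cls_name: str, seqs: ErrorSequences, n: int | None = None):
    n = seqs.n if n is None else n
    return [record(cls_name, seqs, m, n) for m in range(1, n + 1)]


def reconstruct_endpoint(cls_name: str, seqs: ErrorSequences, n: int | None = None):
    """Represented endpoint: the sum of all step records."""
    recs = all_records(cls_name, seqs, n)
    if not recs:
        return np.zeros(2)
    return np.sum([r.vector for r in recs], axis=0)


def renumber_reversed(records: list) -> list:
    """Renumber records in reverse temporal order (step n -> 1, ...).

    The endpoint (sum) is unchanged; the reversed sequence's incremental
    angles are fresh per-step errors accumulating forward, i.e. the
    cumulative form of an idiothetic directed walk.
    """
    n = len(records)
    return [
        RecordStep(m=n - r.m + 1, angle=r.angle, u=r.u, v=r.v)
        for r in reversed(records)
    ]


def records_to_frame(records: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "m": [r.m for r in records],
            "angle": [r.angle for r in records],
            "u": [r.u for r in records],
            "v": [r.v for r in records],
        }
    )


# --------------------------------------------------------------------------
# Independent route: sequential simulation with matched noise
# --------------------------------------------------------------------------

# Which model kernel realises each record class on a straight real walk,
# and how the noise sequences are fed to it.
_CLASS_MODEL = {
    "esvr": "ec",
    "advr": "ap",
    "edvr": "ep",
    "asvr": "ac",
    "asvr_idiothetic": "ac-idiothetic",
}


def simulate_endpoint(cls_name: str, seqs: ErrorSequences) -> np.ndarray:
    """Endpoint of the corresponding sequential model update on a straight
    real walk, driven by the identical noise realisation.

    This is the step-by-step route through :mod:`pathint.models` kernels --
    deliberately independent of the closed-form record algebra.  Linear
    update noise is honoured only for the ASVR classes (elsewhere it is not
    representable by a per-step record).
    """
    kind = _CLASS_MODEL[cls_name]
    n = seqs.n
    lam = seqs.step_lengths
    lin_u = seqs.eps_linear_u if seqs.eps_linear_u is not None else np.zeros(n)
    lin_v = seqs.eps_linear_v if seqs.eps_linear_v is not None else np.zeros(n)

    if kind == "ac":
        u = v = 0.0
        for j in range(n):
            u, v = models.ac_step(u, v, lam[j], seqs.delta[j], lin_u[j], lin_v[j])
        return np.array([u, v])

    if kind == "ac-idiothetic":
        u = v = 0.0
        heading_est = 0.0
        for j in range(n):
            heading_est += seqs.delta[j]  # true rotations are all zero
            u, v = models.ac_step(u, v, lam[j], heading_est, lin_u[j], lin_v[j])
        return np.array([u, v])

    if kind == "ap":
        r = phi = 0.0
        for j in range(n):
            # advr oracle configuration: perfect heading input, angular
            # update noise only
            r, phi, _ = models.ap_step(r, phi, lam[j], 0.0, 0.0, seqs.eps_angular[j])
        return np.array([r * np.cos(phi), r * np.sin(phi)])

    if kind == "ec":
        u = v = 0.0
        for j in range(n):
            u, v = models.ec_step(u, v, lam[j], seqs.delta[j])
        # body frame stays aligned with +X on a straight walk
        return np.array([-u, -v])

    # ep
    r = phi = 0.0
    for j in range(n):
        r, phi, _ = models.ep_step(
            r, phi, lam[j], seqs.delta[j], 0.0, seqs.eps_angular[j]
        )
    return np.array([-r * np.cos(phi), -r * np.sin(phi)])
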