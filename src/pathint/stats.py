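"""Ensemble statistics and closed-form checks for directed walks and PI runs.

Closed forms (mean contraction factor, ADW mean endpoint, IDW finite limit)
use the per-step mean cosine ``c = E[cos(delta)] = exp(-sd^2/2)`` of a
Gaussian angular error; Monte-Carlo estimators in this module provide the
in-repo ground truth for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import NoiseSpec, make_rng, wrap_angle
from .walks import headings_from_turn_errors
from . import models as _m

__all__ = [
    "expected_cos",
    "adw_mean_endpoint",
    "idw_limit",
    "dw_endpoints",
    "class_endpoints",
    "moment_comparison",
    "variance_ordering",
    "EnsembleCurves",
    "ensemble_hv_error",
    "growth_exponent",
    "TABLE1_MAPPING",
]

#: Record class -> (directed-walk kind, angular-error SD builder). The
#: representational endpoint distribution of each class on a straight real
#: walk equals the real-space endpoint distribution of this DW generator
#: with matched angular error.
TABLE1_MAPPING = {
    "esvr": ("idw", lambda d, e: d),
    "advr": ("idw", lambda d, e: e),
    "edvr": ("idw", lambda d, e: math.hypot(d, e)),
    "asvr": ("adw", lambda d, e: d),
    "asvr_idiothetic": ("idw", lambda d, e: d),
}


def expected_cos(delta_sd: float) -> float:
    """``E[cos(delta)]`` for ``delta ~ N(0, sd^2)``: ``exp(-sd^2/2)``."""
    if delta_sd < 0:
        raise ValueError("delta_sd must be >= 0")
    return math.exp(-0.5 * delta_sd * delta_sd)


def adw_mean_endpoint(n: int, L: float, delta_sd: float) -> np.ndarray:
    """Mean ADW endpoint ``(n L c, 0)``: the ideal shape shrunk by ``c``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.array([n * L * expected_cos(delta_sd), 0.0])


def idw_limit(L: float, delta_sd: float) -> float:
    """Limiting mean along-axis displacement of an IDW: ``L c / (1 - c)``.

    Each step's mean contracts geometrically (the first step already
    carries an error, contributing ``L c``), so the mean X saturates at
    ``L sum_{k>=1} c^k``.  Diverges at zero noise.
    """
    if delta_sd <= 0:
        raise ValueError("idw_limit requires delta_sd > 0 (no finite limit at 0)")
    c = expected_cos(delta_sd)
    return L * c / (1.0 - c)


# --------------------------------------------------------------------------
# Endpoint ensembles
# --------------------------------------------------------------------------


def dw_endpoints(
    kind: str,
    n: int,
    L: float,
    sd: float,
    n_paths: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """Endpoints (n_paths, 2) of elementary directed/random walks.

    ``kind``: ``"adw"`` (fresh heading errors), ``"idw"`` (accumulating),
    or ``"rw"`` (iid uniform headings, ``sd`` ignored).
    """
    if kind not in ("adw", "idw", "rw"):
        raise ValueError("kind must be 'adw', 'idw' or 'rw'")
    out = np.empty((n_paths, 2))
    done = 0
    while done < n_paths:
        p = min(chunk, n_paths - done)
        if kind == "rw":
            headings = rng.uniform(-math.pi, math.pi, size=(n, p))
        else:
            errors = rng.normal(0.0, sd, size=(n, p))
            headings = headings_from_turn_errors(errors, accumulate=(kind == "idw"))
        out[done : done + p, 0] = L * np.cos(headings).sum(axis=0)
        out[done : done + p, 1] = L * np.sin(headings).sum(axis=0)
        done += p
    return out


def class_endpoints(
    cls_name: str,
    n: int,
    delta_sd: float,
    eps_sd: float,
    n_paths: int,
    rng: np.random.Generator,
    L: float = 1.0,
) -> np.ndarray:
    """Representational endpoints (n_paths, 2) of a record class on a
    straight real walk, via the closed-form record angles (batched)."""
    delta = rng.normal(0.0, delta_sd, size=(n, n_paths))
    eps = rng.normal(0.0, eps_sd, size=(n, n_paths))
    if cls_name == "esvr":
        alpha = -(np.cumsum(delta[::-1], axis=0)[::-1])
    elif cls_name == "advr":
        alpha = np.cumsum(eps[::-1], axis=0)[::-1]
    elif cls_name == "edvr":
        alpha = np.cumsum((eps - delta)[::-1], axis=0)[::-1]
    elif cls_name == "asvr":
        alpha = delta
    elif cls_name == "asvr_idiothetic":
        alpha = np.cumsum(delta, axis=0)
    else:
        raise ValueError(f"unknown record class {cls_name!r}")
    return np.column_stack(
        (L * np.cos(alpha).sum(axis=0), L * np.sin(alpha).sum(axis=0))
    )


def moment_comparison(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator, n_boot: int = 400
) -> dict:
    """Two-sample comparison of endpoint mean and covariance.

    Returns per-component z-scores: difference divided by the combined
    standard error (analytic for means, bootstrap for covariance entries).
    """

    def cov_entries(x):
        c = np.cov(x, rowvar=False)
        return np.array([c[0, 0], c[1, 1], c[0, 1]])

    def boot_se(x):
        stats = np.empty((n_boot, 3))
        for i in range(n_boot):
            idx = rng.integers(0, len(x), size=len(x))
            stats[i] = cov_entries(x[idx])
        return stats.std(axis=0, ddof=1)

    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    mean_se = np.sqrt(
        a.var(axis=0, ddof=1) / len(a) + b.var(axis=0, ddof=1) / len(b)
    )
    cov_diff = cov_entries(a) - cov_entries(b)
    cov_se = np.sqrt(boot_se(a) ** 2 + boot_se(b) ** 2)
    return {
        "mean_diff": mean_diff,
        "mean_z": mean_diff / mean_se,
        "cov_diff": cov_diff,
        "cov_z": cov_diff / cov_se,
        "max_abs_z": float(
            max(np.max(np.abs(mean_diff / mean_se)), np.max(np.abs(cov_diff / cov_se)))
        ),
    }


def variance_ordering(
    n: int,
    L: float,
    delta_sd: float,
    n_paths: int,
    rng: np.random.Generator,
    n_boot: int = 500,
    ci: float = 0.95,
) -> dict:
    """Endpoint variance (trace of covariance) of IDW vs uniform random
    walk vs ADW, with bootstrap confidence intervals.

    The expected strict ordering is ``var_idw > var_rw > var_adw``.
    """
    endpoints = {
        "idw": dw_endpoints("idw", n, L, delta_sd, n_paths, rng),
        "rw": dw_endpoints("rw", n, L, 0.0, n_paths, rng),
        "adw": dw_endpoints("adw", n, L, delta_sd, n_paths, rng),
    }

    def trace_var(x):
        return float(np.trace(np.cov(x, rowvar=False)))

    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    report = {}
    for name, pts in endpoints.items():
        boots = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n_paths, size=n_paths)
            boots[i] = trace_var(pts[idx])
        report[name] = {
            "var": trace_var(pts),
            "ci": (float(np.percentile(boots, lo_q)), float(np.percentile(boots, hi_q))),
        }
    ordered = (
        report["idw"]["ci"][0] > report["rw"]["ci"][1]
        and report["rw"]["ci"][0] > report["adw"]["ci"][1]
    )
    report["ordering_holds"] = bool(ordered)
    return report


# --------------------------------------------------------------------------
# HV-error ensembles over shared true paths
# --------------------------------------------------------------------------


@dataclass
class EnsembleCurves:
    """Per-step ensemble statistics of HV positional error.

    ``mean_err[model]`` and ``se[model]`` have length ``n_steps + 1``;
    ``mean_R`` is the mean radial distance of the true paths.
    """

    steps: np.ndarray
    mean_err: dict
    se: dict
    mean_R: np.ndarray
    endpoint_mean: dict = field(default_factory=dict)
    n_paths: int = 0
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for model, curve in self.mean_err.items():
            frames.append(
                pd.DataFrame(
                    {
                        "step": self.steps,
                        "model": model,
                        "mean_err": curve,
                        "se": self.se[model],
                        "mean_R": self.mean_R,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _model_key(model) -> str:
    if isinstance(model, (tuple, list)):
        return f"{model[0]}{model[1]}"
    return str(model)


def _ensemble_decoded(model, headings, turns, lengths, spec, rng, n_units):
    """Decoded HV positions, shape (n_steps + 1, 2, n_paths), batched."""
    n, P = headings.shape
    out = np.zeros((n + 1, 2, P))
    name = model[0] if isinstance(model, (tuple, list)) else model
    if isinstance(model, (tuple, list)):
        n_units = model[1]

    if name in ("ec", "ep"):
        eff = spec if spec.input_mode != "compass" else spec.replace(
            input_mode="direct_rotation"
        )
        sensor = _m.RotationSensor(eff, rng)
        rotations = np.zeros((n, P))
        if n > 1:
            rotations[:-1] = wrap_angle(headings[1:] - headings[:-1])
        frames = np.vstack((headings, headings[-1:]))  # frame after step j is frames[j+1-1]... see below
        # frame while taking step j is headings[j]; after step j it is
        # headings[j+1] (last step: unchanged)
        if name == "ec":
            u = np.zeros(P)
            v = np.zeros(P)
            for j in range(n):
                meas = sensor.measure(rotations[j], new_true_heading=frames[j + 1])
                eu, ev = _lin2(spec, rng, P)
                u, v = _m.ec_step(u, v, lengths[j], meas, eu, ev)
                fh = frames[j + 1]
                c, s = np.cos(fh), np.sin(fh)
                out[j + 1, 0] = -(c * u - s * v)
                out[j + 1, 1] = -(s * u + c * v)
        else:
            r = np.zeros(P)
            phi = np.zeros(P)
            for j in range(n):
                meas = sensor.measure(rotations[j], new_true_heading=frames[j + 1])
                er = _lin1(spec, rng, P)
                ep_ = _ang1(spec, rng, P)
                r, phi, _ = _m.ep_step(r, phi, lengths[j], meas, er, ep_)
                fh = frames[j + 1]
                hx, hy = r * np.cos(phi), r * np.sin(phi)
                c, s = np.cos(fh), np.sin(fh)
                out[j + 1, 0] = -(c * hx - s * hy)
                out[j + 1, 1] = -(s * hx + c * hy)
        return out

    if name == "ac" and spec.input_mode != "compass":
        # idiothetic-input ASVR: integrate measured rotations into a
        # heading estimate
        sensor = _m.RotationSensor(spec, rng)
        u = np.zeros(P)
        v = np.zeros(P)
        est = np.zeros(P)
        for j in range(n):
            meas = sensor.measure(turns[j], new_true_heading=headings[j])
            est = est + meas
            eu, ev = _lin2(spec, rng, P)
            u, v = _m.ac_step(u, v, lengths[j], est, eu, ev)
            out[j + 1, 0] = u
            out[j + 1, 1] = v
        return out

    # compass-input models
    if name == "ac":
        u = np.zeros(P)
        v = np.zeros(P)
        for j in range(n):
            meas = _sense(headings[j], spec, rng)
            eu, ev = _lin2(spec, rng, P)
            u, v = _m.ac_step(u, v, lengths[j], meas, eu, ev)
            out[j + 1, 0] = u
            out[j + 1, 1] = v
        return out
    if name == "ap":
        r = np.zeros(P)
        phi = np.zeros(P)
        for j in range(n):
            meas = _sense(headings[j], spec, rng)
            er = _lin1(spec, rng, P)
            ep_ = _ang1(spec, rng, P)
            r, phi, _ = _m.ap_step(r, phi, lengths[j], meas, er, ep_)
            out[j + 1, 0] = r * np.cos(phi)
            out[j + 1, 1] = r * np.sin(phi)
        return out
    if name == "ring":
        state = _m.RingState.zeros(n_units, P)
        decoder = _m.ring_decode_matrix(state.preferred_dirs)
        moduli = state.moduli
        for j in range(n):
            meas = _sense(headings[j], spec, rng)
            if spec.eps_linear_sd > 0:
                eps = rng.normal(0.0, spec.eps_linear_sd, size=(n_units, P))
            else:
                eps = 0.0
            moduli = _m.ring_step(moduli, state.preferred_dirs, lengths[j], meas, eps)
            out[j + 1] = decoder @ moduli
        return out
    raise ValueError(f"unknown model {model!r}")


def _sense(h, spec, rng):
    if spec.delta_sd == 0:
        return h
    return h + rng.normal(0.0, spec.delta_sd, size=h.shape)


def _lin2(spec, rng, P):
    if spec.eps_linear_sd == 0:
        return 0.0, 0.0
    return (
        rng.normal(0.0, spec.eps_linear_sd, size=P),
        rng.normal(0.0, spec.eps_linear_sd, size=P),
    )


def _lin1(spec, rng, P):
    if spec.eps_linear_sd == 0:
        return 0.0
    return rng.normal(0.0, spec.eps_linear_sd, size=P)


def _ang1(spec, rng, P):
    if spec.eps_angular_sd == 0:
        return 0.0
    return rng.normal(0.0, spec.eps_angular_sd, size=P)


def ensemble_hv_error(
    models,
    spec: NoiseSpec,
    n_paths: int,
    n_steps: int,
    step_length: float = 1.0,
    turn_sd: float = 0.1,
    seed: int = 0,
    n_units: int = 16,
) -> EnsembleCurves:
    """Mean HV positional error per step for several models run over the
    same set of random turning-walk paths.

    Each model consumes its own independent noise stream; the true paths
    are shared across models.  ``models`` entries are model names or
    ``("ring", N)`` tuples.
    """
    path_rng = make_rng(seed, "path-turns")
    turns = path_rng.normal(0.0, turn_sd, size=(n_steps, n_paths))
    headings = np.cumsum(turns, axis=0)
    lengths = np.full(n_steps, float(step_length))
    dx = lengths[:, None] * np.cos(headings)
    dy = lengths[:, None] * np.sin(headings)
    X = np.vstack((np.zeros((1, n_paths)), np.cumsum(dx, axis=0)))
    Y = np.vstack((np.zeros((1, n_paths)), np.cumsum(dy, axis=0)))
    R = np.hypot(X, Y)

    steps = np.arange(n_steps + 1)
    mean_err, se, endpoint_mean = {}, {}, {}
    for model in models:
        key = _model_key(model)
        rng = make_rng(seed, f"model:{key}")
        decoded = _ensemble_decoded(
            model, headings, turns, lengths, spec, rng, n_units
        )
        err = np.hypot(decoded[:, 0, :] - X, decoded[:, 1, :] - Y)
        mean_err[key] = err.mean(axis=1)
        se[key] = err.std(axis=1, ddof=1) / math.sqrt(n_paths)
        endpoint_mean[key] = decoded[-1].mean(axis=1)

    return EnsembleCurves(
        steps=steps,
        mean_err=mean_err,
        se=se,
        mean_R=R.mean(axis=1),
        endpoint_mean=endpoint_mean,
        n_paths=n_paths,
        config={
            "n_paths": n_paths,
            "n_steps": n_steps,
            "step_length": step_length,
            "turn_sd": turn_sd,
            "seed": seed,
            "delta_sd": spec.delta_sd,
            "eps_angular_sd": spec.eps_angular_sd,
            "eps_linear_sd": spec.eps_linear_sd,
            "input_mode": spec.input_mode,
        },
    )


def growth_exponent(steps, values, lo: int = 100, hi: int | None = None) -> float:
    """Log-log OLS slope of ``values`` vs ``steps`` over ``[lo, hi]``."""
    steps = np.asarray(steps, float)
    values = np.asarray(values, float)
    hi = steps.max() if hi is None else hi
    mask = (steps >= lo) & (steps <= hi) & (values > 0)
    if mask.sum() < 2:
        raise ValueError("not enough points in the fit window")
    slope, _ = np.polyfit(np.log(steps[mask]), np.log(values[mask]), 1)
    return float(slope)
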