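"""Config-driven experiments: the four-model HV-error ensemble and a small
deterministic test fixture."""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import DEFAULT_SD, NoiseSpec, make_rng
from .models import run_pi
from .records import ErrorSequences, all_records, reconstruct_endpoint, RECORD_CLASSES
from .stats import EnsembleCurves, ensemble_hv_error
from .walks import straight_walk, turning_walk

__all__ = ["ExperimentConfig", "run_fig4", "make_fixture", "DEFAULT_MODELS"]

DEFAULT_MODELS = ("ap", "ep", "ac", "ec")


@dataclass
class ExperimentConfig:
    """Ensemble experiment configuration.

    Defaults reproduce the reference experiment: 1000 random turning-walk
    paths of 1000 unit steps (turn SD 0.1 rad), input and update noise SDs
    of pi/36.
    """

    n_paths: int = 1000
    n_steps: int = 1000
    step_length: float = 1.0
    turn_sd: float = 0.1
    delta_sd: float = DEFAULT_SD
    eps_angular_sd: float = DEFAULT_SD
    eps_linear_sd: float = DEFAULT_SD
    input_mode: str = "compass"
    models: tuple = DEFAULT_MODELS
    n_units: int = 16
    seed: int = 0
    trace_steps: int = 100
    out_dir: str | None = None

    def __post_init__(self):
        for name in ("n_paths", "n_steps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.step_length <= 0:
            raise ValueError("step_length must be > 0")
        self.models = tuple(self.models)

    @property
    def noise(self) -> NoiseSpec:
        return NoiseSpec(
            delta_sd=self.delta_sd,
            eps_angular_sd=self.eps_angular_sd,
            eps_linear_sd=self.eps_linear_sd,
            input_mode=self.input_mode,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def run_fig4(config: ExperimentConfig) -> tuple[EnsembleCurves, dict]:
    """Run the multi-model HV-error ensemble and per-model example traces.

    Returns the ensemble curves and a dict of one :class:`HVTrace` per
    model, computed on a single shared short turning walk.  If
    ``config.out_dir`` is set, writes ``curves.csv``, ``trace_<model>.csv``
    and a ``config.json`` echo there.
    """
    curves = ensemble_hv_error(
        list(config.models),
        config.noise,
        n_paths=config.n_paths,
        n_steps=config.n_steps,
        step_length=config.step_length,
        turn_sd=config.turn_sd,
        seed=config.seed,
        n_units=config.n_units,
    )

    n_trace = min(config.trace_steps, config.n_steps)
    trace_walk = turning_walk(
        n_trace, config.step_length, config.turn_sd, make_rng(config.seed, "trace-path")
    )
    traces = {}
    for model in config.models:
        name = model[0] if isinstance(model, (tuple, list)) else model
        n_units = model[1] if isinstance(model, (tuple, list)) else config.n_units
        spec = config.noise
        if name in ("ec", "ep") and spec.input_mode == "compass":
            spec = spec.replace(input_mode="direct_rotation")
        key = name if not isinstance(model, (tuple, list)) else f"{name}{n_units}"
        traces[key] = run_pi(
            trace_walk, name, spec, make_rng(config.seed, f"trace:{key}"),
            n_units=n_units,
        )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        curves.to_csv(out / "curves.csv")
        for key, trace in traces.items():
            trace.to_csv(out / f"trace_{key}.csv")
        with open(out / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2)
    return curves, traces


def make_fixture(seed: int = 0, n_steps: int = 3) -> dict:
    """Small deterministic bundle: a straight walk, fixed noise sequences,
    and the per-class records/endpoints frozen at generation time.

    All values are plain lists so the bundle is JSON-serialisable.
    """
    rng_delta = make_rng(seed, "fixture-delta")
    rng_eps = make_rng(seed, "fixture-eps")
    seqs = ErrorSequences(
        delta=rng_delta.normal(0.0, DEFAULT_SD, size=n_steps),
        eps_angular=rng_eps.normal(0.0, DEFAULT_SD, size=n_steps),
        step_lengths=np.ones(n_steps),
    )
    walk = straight_walk(n_steps, 1.0)
    bundle = {
        "seed": seed,
        "n_steps": n_steps,
        "delta": seqs.delta.tolist(),
        "eps_angular": seqs.eps_angular.tolist(),
        "step_lengths": seqs.step_lengths.tolist(),
        "walk_endpoint": walk.endpoint.tolist(),
        "records": {},
        "endpoints": {},
    }
    for cls_name in RECORD_CLASSES:
        recs = all_records(cls_name, seqs)
        bundle["records"][cls_name] = [
            {"m": r.m, "angle": r.angle, "u": r.u, "v": r.v} for r in recs
        ]
        bundle["endpoints"][cls_name] = reconstruct_endpoint(cls_name, seqs).tolist()
    return bundle
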