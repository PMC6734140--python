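"""Run configuration: schema-validated specs, execution helpers, manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import analysis
from .generative_model import validate_model
from .paradigms import RivalrySpec, TroxlerSpec, build_necker_model, \
    build_rivalry_model, build_troxler_model
from .simulation import SimulationRecord, run_simulation

__all__ = ["EngineConfig", "RunConfig", "load_config", "dump_config",
           "build_paradigm", "execute_run", "execute_sweep"]

_BUILDERS = {
    "troxler": (TroxlerSpec, build_troxler_model),
    "rivalry": (RivalrySpec, build_rivalry_model),
    "necker": (RivalrySpec, build_necker_model),
}


class EngineConfig(BaseModel):
    """Inference/planning engine settings shared across paradigms."""

    model_config = ConfigDict(extra="forbid")

    gamma: float = Field(default=16.0, ge=0)
    tol: float = Field(default=1e-6, gt=0)
    max_iters: int = Field(default=16, ge=1)
    mode: Literal["argmax", "sample"] = "argmax"
    dt: float = Field(default=0.25, gt=0)


class RunConfig(BaseModel):
    """A fully specified simulation job.

    ``spec`` holds the paradigm parameters (a :class:`TroxlerSpec` for
    ``troxler``, a :class:`RivalrySpec` for ``rivalry``/``necker``); unknown
    keys anywhere in the config are rejected.  ``seed`` overrides the spec's
    seed when given.
    """

    model_config = ConfigDict(extra="forbid")

    paradigm: Literal["troxler", "rivalry", "necker"]
    spec: Union[TroxlerSpec, RivalrySpec] = Field(default_factory=dict)
    engine: EngineConfig = Field(default_factory=EngineConfig)
    outdir: str | None = None
    seed: int | None = None

    @model_validator(mode="before")
    @classmethod
    def _typed_spec(cls, data):
        # the paradigm decides which spec schema the spec block must satisfy
        if isinstance(data, dict) and data.get("paradigm") in _BUILDERS:
            spec_cls = _BUILDERS[data["paradigm"]][0]
            spec = data.get("spec", {})
            if isinstance(spec, dict):
                data = {**data, "spec": spec_cls(**spec)}
        return data

    @model_validator(mode="after")
    def _spec_matches_paradigm(self) -> "RunConfig":
        spec_cls = _BUILDERS[self.paradigm][0]
        if not isinstance(self.spec, spec_cls):
            raise ValueError(
                f"paradigm {self.paradigm!r} requires a {spec_cls.__name__}, "
                f"got {type(self.spec).__name__}")
        return self

    @property
    def effective_seed(self) -> int:
        return self.seed if self.seed is not None else self.spec.seed


def load_config(path) -> RunConfig:
    """Read and validate a YAML/JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return RunConfig(**data)


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False)


def build_paradigm(cfg: RunConfig):
    """Construct the (model, environment) pair for a configuration."""
    _, builder = _BUILDERS[cfg.paradigm]
    return builder(cfg.spec)


def execute_run(cfg: RunConfig, outdir=None) -> SimulationRecord:
    """Build, simulate and (optionally) write traces plus a re-run manifest."""
    model, env = build_paradigm(cfg)
    eng = cfg.engine
    record = run_simulation(
        model, env, cfg.spec.horizon, mode=eng.mode, seed=cfg.effective_seed,
        gamma=eng.gamma, tol=eng.tol, max_iters=eng.max_iters, dt=eng.dt,
        metadata={"config": cfg.model_dump(mode="json")})
    outdir = outdir or cfg.outdir
    if outdir is not None:
        record.save(outdir)
    return record


def _summarise(cfg: RunConfig, record: SimulationRecord) -> dict:
    if cfg.paradigm == "troxler":
        stim = [f.name for f in record.factors if f.name != "fixation"]
        trace = analysis.entropy_trace(record, stim)
        bound = analysis.max_entropy(record, stim)
        fade = analysis.time_to_fade(trace, 0.99, bound)
        return {"fade_time_steps": np.nan if fade is None else fade,
                "final_entropy": float(trace[-1]),
                "max_entropy": bound}
    sw = analysis.detect_switches(record)
    return {"n_switches": sw.n_switches,
            "switch_rate_per_step": sw.rate_per_step,
            "switch_rate_hz": sw.rate_hz(record.dt)}


def execute_sweep(cfg: RunConfig, param: str, values, outdir=None) -> pd.DataFrame:
    """Re-run the configured job over a grid of one paradigm parameter.

    ``param`` names a field of the paradigm spec (e.g. ``omega_stim`` for the
    Fig.-style transition-precision experiment, or ``zeta_R`` for likelihood
    asymmetries); one summary row is produced per value.
    """
    spec_cls = type(cfg.spec)
    rows = []
    for v in values:
        spec_v = spec_cls(**{**cfg.spec.model_dump(), param: v})
        cfg_v = cfg.model_copy(update={"spec": spec_v, "outdir": None})
        record = execute_run(cfg_v)
        rows.append({"param": param, "value": v, **_summarise(cfg_v, record)})
    frame = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(outdir / "sweep.csv", index=False)
        (outdir / "sweep_manifest.json").write_text(json.dumps({
            "param": param, "values": list(map(float, values)),
            "config": cfg.model_dump(mode="json")}, indent=2, sort_keys=True))
    return frame
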