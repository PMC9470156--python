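"""JSON configuration loading, validation and result/trajectory output.

All model runs are deterministic; the only seed consumer is the
synthetic observation-table generator.  Configurations are strict JSON:
unknown keys are rejected and numeric parameters are range-checked by
the owning model's constructors before any computation starts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .lande import MutationKernel, detect_phases
from .lifecycle import LifeCycle, fitness_report
from .observations import analyse, synth_observations
from .ratchet import RatchetParams, evolve_ratchet
from .scaffolding import ScaffoldParams, evolve_scaffold
from .tradeoff import TradeoffParams, argmax_trait, fitness_landscape

log = logging.getLogger("etidyn")

__all__ = ["RunConfig", "load_config", "write_trajectory", "run"]

_MODELS = ("lifecycle", "tradeoff", "scaffold", "ratchet", "observe")

_PARAM_TYPES = {
    "tradeoff": TradeoffParams,
    "scaffold": ScaffoldParams,
    "ratchet": RatchetParams,
}


@dataclass
class RunConfig:
    """Validated run description: model, parameters, output paths, seed."""

    model: str
    parameters: dict[str, Any] = field(default_factory=dict)
    output: dict[str, str] = field(default_factory=dict)
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}, got {self.model!r}")
        if self.seed is not None and not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _validate_parameters(model: str, params: dict) -> dict:
    """Range-check model parameters by building the owning dataclass."""
    params = dict(params)
    if model == "lifecycle":
        LifeCycle.from_dict({k: v for k, v in params.items() if k != "method" and k != "horizon"})
        return params
    if model == "observe":
        return params
    cls = _PARAM_TYPES[model]
    names = {f.name for f in dataclasses.fields(cls)}
    extra = {"kernel", "grid", "theta0", "sigma_theta", "t_max"}
    unknown = set(params) - names - extra
    if unknown:
        raise ValueError(f"unknown {model} parameter keys: {sorted(unknown)}")
    cls(**{k: v for k, v in params.items() if k in names})
    if "kernel" in params:
        MutationKernel(**params["kernel"])
    return params


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a JSON object")
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; allowed: {sorted(allowed)}")
    cfg = RunConfig(**raw)
    cfg.parameters = _validate_parameters(cfg.model, cfg.parameters)
    log.info("loaded config: model=%s parameters=%s", cfg.model, cfg.parameters)
    return cfg


def write_trajectory(traj, path: str | Path) -> None:
    """Write a trajectory CSV with 17-significant-digit floats."""
    frame: pd.DataFrame = traj.to_frame() if hasattr(traj, "to_frame") else traj
    if len(frame) == 0:
        raise ValueError("refusing to write an empty trajectory")
    frame.to_csv(path, index=False, float_format="%.17g")


def _trajectory_summary(traj) -> dict:
    t0, t1, t2 = (None, None, None)
    try:
        t0, t1, t2 = detect_phases(traj)
    except ValueError:
        pass
    return {
        "final_traits": traj.traits[-1].tolist(),
        "F_initial": float(traj.F_values[0]),
        "F_final": float(traj.F_values[-1]),
        "phases": {"t0": t0, "t1": t1, "t2": t2},
        "converged": bool(traj.converged),
        "message": traj.message,
    }


def run(config: RunConfig) -> dict:
    """Dispatch a validated config to its model and summarise the result."""
    p = dict(config.parameters)
    out: dict[str, Any] = {"model": config.model, "version": __version__}
    traj = None
    if config.model == "lifecycle":
        lc = LifeCycle.from_dict({k: v for k, v in p.items() if k not in ("method", "horizon")})
        rep = fitness_report(lc, f3_method=p.get("method", "eigen"))
        out.update(rep.to_dict())
    elif config.model == "tradeoff":
        kernel = p.pop("kernel", None)
        grid = p.pop("grid", 1001)
        theta0 = p.pop("theta0", None)
        sigma_theta = p.pop("sigma_theta", 0.01)
        t_max = p.pop("t_max", 1e4)
        params = TradeoffParams(**p)
        land = fitness_landscape(params, grid)
        out["theta0_hat"] = argmax_trait(land, "f2")
        out["theta_star_hat"] = argmax_trait(land, "F")
        if theta0 is not None:
            from .tradeoff import fitness_F, fitness_f2
            from .lande import integrate_lande_1d

            traj = integrate_lande_1d(
                lambda th: fitness_F(th, params),
                theta0,
                sigma_theta,
                t_max=t_max,
                aux={"f2": lambda th: fitness_f2(th, params)},
            )
            out.update(_trajectory_summary(traj))
        _ = kernel
    elif config.model == "scaffold":
        kernel = p.pop("kernel", None)
        t_max = p.pop("t_max", 300.0)
        params = ScaffoldParams(**p)
        kern = MutationKernel(**kernel) if kernel else None
        traj = evolve_scaffold(params, kern, t_max=t_max)
        out.update(_trajectory_summary(traj))
    elif config.model == "ratchet":
        kernel = p.pop("kernel", None)
        t_max = p.pop("t_max", 5e9)
        params = RatchetParams(**p)
        kern = MutationKernel(**kernel) if kernel else None
        traj = evolve_ratchet(params, kern, t_max=t_max)
        out["prop_G_initial"] = float(traj.extras["prop_G"][0])
        out["prop_G_final"] = float(traj.extras["prop_G"][-1])
        out.update(_trajectory_summary(traj))
    elif config.model == "observe":
        if "table_csv" in p:
            from .observations import TraitObservationTable

            table = TraitObservationTable.from_csv(p["table_csv"])
        else:
            if config.seed is None:
                raise ValueError("observe without table_csv requires a seed")
            table = synth_observations(seed=config.seed, **{
                k: v for k, v in p.items() if k != "k_sd"
            })
        res = analyse(table, k_sd=p.get("k_sd", 2.0))
        out["pooled_slope"] = res.pooled_slope
        out["pooled_intercept"] = res.pooled_intercept
        out["n_flagged"] = int(res.flags.sum())
        out["flagged_rows"] = [int(i) for i in res.flags.nonzero()[0]]
    if traj is not None and "trajectory_csv" in config.output:
        write_trajectory(traj, config.output["trajectory_csv"])
    if "summary_json" in config.output:
        Path(config.output["summary_json"]).write_text(json.dumps(out, indent=2))
    return out
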