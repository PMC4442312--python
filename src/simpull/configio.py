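"""YAML (de)serialization of run configurations."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .pipeline import (ColocParams, DetectionParams, RunConfig, StepFitParams,
                       StoichParams, TraceParams)
from .simulator import ChannelModel, SimulationConfig

__all__ = ["run_config_to_dict", "run_config_from_dict",
           "load_run_config", "save_run_config"]


def _sim_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    channels = d.pop("channels", None)
    if channels is not None:
        d["channels"] = tuple(
            ChannelModel(
                label=c.get("label", "A"),
                copy_number_dist={int(k): float(v)
                                  for k, v in c.get("copy_number_dist", {1: 1.0}).items()},
                maturation_prob=float(c.get("maturation_prob", 0.75)),
                unit_intensity=float(c.get("unit_intensity", 300.0)),
            ) for c in channels)
    if "channel_offset_px" in d:
        d["channel_offset_px"] = tuple(d["channel_offset_px"])
    return SimulationConfig(**d)


def run_config_to_dict(config: RunConfig) -> dict:
    return asdict(config)


def run_config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    kwargs: dict = {}
    if "simulation" in d:
        kwargs["simulation"] = _sim_from_dict(d.pop("simulation"))
    ctrl = d.pop("control", None)
    if ctrl is not None:
        kwargs["control"] = _sim_from_dict(ctrl)
    blocks = {"detection": DetectionParams, "trace": TraceParams,
              "steps": StepFitParams, "stoichiometry": StoichParams,
              "colocalization": ColocParams}
    for name, cls in blocks.items():
        if name in d:
            block = dict(d.pop(name))
            for key in ("annulus_radii_px", "offset_px"):
                if key in block:
                    block[key] = tuple(block[key])
            kwargs[name] = cls(**block)
    kwargs.update(d)
    return RunConfig(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return run_config_from_dict(yaml.safe_load(fh))


def save_run_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(run_config_to_dict(config), fh, sort_keys=True)
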