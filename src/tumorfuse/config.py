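"""YAML configuration for experiments.

A config file is a nested mapping with optional sections ``params``
(full-model parameter overrides), ``experiment`` (benchmark settings)
and ``grid``; anything omitted keeps the package defaults, so a file
can pin just the values a study varies.  The replicate protocol
(several cohort sizes, several repetitions each) is expressible in one
file via ``experiment.n_patients`` and ``experiment.replicates``.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .benchmark import ExperimentConfig
from .glioma import FullModelParams

__all__ = ["load_experiment_config", "save_experiment_config"]


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    params = FullModelParams(**(raw.get("params") or {}))
    exp = dict(raw.get("experiment") or {})
    grid = raw.get("grid") or {}
    if "length" in grid:
        exp["grid_length"] = grid["length"]
    if "n_nodes" in grid:
        exp["grid_nodes"] = grid["n_nodes"]
    for key in ("t0_list", "tp_list"):
        if key in exp:
            exp[key] = tuple(exp[key])
    if "sampling_ranges" in exp:
        exp["sampling_ranges"] = {
            k: tuple(v) for k, v in exp["sampling_ranges"].items()
        }
    return ExperimentConfig(base_params=params, **exp)


def save_experiment_config(config: ExperimentConfig, path: str | Path) -> None:
    data = asdict(config)
    params = data.pop("base_params")
    data.pop("grid_length", None)
    data.pop("grid_nodes", None)
    doc = {
        "params": params,
        "grid": {"length": config.grid_length, "n_nodes": config.grid_nodes},
        "experiment": {
            **data,
            "t0_list": list(config.t0_list),
            "tp_list": list(config.tp_list),
            "sampling_ranges": {k: list(v) for k, v in config.sampling_ranges.items()},
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
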