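"""Plain-text (YAML) configuration for generator and pipeline runs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .errors import ParameterError
from .evaluate import DEFAULT_WINDOWS
from .preprocess import PreprocessParams
from .spectra import WavenumberGrid
from .synth import BandSpec, GeneratorConfig, HillParams


def generator_to_dict(config: GeneratorConfig) -> dict:
    return {
        "grid": {
            "lo": float(config.grid.values[0]),
            "hi": float(config.grid.values[-1]),
            "spacing": config.grid.spacing,
        },
        "bands": [asdict(b) for b in config.bands],
        "noise_sd": config.noise_sd,
        "baseline_offset_sd": config.baseline_offset_sd,
        "baseline_slope_sd": config.baseline_slope_sd,
        "scale_jitter_sd": config.scale_jitter_sd,
        "concentrations": list(config.concentrations),
        "n_replicates": config.n_replicates,
        "seed": config.seed,
    }


def generator_from_dict(data: dict) -> GeneratorConfig:
    kwargs = dict(data)
    grid_spec = kwargs.pop("grid", None)
    if grid_spec is not None:
        lo, hi, spacing = grid_spec["lo"], grid_spec["hi"], grid_spec["spacing"]
        n = int(round((hi - lo) / spacing)) + 1
        kwargs["grid"] = WavenumberGrid(lo + spacing * np.arange(n))
    bands = kwargs.pop("bands", None)
    if bands is not None:
        kwargs["bands"] = tuple(BandSpec(**b) for b in bands)
    try:
        return GeneratorConfig(**kwargs)
    except TypeError as exc:
        raise ParameterError(f"bad generator config: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one end-to-end pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    hill: HillParams = field(default_factory=HillParams)
    windows: tuple = DEFAULT_WINDOWS
    n_models: int = 20
    max_lv: int = 15
    k_folds: int = 7
    n_cells: int = 100
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed, generator=replace(self.generator, seed=seed))


def run_config_to_dict(config: RunConfig) -> dict:
    return {
        "generator": generator_to_dict(config.generator),
        "preprocess": asdict(config.preprocess),
        "hill": asdict(config.hill),
        "windows": [list(w) for w in config.windows],
        "n_models": config.n_models,
        "max_lv": config.max_lv,
        "k_folds": config.k_folds,
        "n_cells": config.n_cells,
        "seed": config.seed,
    }


def run_config_from_dict(data: dict) -> RunConfig:
    kwargs = dict(data)
    if "generator" in kwargs:
        kwargs["generator"] = generator_from_dict(kwargs["generator"])
    if "preprocess" in kwargs:
        kwargs["preprocess"] = PreprocessParams(**kwargs["preprocess"])
    if "hill" in kwargs:
        kwargs["hill"] = HillParams(**kwargs["hill"])
    if "windows" in kwargs:
        kwargs["windows"] = tuple(tuple(w) for w in kwargs["windows"])
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ParameterError(f"bad run config: {exc}") from exc


def save_run_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(run_config_to_dict(config), fh, sort_keys=False)


def load_run_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return run_config_from_dict(yaml.safe_load(fh))
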