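"""Scenario configuration: YAML round-trip and model construction.

A scenario file has three sections.  ``model`` describes the healthy
hierarchy, either with the constant-parameter shorthand (scalar ``eps``,
``d``, ``r1``, ``rate_ratio``) or with explicit per-compartment arrays
(``rates``, ``eps``, ``d``).  ``clone`` gives the compartment of origin,
the founder count and optional mutant parameter overrides.  ``run`` holds
execution settings (grid, seed, realization count, thresholds, output
directory).  Loading resolves every default, so the emitted resolved config
is explicit and round-trips unchanged.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import CloneInit, CompartmentModel, validate_model

__all__ = ["ScenarioConfig", "load_config", "save_config"]

_MODEL_DEFAULTS = {
    "K": 4,
    "N0": 1.0,
    "r0": 1.0,
    "influx_factor": 1.0,
    "eps": 0.85,
    "d": 0.0,
    "r1": 1.0,
    "rate_ratio": 1.26,
}

_CLONE_DEFAULTS = {"origin": 1, "initial_count": 1.0, "mutant": {}}

_RUN_DEFAULTS = {
    "horizon": 5.0,
    "n_times": 101,
    "seed": 1,
    "n_runs": 100,
    "K_sim": 4,
    "threshold": 1.0,
    "sample_level": 51.0,
    "detection_limit": 7.5,
    "reference_compartment": None,  # defaults to K at build time
    "extinction_compartment": None,  # defaults to origin + 2
    "output_dir": "clonecascade-out",
}


def _merged(defaults: dict, given: dict | None) -> dict:
    out = copy.deepcopy(defaults)
    out.update(given or {})
    return out


@dataclass
class ScenarioConfig:
    """Resolved configuration with explicit defaults in every section."""

    model: dict = field(default_factory=dict)
    clone: dict = field(default_factory=dict)
    run: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.model = _merged(_MODEL_DEFAULTS, self.model)
        self.clone = _merged(_CLONE_DEFAULTS, self.clone)
        self.run = _merged(_RUN_DEFAULTS, self.run)

    # -- builders ---------------------------------------------------------------

    def build_model(self) -> CompartmentModel:
        return validate_model(_model_from_section(self.model))

    def build_mutant_model(self) -> CompartmentModel:
        """Healthy model with the clone section's mutant overrides applied."""
        section = dict(self.model)
        section.update(self.clone.get("mutant") or {})
        return validate_model(_model_from_section(section))

    def build_clone(self) -> CloneInit:
        clone = CloneInit(
            origin=int(self.clone["origin"]),
            initial_count=float(self.clone["initial_count"]),
        )
        return clone.validate(int(self.model["K"]))

    def to_dict(self) -> dict:
        return {
            "model": copy.deepcopy(self.model),
            "clone": copy.deepcopy(self.clone),
            "run": copy.deepcopy(self.run),
        }


def _model_from_section(section: dict) -> CompartmentModel:
    K = int(section["K"])
    common = dict(
        stem_count=float(section["N0"]),
        stem_rate=float(section["r0"]),
        influx_factor=float(section["influx_factor"]),
    )
    if "rates" in section:
        return CompartmentModel(
            rates=np.asarray(section["rates"], dtype=float),
            diff_prob=_per_compartment(section["eps"], K),
            death_prob=_per_compartment(section["d"], K),
            **common,
        )
    if np.isscalar(section["eps"]) and np.isscalar(section["d"]):
        return CompartmentModel.constant(
            K,
            eps=float(section["eps"]),
            d=float(section["d"]),
            r1=float(section["r1"]),
            rate_ratio=float(section["rate_ratio"]),
            **common,
        )
    k = np.arange(K)
    return CompartmentModel(
        rates=float(section["r1"]) * float(section["rate_ratio"]) ** k,
        diff_prob=_per_compartment(section["eps"], K),
        death_prob=_per_compartment(section["d"], K),
        **common,
    )


def _per_compartment(value, K: int) -> np.ndarray:
    arr = np.full(K, float(value)) if np.isscalar(value) else np.asarray(value, float)
    if len(arr) != K:
        raise ValueError(f"per-compartment array has length {len(arr)}, expected {K}")
    return arr


def load_config(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"model", "clone", "run"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return ScenarioConfig(
        model=raw.get("model", {}), clone=raw.get("clone", {}), run=raw.get("run", {})
    )


def save_config(config: ScenarioConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
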