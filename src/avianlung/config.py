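"""Configuration loading, named parameter fixtures and run manifests.

Configs are flat JSON dicts keyed by the conventional parameter symbols
(``R_trachea``, ``C_tot``, ``gamma``, ...) with compliances in
mL/cmH2O and volumes in mL.  Three named presets ship with the package:

``default``
    duck parameter set (both valves effective),
``fig7a``
    inspiratory valving only (expiratory condition holds with equality),
``fig7b``
    expiratory valving only (inspiratory condition holds with equality).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

from .model import ModelParameters, ParameterError, resolve_parameters

__all__ = ["PRESETS", "load_config", "preset_config", "load_parameters", "RunManifest"]

PRESETS = ("default", "fig7a", "fig7b")


def preset_config(name: str) -> dict[str, float]:
    """Return a copy of a named shipped configuration."""
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; available: {PRESETS}")
    text = resources.files("avianlung.configs").joinpath(f"{name}.json").read_text()
    return json.loads(text)


def load_config(path) -> dict[str, float]:
    """Load and syntactically validate a JSON config file."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ParameterError("config must be a JSON object of parameter: value pairs")
    for key, value in raw.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ParameterError(f"config value for {key!r} must be a number, got {value!r}")
    return raw


def load_parameters(path=None, preset: str | None = None) -> ModelParameters:
    """Resolve parameters from a config file or a named preset."""
    if (path is None) == (preset is None):
        raise ParameterError("supply exactly one of a config path or a preset name")
    raw = preset_config(preset) if preset else load_config(path)
    return resolve_parameters(raw)


@dataclass
class RunManifest:
    """Record of a simulation run: inputs, solver settings and outputs."""

    parameters: dict[str, float]
    version: str
    dt: float
    tol: float
    max_breaths: int
    whole_animal: bool
    outputs: dict[str, str]
    breaths: int
    net_tracheal_volume: float
    converged: bool

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
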