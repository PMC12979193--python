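"""Run configuration: flat YAML with a strict, documented schema.

Unknown keys are rejected rather than ignored, so a typo in a scenario
file fails loudly instead of silently running defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]

DEFAULT_ADOPTION_LEVELS = (0.0, 0.1, 0.2, 0.5, 0.8)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on.

    ``parameter_table`` / ``nutrient_table`` of ``None`` select the
    shipped global parameters and the packaged isolate composition.
    """

    parameter_table: str | None = None
    adoption_levels: tuple[float, ...] = DEFAULT_ADOPTION_LEVELS
    nutrient_table: str | None = None
    portion_overrides: dict = field(default_factory=dict)
    econ_scenarios: tuple[str, ...] = ("negative", "neutral", "positive")
    published_compat: bool = True
    output_dir: str = "fishflow-out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.adoption_levels:
            raise ConfigError("adoption_levels must be non-empty")
        for x in self.adoption_levels:
            if not (0.0 <= x <= 1.0):
                raise ConfigError(f"adoption level {x!r} outside [0, 1]")
        from .economics import SCENARIOS

        unknown = [s for s in self.econ_scenarios if s not in SCENARIOS]
        if unknown:
            raise ConfigError(f"unknown econ scenarios {unknown}; choose from {sorted(SCENARIOS)}")
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")


_KEYS = {
    "parameter_table": str,
    "adoption_levels": list,
    "nutrient_table": str,
    "portion_overrides": dict,
    "econ_scenarios": list,
    "published_compat": bool,
    "output_dir": str,
    "seed": int,
}


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = sorted(set(raw) - set(_KEYS))
    if unknown:
        raise ConfigError(f"{path}: unknown keys {unknown}; allowed: {sorted(_KEYS)}")
    kwargs = {}
    for key, value in raw.items():
        if value is None:
            continue
        if key in ("adoption_levels",):
            kwargs[key] = tuple(float(v) for v in value)
        elif key == "econ_scenarios":
            kwargs[key] = tuple(str(v) for v in value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)
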