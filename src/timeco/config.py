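"""Run configuration: validated parameter files and shipped fixtures.

A config file (YAML or JSON) must spell out all eleven model parameters —
there are no silent defaults, so a missing rate cannot quietly fall back
to a baseline value.  Variant flags, a seed, and free-form command options
are optional.  The shipped fixtures (``killing_sweep`` ... ``runaway_ref``) encode the
reference parameter sets used throughout the analysis; interval-valued
entries (the swept parameters of each analysis) are recorded under
``options.ranges`` with a representative scalar in ``parameters``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .model import BASELINE_VARIANT, ModelParameters, ModelVariant

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "fixture_path",
    "load_fixture",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("killing_sweep", "fold_sweep", "basin_ref", "variant_ref", "regime_ref", "runaway_ref")

_TOP_LEVEL_KEYS = {"parameters", "variant", "seed", "options"}
_VARIANT_KEYS = {"pti_self_limitation", "pti_tumor_growth", "ati_dynamics"}


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one command run."""

    parameters: ModelParameters
    variant: ModelVariant = BASELINE_VARIANT
    seed: int = 0
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters.as_dict(),
            "variant": {
                "pti_self_limitation": self.variant.pti_self_limitation,
                "pti_tumor_growth": self.variant.pti_tumor_growth,
                "ati_dynamics": self.variant.ati_dynamics,
            },
            "seed": self.seed,
            "options": self.options,
        }


def _parse(data: dict, source: str) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    unknown = set(data) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigError(f"{source}: unknown keys {sorted(unknown)}")
    if "parameters" not in data:
        raise ConfigError(f"{source}: missing 'parameters' section")

    raw = dict(data["parameters"])
    names = set(ModelParameters.field_names())
    unknown = set(raw) - names
    if unknown:
        raise ConfigError(f"{source}: unknown parameters {sorted(unknown)}")
    missing = names - set(raw)
    if missing:
        raise ConfigError(
            f"{source}: missing parameters {sorted(missing)} "
            "(all eleven are mandatory)"
        )
    offenders = [k for k, v in raw.items() if not isinstance(v, (int, float))]
    offenders += [k for k, v in raw.items() if isinstance(v, (int, float)) and v < 0]
    if offenders:
        raise ConfigError(
            f"{source}: invalid (non-numeric or negative) parameters "
            f"{sorted(set(offenders))}"
        )
    try:
        params = ModelParameters(**raw)
    except ValueError as exc:
        raise ConfigError(f"{source}: {exc}") from exc

    vdata = data.get("variant", {}) or {}
    unknown = set(vdata) - _VARIANT_KEYS
    if unknown:
        raise ConfigError(f"{source}: unknown variant keys {sorted(unknown)}")
    try:
        variant = ModelVariant(**vdata)
    except ValueError as exc:
        raise ConfigError(f"{source}: {exc}") from exc

    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"{source}: seed must be an integer")
    options = data.get("options", {}) or {}
    if not isinstance(options, dict):
        raise ConfigError(f"{source}: options must be a mapping")
    return RunConfig(parameters=params, variant=variant, seed=seed, options=options)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    elif path.suffix == ".json":
        data = json.loads(text)
    else:
        raise ConfigError(f"unsupported config format: {path.suffix!r}")
    return _parse(data, str(path))


def save_config(config: RunConfig, path) -> None:
    """Write a configuration back to YAML or JSON (lossless round trip)."""
    path = Path(path)
    data = config.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        raise ConfigError(f"unsupported config format: {path.suffix!r}")


def fixture_path(name: str) -> Path:
    """Filesystem path of a shipped parameter fixture (``killing_sweep`` .. ``runaway_ref``)."""
    if name not in FIXTURE_NAMES:
        raise ConfigError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return Path(str(resources.files("timeco") / "fixtures" / f"{name}.yaml"))


def load_fixture(name: str) -> RunConfig:
    """Load one of the shipped parameter-set fixtures."""
    return load_config(fixture_path(name))
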