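"""Configuration loading: model constants, absorption class parameters,
the brand registry and the HbA1c regression choice.

Defaults ship inside the package (``data/model_defaults.yaml`` and
``data/insulin_registry.tsv``); a user YAML file with the same structure
overrides individual keys.  Every constant is validated against its type
invariants when the config is constructed, so an invalid override (a
negative volume, a non-monotone NHGB grid) is rejected at load time.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .model import ModelConstants, ModelError
from .profiles import (
    AbsorptionClass,
    AbsorptionClassParams,
    AbsorptionTable,
    InsulinPreparation,
    ProfileError,
    build_all_tables,
    load_registry,
)

__all__ = ["SimulatorConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class SimulatorConfig:
    constants: ModelConstants
    class_params: dict[AbsorptionClass, AbsorptionClassParams]
    registry: dict[str, InsulinPreparation]
    hba1c_model: str = "classic"
    _tables: dict[str, AbsorptionTable] | None = field(default=None, repr=False)

    def tables(self) -> dict[str, AbsorptionTable]:
        """The nine-member lookup-table set, built once and cached."""
        if self._tables is None:
            self._tables = build_all_tables(self.class_params, self.constants)
        return self._tables


def _read_yaml(path: Path) -> dict:
    data = yaml.safe_load(path.read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return data


def load_config(path: Path | str | None = None) -> SimulatorConfig:
    """Load defaults, optionally merged with overrides from ``path``.

    Raises ConfigError naming the offending key for any constant that
    violates its invariants.
    """
    defaults = yaml.safe_load(
        (importlib.resources.files("glucosim.data") / "model_defaults.yaml").read_text())
    merged = dict(defaults)
    if path is not None:
        user = _read_yaml(Path(path))
        for key, value in user.items():
            if key in ("class_params", "constants") and isinstance(value, dict):
                section = dict(merged.get(key) or {})
                section.update(value)
                merged[key] = section
            else:
                merged[key] = value

    known = {"hba1c_model", "class_params", "constants"}
    unknown = set(merged) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")

    hba1c_model = merged.get("hba1c_model", "classic")
    if hba1c_model not in ("classic", "eag"):
        raise ConfigError(f"hba1c_model: unknown regression {hba1c_model!r}")

    valid_fields = {f.name for f in fields(ModelConstants)}
    overrides = merged.get("constants") or {}
    for key in overrides:
        if key not in valid_fields:
            raise ConfigError(f"constants.{key}: unknown model constant")
    try:
        constants = ModelConstants(**overrides)
    except (ModelError, TypeError) as exc:
        raise ConfigError(f"constants: {exc}") from exc

    class_params: dict[AbsorptionClass, AbsorptionClassParams] = {}
    for cls_name, spec in (merged.get("class_params") or {}).items():
        try:
            cls = AbsorptionClass(cls_name)
            class_params[cls] = AbsorptionClassParams(class_id=cls, **spec)
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"class_params.{cls_name}: {exc}") from exc
    missing = set(AbsorptionClass) - set(class_params)
    if missing:
        raise ConfigError(
            f"class_params missing for: {', '.join(c.value for c in sorted(missing))}")

    return SimulatorConfig(
        constants=constants,
        class_params=class_params,
        registry=load_registry(),
        hba1c_model=hba1c_model,
    )
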