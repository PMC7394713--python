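"""Flat key-value configuration files (TOML or YAML) for the CLI.

A config file may contain top-level keys or ``[preprocess]`` / ``[contour]``
/ ``[scene]`` sections; section-less keys are matched to the dataclass that
declares them.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

import yaml

from .counting import ContourConfig
from .errors import FormatError
from .preprocess import PreprocessConfig
from .synth import SceneSpec

__all__ = ["load_config", "build_configs", "build_scene_spec"]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".toml":
        return tomllib.loads(text)
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    raise FormatError(f"unsupported config format: {path.suffix!r} (use .toml or .yaml)")


def _section(raw: dict, name: str, cls) -> dict:
    fields = {f.name for f in dataclasses.fields(cls)}
    out = {k: v for k, v in raw.items() if k in fields}
    sec = raw.get(name, {})
    if not isinstance(sec, dict):
        raise FormatError(f"config section [{name}] must be a table")
    unknown = set(sec) - fields
    if unknown:
        raise FormatError(f"unknown keys in [{name}]: {sorted(unknown)}")
    out.update(sec)
    return out


def build_configs(raw: dict) -> tuple[PreprocessConfig, ContourConfig]:
    pre = PreprocessConfig(**_section(raw, "preprocess", PreprocessConfig))
    contour = ContourConfig(**_section(raw, "contour", ContourConfig))
    return pre, contour


def build_scene_spec(raw: dict, **overrides) -> SceneSpec:
    kwargs = _section(raw, "scene", SceneSpec)
    kwargs.update(overrides)
    return SceneSpec(**kwargs)
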