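"""Structured (YAML) configuration loading with strict key checking."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from pathlib import Path

import yaml

from .emulator import EmulatorConfig
from .errors import ArgumentError, FormatError
from .regressors import RegressorSpec
from .sampling import SamplingPlan
from .synth import SceneConfig


def load_yaml(path: str | os.PathLike) -> dict:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise FormatError(f"malformed YAML in {path}: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path} must contain a mapping at top level")
    return data


def _build(cls, data: dict, context: str):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - field_names)
    if unknown:
        raise ArgumentError(f"unknown {context} key(s): {', '.join(unknown)}")
    kwargs = dict(data)
    for key in ("input_grid", "output_grid", "sif_amplitude_range",
                "lambda_grid", "sigma_grid", "sigma_multipliers", "scene_quotas"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def scene_config(data: dict) -> SceneConfig:
    return _build(SceneConfig, data, "scene")


def sampling_plan(data: dict) -> SamplingPlan:
    return _build(SamplingPlan, data, "sampling")


def emulator_config(data: dict) -> EmulatorConfig:
    data = dict(data)
    reg = data.pop("regressor", None)
    config = _build(EmulatorConfig, data, "emulator")
    if reg is not None:
        config = dataclasses.replace(config,
                                     regressor=_build(RegressorSpec, reg, "regressor"))
    return config


def config_hash(config) -> str:
    """Short stable digest of a resolved config, for artifact metadata."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write via a temp file in the same directory, then rename."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
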