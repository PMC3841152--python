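"""Run configuration, validation and reproducibility plumbing.

A run is fully described by a :class:`RunConfig`: model coefficients,
stimulus, noise process, experiment protocol, reaching-model parameters and
output location.  Configs load from a YAML file with CLI flags taking
precedence; unknown keys and out-of-range values are reported together in a
single validation error.  Every command writes a JSON provenance sidecar
(resolved config + seed + package version) from which the run can be
repeated byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .dynamics import SRParams
from .reaching import RLConfig
from .signals import KickStimulus, NoiseSpec


class ConfigError(ValueError):
    """Raised with the full list of offending configuration keys."""


@dataclass(frozen=True)
class ExperimentSection:
    n_trials: int = 1000
    seed: int = 0
    win: int | None = None  # default by noise kind: 9 white, 15 colored
    T_list: tuple[int, ...] | None = None  # default by noise kind
    D_start: float = 0.0
    D_stop: float = 10.0
    D_step: float = 0.2
    ft_tol: float = 0.1

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError(f"experiment.n_trials must be >= 1, got {self.n_trials}")
        if self.D_step <= 0 or self.D_stop < self.D_start:
            raise ValueError("experiment D grid must be increasing with positive step")
        if self.win is not None and (self.win < 1 or self.win % 2 == 0):
            raise ValueError(f"experiment.win must be odd and >= 1, got {self.win}")

    def D_grid(self) -> np.ndarray:
        return np.round(np.arange(self.D_start, self.D_stop + 1e-9, self.D_step), 10)


@dataclass(frozen=True)
class OutputSection:
    dir: str = "runs"
    float_format: str = "%.6g"


@dataclass(frozen=True)
class RunConfig:
    model: SRParams = field(default_factory=SRParams)
    stimulus: KickStimulus = field(default_factory=KickStimulus)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    experiment: ExperimentSection = field(default_factory=ExperimentSection)
    reaching: RLConfig = field(default_factory=RLConfig)
    output: OutputSection = field(default_factory=OutputSection)

    def resolved(self) -> dict[str, Any]:
        """Plain-dict form of the fully resolved configuration."""
        return {
            sec.name: dataclasses.asdict(getattr(self, sec.name))
            for sec in dataclasses.fields(self)
        }


_SECTIONS = {
    "model": SRParams,
    "stimulus": KickStimulus,
    "noise": NoiseSpec,
    "experiment": ExperimentSection,
    "reaching": RLConfig,
    "output": OutputSection,
}


def _build_section(name: str, cls, data: dict, errors: list[str]):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in known:
            errors.append(f"unknown key {name}.{key}")
            continue
        if isinstance(val, list):
            val = tuple(tuple(v) if isinstance(v, list) else v for v in val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        errors.append(f"{name}: {exc}")
        return cls()


def load_config(
    path: str | Path | None = None,
    overrides: dict[str, dict[str, Any]] | None = None,
) -> RunConfig:
    """Build a validated RunConfig from a YAML file and/or override dict.

    ``overrides`` maps section name to field updates and wins over file
    values (the CLI flag precedence rule).  All unknown keys and invalid
    values are collected and reported in one :class:`ConfigError`.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data = loaded
    errors: list[str] = []
    for section in data:
        if section not in _SECTIONS:
            errors.append(f"unknown section {section!r}")
    merged: dict[str, dict[str, Any]] = {
        name: dict(data.get(name, {})) for name in _SECTIONS
    }
    for name, upd in (overrides or {}).items():
        if name not in _SECTIONS:
            errors.append(f"unknown section {name!r}")
            continue
        merged[name].update({k: v for k, v in upd.items() if v is not None})
    sections = {
        name: _build_section(name, cls, merged.get(name, {}), errors)
        for name, cls in _SECTIONS.items()
    }
    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(errors))
    return RunConfig(**sections)


def atomic_write_text(path: Path, text: str) -> None:
    """Write via a temp file and atomic rename: no partial output on failure."""
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_provenance(out_dir: Path, command: str, cfg: RunConfig, seed: int) -> Path:
    from . import __version__

    record = {
        "command": command,
        "seed": int(seed),
        "version": __version__,
        "config": cfg.resolved(),
    }
    path = Path(out_dir) / f"{command}.provenance.json"
    atomic_write_text(path, json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path
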