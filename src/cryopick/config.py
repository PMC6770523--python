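"""One config object for the whole pipeline.

Every stage's knobs live in a single :class:`PipelineConfig` so one YAML
snapshot fully reproduces a run.  Sections mirror the stages: ``preprocess``,
``slic``, ``cluster``, ``clean``, ``pick``, ``synthetic``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .mask import CleaningParams, min_area_for_radius
from .preprocess import PreprocessConfig
from .superpixel import SlicParams

__all__ = ["ClusterConfig", "PickConfig", "PipelineConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class ClusterConfig:
    """Clustering stage: method name plus the knobs shared by the clusterers."""

    method: str = "sp_ibc"
    interval_size: float = 0.15
    fuzzifier: float = 2.0
    tol: float = 1e-5
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.interval_size <= 0:
            raise ParameterError("cluster.interval_size must be positive")
        if self.fuzzifier <= 1:
            raise ParameterError("cluster.fuzzifier must be > 1")
        if self.connectivity not in (4, 8):
            raise ParameterError("cluster.connectivity must be 4 or 8")


@dataclass(frozen=True)
class PickConfig:
    """Picking stage: bounding-box mode and the cleaning policy.

    ``clean_after_super`` forces mask cleaning even for super-clustering,
    whose masks normally need no post-processing; base methods always clean.
    """

    box_mode: str = "tight"
    box_size: int | None = None
    clean_after_super: bool = False

    def __post_init__(self) -> None:
        if self.box_mode not in ("tight", "fixed"):
            raise ParameterError("pick.box_mode must be 'tight' or 'fixed'")
        if self.box_mode == "fixed" and (self.box_size is None or self.box_size < 1):
            raise ParameterError("pick.box_mode='fixed' requires a positive pick.box_size")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters plus the one physically meaningful scale,
    ``expected_particle_radius`` (pixels), which seeds the default minimum
    component area and the default evaluation match tolerance."""

    expected_particle_radius: float = 15.0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    slic: SlicParams = field(default_factory=SlicParams)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    clean: CleaningParams | None = None
    pick: PickConfig = field(default_factory=PickConfig)

    def cleaning_params(self) -> CleaningParams:
        if self.clean is not None:
            return self.clean
        return CleaningParams(min_area=min_area_for_radius(self.expected_particle_radius))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.clean is None:
            d.pop("clean")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "slic": SlicParams,
    "cluster": ClusterConfig,
    "clean": CleaningParams,
    "pick": PickConfig,
}


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ParameterError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        if k == "steps_enabled" and isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from an optional YAML file plus overrides.

    Precedence: ``overrides`` (CLI flags) > file values > built-in defaults.
    ``overrides`` uses dotted keys, e.g. ``{"cluster.interval_size": 0.2}``.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ParameterError(f"config file {path} must hold a mapping")
        data = loaded
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if "." in key:
            section, name = key.split(".", 1)
            data.setdefault(section, {})[name] = value
        else:
            data[key] = value
    kwargs: dict = {}
    if "expected_particle_radius" in data:
        kwargs["expected_particle_radius"] = float(data.pop("expected_particle_radius"))
    data.pop("synthetic", None)  # consumed by the simulate command, not here
    for section, payload in data.items():
        if section not in _SECTIONS:
            raise ParameterError(f"unknown config section {section!r}")
        if not isinstance(payload, dict):
            raise ParameterError(f"config section {section!r} must be a mapping")
        kwargs[section] = _build(_SECTIONS[section], payload)
    return PipelineConfig(**kwargs)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
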