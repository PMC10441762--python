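"""YAML-backed configuration for the end-to-end pipeline.

Each section maps onto the dataclass config of one stage; unknown keys are
rejected so typos fail before any compute.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .imaging import ImagingConfig
from .sc import QCThresholds
from .simulate import CountsSimConfig, CtSimConfig, ImageSimConfig

__all__ = ["PipelineConfig", "build_dataclass", "load_pipeline_config"]

_TUPLE_FIELDS = {"radius_range_px", "nucleus_radius_range_px", "genes", "gene_symbols", "de_genes"}


def build_dataclass(cls, data: Mapping[str, Any] | None, context: str = ""):
    """Instantiate a config dataclass from a mapping, rejecting unknown keys."""
    data = dict(data or {})
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in {context or cls.__name__}: {sorted(unknown)}")
    for key in list(data):
        if key in _TUPLE_FIELDS and isinstance(data[key], list):
            data[key] = tuple(tuple(v) if isinstance(v, list) else v for v in data[key])
    return cls(**data)


@dataclass
class PipelineConfig:
    """Configuration of the synthetic end-to-end demonstration run."""

    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    image_sim: ImageSimConfig = field(default_factory=ImageSimConfig)
    counts_sim: CountsSimConfig = field(default_factory=CountsSimConfig)
    ct_sim: CtSimConfig = field(default_factory=CtSimConfig)
    n_fields: int = 3
    samples_per_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fields <= 0 or self.samples_per_group <= 0:
            raise ValueError("n_fields and samples_per_group must be positive")


_SECTION_TYPES = {
    "imaging": ImagingConfig,
    "qc": QCThresholds,
    "image_sim": ImageSimConfig,
    "counts_sim": CountsSimConfig,
    "ct_sim": CtSimConfig,
}


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline YAML; every section optional, unknown sections rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level of the pipeline config must be a mapping")
    known = set(_SECTION_TYPES) | {"n_fields", "samples_per_group", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config sections {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            kwargs[name] = build_dataclass(cls, raw[name], context=name)
    for scalar in ("n_fields", "samples_per_group", "seed"):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
    return PipelineConfig(**kwargs)
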