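"""Pipeline configuration: one YAML/JSON file driving every stage.

The file mirrors the parameter dataclasses one-to-one:

.. code-block:: yaml

    scan:      {n_images: 9, step_mm: 31.25, image_w: 640, image_h: 480, motion_axis: x}
    grouping:  {ks: 1.0, kp: 1.0, p_threshold: 0.016667, max_gap: 2, ...}
    camera:    {a: 381.0, b: -0.95, phi_x: 0.48869, phi_y: 0.37941, pm_x: 320, pm_y: 240}
    simulator: {n_leaves: 18, length_range: [55, 115], height_range: [90, 340], ...}

All blocks are optional; omitted values take the defaults.  YAML is a
superset of JSON here, so `.json` configs load through the same path.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .geometry import CameraModel
from .grouping import GroupingParams

__all__ = ["ScanConfig", "SimulatorConfig", "PipelineConfig",
           "load_config", "dump_config"]


@dataclass(frozen=True)
class ScanConfig:
    n_images: int = 9
    step_mm: float = 31.25
    image_w: int = 640
    image_h: int = 480
    motion_axis: str = "x"


@dataclass(frozen=True)
class SimulatorConfig:
    n_leaves: int = 18
    length_range: tuple[float, float] = (55.0, 115.0)
    height_range: tuple[float, float] = (90.0, 340.0)
    sigma_px: float = 0.0
    detect_prob: float = 1.0
    fp_rate: float = 0.0
    occlusion: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    scan: ScanConfig = field(default_factory=ScanConfig)
    grouping: GroupingParams = field(default_factory=GroupingParams)
    camera: CameraModel = field(default_factory=CameraModel)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    log_level: str = "INFO"


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config; raises ValueError on unknown keys or values
    violating the owning type's invariants."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return PipelineConfig(
        scan=_build(ScanConfig, doc.get("scan", {})),
        grouping=_build(GroupingParams, doc.get("grouping", {})),
        camera=_build(CameraModel, doc.get("camera", {})),
        simulator=_build(SimulatorConfig, doc.get("simulator", {})),
        log_level=doc.get("log_level", "INFO"),
    )


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a config so that load(dump(c)) == c."""
    doc = {
        "scan": asdict(config.scan),
        "grouping": asdict(config.grouping),
        "camera": asdict(config.camera),
        "simulator": asdict(config.simulator),
        "log_level": config.log_level,
    }
    for block in doc.values():
        if isinstance(block, dict):
            for k, v in block.items():
                if isinstance(v, tuple):
                    block[k] = list(v)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
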