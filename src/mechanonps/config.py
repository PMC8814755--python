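"""Pipeline configuration: typed parameter blocks, YAML round-tripping with
strict (unknown keys rejected) parsing, and a content hash carried into
every output table so results are traceable to the exact parameters."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import ChannelGeometry, Segment
from .simulate import AcquisitionConfig

__all__ = [
    "ConfigError",
    "PreprocessParams",
    "DetectionParams",
    "FitParams",
    "StatsParams",
    "SimulationParams",
    "PipelineConfig",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessParams:
    filter_window: int = 20  # samples at the raw rate (0.4 ms at 50 kHz)
    downsample_factor: int = 20  # 50 kHz -> 2.5 kHz
    baseline_window_s: float = 2.0


@dataclass(frozen=True)
class DetectionParams:
    k_threshold: float = 5.0  # robust-sigma units
    abs_threshold: float = 1e-9  # A, fallback when the noise scale is zero
    merge_horizon_s: float = 0.05  # node length / minimum plausible velocity
    min_run_s: float = 0.002
    min_gap_samples: int = 2
    edge_trim_frac: float = 0.10


@dataclass(frozen=True)
class FitParams:
    min_points: int = 4
    tau_band: tuple[float, float] = (0.005, 2.0)


@dataclass(frozen=True)
class StatsParams:
    alpha: float = 0.05
    adjustment: str = "auto"  # auto | none | bonferroni | tukey
    metrics: tuple[str, ...] = ("wcdi", "tau_ms")


@dataclass(frozen=True)
class SimulationParams:
    contraction_depth_factor: float = 3.0


@dataclass(frozen=True)
class PipelineConfig:
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    fit: FitParams = field(default_factory=FitParams)
    stats: StatsParams = field(default_factory=StatsParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    seed: int = 0

    def to_dict(self) -> dict:
        geo = self.geometry
        return {
            "geometry": {
                "h_channel_m": geo.h_channel,
                "sizing_segment": _seg_dict(geo.sizing_segment),
                "contraction_segment": _seg_dict(geo.contraction_segment),
                "node": _seg_dict(geo.node),
                "recovery_segments": [_seg_dict(s) for s in geo.recovery_segments],
            },
            "acquisition": dataclasses.asdict(self.acquisition),
            "preprocess": dataclasses.asdict(self.preprocess),
            "detection": dataclasses.asdict(self.detection),
            "fit": {
                "min_points": self.fit.min_points,
                "tau_band": list(self.fit.tau_band),
            },
            "stats": {
                "alpha": self.stats.alpha,
                "adjustment": self.stats.adjustment,
                "metrics": list(self.stats.metrics),
            },
            "simulation": dataclasses.asdict(self.simulation),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {
            "geometry", "acquisition", "preprocess", "detection",
            "fit", "stats", "simulation", "seed",
        }
        _reject_unknown(data, known, "top level")
        kwargs: dict = {}
        if "geometry" in data:
            g = dict(data["geometry"])
            gknown = {
                "h_channel_m", "sizing_segment", "contraction_segment",
                "node", "recovery_segments",
            }
            _reject_unknown(g, gknown, "geometry")
            kwargs["geometry"] = ChannelGeometry(
                h_channel=g.get("h_channel_m", 12.9e-6),
                sizing_segment=_seg_from(g.get("sizing_segment", {"width_m": 13e-6, "length_m": 800e-6})),
                contraction_segment=_seg_from(g.get("contraction_segment", {"width_m": 7e-6, "length_m": 2000e-6})),
                node=_seg_from(g.get("node", {"width_m": 85e-6, "length_m": 50e-6})),
                recovery_segments=tuple(
                    _seg_from(s)
                    for s in g.get(
                        "recovery_segments",
                        [{"width_m": 13e-6, "length_m": 290e-6}] * 10,
                    )
                ),
            )
        for key, klass in [
            ("acquisition", AcquisitionConfig),
            ("preprocess", PreprocessParams),
            ("detection", DetectionParams),
            ("simulation", SimulationParams),
        ]:
            if key in data:
                block = dict(data[key])
                fields = {f.name for f in dataclasses.fields(klass)}
                _reject_unknown(block, fields, key)
                kwargs[key] = klass(**block)
        if "fit" in data:
            block = dict(data["fit"])
            _reject_unknown(block, {"min_points", "tau_band"}, "fit")
            if "tau_band" in block:
                block["tau_band"] = tuple(block["tau_band"])
            kwargs["fit"] = FitParams(**block)
        if "stats" in data:
            block = dict(data["stats"])
            _reject_unknown(block, {"alpha", "adjustment", "metrics"}, "stats")
            if "metrics" in block:
                block["metrics"] = tuple(block["metrics"])
            kwargs["stats"] = StatsParams(**block)
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _seg_dict(seg: Segment) -> dict:
    return {"width_m": seg.width, "length_m": seg.length}


def _seg_from(d: dict) -> Segment:
    d = dict(d)
    _reject_unknown(d, {"width_m", "length_m"}, "segment")
    return Segment(d["width_m"], d["length_m"])


def _reject_unknown(block: dict, known: set[str], where: str) -> None:
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"unknown config keys in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=True)
    return path
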