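"""Pipeline configuration: one structured-text file, full defaults.

Every default equals the operating point of the modeled system (0.36°
resolution, 90° FOV, 5 Hz output, 0.48 m·s⁻¹ travel, 1.52 m sensor
spacing, 1728-plot layout), so a bare command reproduces it.  One master
seed fans out to named streams inside the simulator.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .field_simulator import PlatformTrack
from .sweep_geometry import SensorGeometry
from .trait_extraction import ExtractionParams


@dataclass
class LayoutConfig:
    n_cols: int = 72
    n_ranges: int = 24
    plot_width: float = 1.52
    plot_length: float = 3.66
    alley: float = 0.76
    origin_easting: float = 409200.0
    origin_northing: float = 3658200.0
    n_accessions: int = 248
    n_checks: int = 4
    check_reps: int = 10
    blocks: int = 6


@dataclass
class GeometryConfig:
    angular_resolution: float = 0.36
    fov: float = 90.0
    mount_height_mm: float = 1682.0


@dataclass
class TrackConfig:
    speed: float = 0.48
    output_rate_hz: float = 5.0
    sensor_offset_m: float = 0.76
    mount_height_m: float = 2.23


@dataclass
class ExtractionConfig:
    h_min_mm: float = 50.0
    soil_tol_mm: float = 50.0
    min_soil_points: int = 5
    window_deg: float = 10.0
    lateral_halfwidth_mm: float = 760.0


@dataclass
class PipelineConfig:
    seed: int = 1
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    track: TrackConfig = field(default_factory=TrackConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    layout: LayoutConfig = field(default_factory=LayoutConfig)

    # adapters -------------------------------------------------------------

    def sensor_geometry(self) -> SensorGeometry:
        g = self.geometry
        return SensorGeometry(
            angular_resolution=g.angular_resolution, fov=g.fov,
            mount_height_mm=g.mount_height_mm,
            output_rate_hz=self.track.output_rate_hz,
        )

    def platform_track(self) -> PlatformTrack:
        t = self.track
        return PlatformTrack(
            speed=t.speed, output_rate_hz=t.output_rate_hz,
            sensor_offset_m=t.sensor_offset_m,
            mount_height_m=t.mount_height_m,
        )

    def extraction_params(self) -> ExtractionParams:
        e = self.extraction
        return ExtractionParams(
            h_min_mm=e.h_min_mm, soil_tol_mm=e.soil_tol_mm,
            min_soil_points=e.min_soil_points, window_deg=e.window_deg,
            lateral_halfwidth_mm=e.lateral_halfwidth_mm,
        )

    # serialization --------------------------------------------------------

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for section, klass in (("geometry", GeometryConfig),
                               ("track", TrackConfig),
                               ("extraction", ExtractionConfig),
                               ("layout", LayoutConfig)):
            if section in data:
                setattr(cfg, section, klass(**data[section]))
        if "seed" in data:
            cfg.seed = int(data["seed"])
        return cfg
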