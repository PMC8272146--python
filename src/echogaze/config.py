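"""Run configuration: a structured, strictly-validated YAML file.

One config describes a full pipeline run (geometry, protocol, burst/noise,
features, regression, seed, output directory).  Unknown keys are rejected,
every section has the bench defaults, and a short hash of the resolved
config is recorded in every output sidecar so artifacts are traceable to
the exact settings and seed that produced them.  Units follow the package
convention: millimetres, degrees, microseconds (Hz for rates).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .bench import BurstSpec, NoiseSpec, ProtocolSpec
from .features import FeatureSpec
from .geometry import EyeModel, OccluderSpec, RingSpec
from .regression import GBRTConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EyeConfig(_Strict):
    sclera_radius_mm: float = 11.925
    cornea_radius_mm: float = 7.8
    cornea_offset_mm: float = 5.6

    def build(self) -> EyeModel:
        return EyeModel(
            sclera_radius=self.sclera_radius_mm,
            cornea_radius=self.cornea_radius_mm,
            cornea_offset=self.cornea_offset_mm,
        )


class RingConfig(_Strict):
    radius_mm: float = 20.0
    standoff_mm: float = 25.0
    positions_deg: list[float] = Field(default_factory=lambda: list(range(-90, 91, 10)))
    receiver_deg: float = 180.0
    aperture_radius_mm: float = 0.5
    acceptance_half_angle_deg: float = 15.0

    def build(self) -> RingSpec:
        return RingSpec(
            radius_mm=self.radius_mm,
            standoff_mm=self.standoff_mm,
            positions_deg=tuple(self.positions_deg),
            receiver_deg=self.receiver_deg,
            aperture_radius_mm=self.aperture_radius_mm,
            acceptance_half_angle_deg=self.acceptance_half_angle_deg,
        )


class OccluderConfig(_Strict):
    enabled: bool = True
    standoff_mm: float = 2.0
    aperture_half_width_mm: float = 5.5
    aperture_half_height_mm: float = 4.5
    aperture_center_y_mm: float = 1.0
    outer_radius_mm: float = 40.0
    wedge_azimuth_deg: float = 20.0
    wedge_extent_deg: float = 30.0
    wedge_radial_mm: float = 4.0
    wedge_protrusion_mm: float = 2.5

    def build(self) -> Optional[OccluderSpec]:
        if not self.enabled:
            return None
        return OccluderSpec(
            standoff_mm=self.standoff_mm,
            aperture_half_width_mm=self.aperture_half_width_mm,
            aperture_half_height_mm=self.aperture_half_height_mm,
            aperture_center_y_mm=self.aperture_center_y_mm,
            outer_radius_mm=self.outer_radius_mm,
            wedge_azimuth_deg=self.wedge_azimuth_deg,
            wedge_extent_deg=self.wedge_extent_deg,
            wedge_radial_mm=self.wedge_radial_mm,
            wedge_protrusion_mm=self.wedge_protrusion_mm,
        )


class GeometryConfig(_Strict):
    eye: EyeConfig = Field(default_factory=EyeConfig)
    ring: RingConfig = Field(default_factory=RingConfig)
    occluder: OccluderConfig = Field(default_factory=OccluderConfig)
    gaze_range_deg: float = 35.0


class BurstConfig(_Strict):
    carrier_hz: float = 1.74e6
    n_cycles: int = 7
    repetition_hz: float = 2000.0
    sample_rate_hz: float = 80e6
    duration_us: float = 300.0

    def build(self) -> BurstSpec:
        return BurstSpec(
            carrier_hz=self.carrier_hz,
            n_cycles=self.n_cycles,
            repetition_hz=self.repetition_hz,
            sample_rate_hz=self.sample_rate_hz,
            duration_us=self.duration_us,
        )


class NoiseConfig(_Strict):
    additive_std: float = 0.35
    session_gain_std: float = 0.05
    session_jitter_us: float = 0.2

    def build(self) -> NoiseSpec:
        return NoiseSpec(
            additive_std=self.additive_std,
            session_gain_std=self.session_gain_std,
            session_jitter_us=self.session_jitter_us,
        )


class ProtocolConfig(_Strict):
    #: None selects the default 36-pose grid {-5,-3,-1,1,3,5}^2
    gaze_grid_deg: Optional[list[tuple[float, float]]] = None
    gaze_step_deg: Optional[float] = None  # e.g. 1.0 for the 11x11 fine grid
    gaze_limit_deg: float = 5.0
    repeats: int = 50
    sessions: int = 9
    group_size: int = 10

    def grid(self) -> tuple[tuple[float, float], ...]:
        if self.gaze_grid_deg is not None:
            return tuple((float(t), float(p)) for t, p in self.gaze_grid_deg)
        if self.gaze_step_deg is not None:
            import numpy as np

            vals = np.arange(-self.gaze_limit_deg, self.gaze_limit_deg + 1e-9, self.gaze_step_deg)
            return tuple((float(t), float(p)) for t in vals for p in vals)
        from .bench import default_gaze_grid

        return default_gaze_grid()

    def build(self, ring: RingConfig) -> ProtocolSpec:
        return ProtocolSpec(
            gaze_grid_deg=self.grid(),
            tx_positions_deg=tuple(ring.positions_deg),
            repeats=self.repeats,
            sessions=self.sessions,
            group_size=self.group_size,
            receiver_deg=ring.receiver_deg,
        )


class FeaturesConfig(_Strict):
    band_low_hz: float = 1.6e6
    band_high_hz: float = 1.9e6
    filter_order: int = 4
    window_us: float = 45.0
    zero_phase: bool = True

    def build(self, group_size: int) -> FeatureSpec:
        return FeatureSpec(
            band_low_hz=self.band_low_hz,
            band_high_hz=self.band_high_hz,
            filter_order=self.filter_order,
            window_us=self.window_us,
            group_size=group_size,
            zero_phase=self.zero_phase,
        )


class RegressionConfig(_Strict):
    learning_rate: float = 0.0825
    max_depth: int = 5
    n_estimators: int = 750
    min_child_weight: float = 23.0
    reg_alpha: float = 0.01
    reg_lambda: float = 1.0
    folds: int = 5

    def build(self) -> GBRTConfig:
        return GBRTConfig(
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            n_estimators=self.n_estimators,
            min_child_weight=self.min_child_weight,
            reg_alpha=self.reg_alpha,
            reg_lambda=self.reg_lambda,
        )


class RunConfig(_Strict):
    seed: int = 0
    output_dir: str = "runs/echogaze"
    fast: bool = True
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    burst: BurstConfig = Field(default_factory=BurstConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    features: FeaturesConfig = Field(default_factory=FeaturesConfig)
    regression: RegressionConfig = Field(default_factory=RegressionConfig)

    def resolved(self) -> dict:
        return self.model_dump(mode="json")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.resolved(), sort_keys=True))
        return path


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run config; missing path gives the full default config."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the resolved configuration."""
    blob = json.dumps(config.resolved(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
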