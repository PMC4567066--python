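"""Pipeline configuration: every tunable the detection chain exposes.

The underlying study reports that its thresholds existed ("an experimental
threshold ... was applied") without publishing values, so every cutoff,
threshold and window here is an explicit config default that can be
overridden from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SignalConfig:
    """Filtering and derived-signal parameters.

    cutoff_detect_hz : low-pass for the detection-band acceleration signals.
    cutoff_gravity_hz : low-pass isolating the gravity/orientation component.
    cutoff_pressure_hz : low-pass on the barometric signal.
    intensity_window_s : centred window of the moving-dispersion intensity.
    metres_per_hpa : barometric altimetry constant near sea level.
    upright_axis : device axis aligned with the trunk when upright.
    """

    cutoff_detect_hz: float = 5.0
    cutoff_gravity_hz: float = 0.25
    cutoff_pressure_hz: float = 1.0
    filter_order: int = 4
    intensity_window_s: float = 1.0
    metres_per_hpa: float = 8.43
    upright_axis: str = "z"


@dataclass
class DetectorConfig:
    # active/inactive segmentation
    active_threshold_g: float = 0.03
    active_min_bout_s: float = 1.0
    active_merge_gap_s: float = 2.0
    # walking (step peaks in the acceleration norm)
    walk_min_peaks: int = 2          # walking is defined from 2 steps up
    walk_min_peak_height_g: float = 0.10   # above the 1 g gravity level
    walk_peak_interval_min_s: float = 0.35
    walk_peak_interval_max_s: float = 1.4
    # lying (sustained tilt away from upright)
    lying_angle_threshold_deg: float = 60.0
    lying_min_duration_s: float = 10.0
    # sit/stand transfer candidates
    transfer_window_s: float = 4.0         # candidate window, within 2–6 s
    transfer_peak_height_g: float = 0.12   # band-signal extremum to propose
    transfer_min_altitude_range_m: float = 0.15
    transfer_min_tilt_range_deg: float = 4.0
    transfer_min_separation_s: float = 1.5
    model_path: str | None = None          # default: packaged fixture


@dataclass
class PipelineConfig:
    signal: SignalConfig = field(default_factory=SignalConfig)
    detectors: DetectorConfig = field(default_factory=DetectorConfig)
    clock_offset_s: float = 0.0   # video-vs-sensor clock offset, if known

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sig = SignalConfig(**d.get("signal", {}))
        det = DetectorConfig(**d.get("detectors", {}))
        return cls(signal=sig, detectors=det,
                   clock_offset_s=d.get("clock_offset_s", 0.0))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
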