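"""Detector configuration.

All numeric gates of the detection pipeline live here so that every stage is
reproducible from a single file.  Band edges, the 15-min reporting epoch, the
30 % acceptance threshold, the 20-min true-negative convention and the
3-SDs-in-2-h cluster rule are the published operating points of the detector;
the remaining gates (SPC amplitude/duration bounds, suppression depth and
recovery fractions, linking windows, clustering cut) are this package's own
defaults, chosen for mV-scale slow potential changes and tens-of-minutes
depressions on a 6-8 contact strip.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["DetectorConfig", "load_config", "save_config"]


@dataclass
class DetectorConfig:
    # Waveband split
    low_band: tuple[float, float] = (0.005, 0.5)   # Hz, slow-potential band
    high_band: tuple[float, float] = (0.5, 45.0)   # Hz, spontaneous activity
    filter_order: int = 4                          # Butterworth, zero-phase
    working_rate: float = 1.0                      # Hz of low band + envelope
    envelope_window_s: float = 60.0                # causal RMS window

    # Channel screening
    bad_channel_floor_uv: float = 1.0              # flat if env below this >50%
    converter_range_uv: float = 32_000.0           # nominal ADC span
    bad_channel_ceiling_fraction: float = 0.9      # saturated above this

    # SPC detection (low band, 1 Hz)
    spc_min_duration_s: float = 60.0
    spc_max_duration_s: float = 900.0
    spc_scan_durations_s: tuple[float, ...] = (120.0, 180.0, 300.0, 450.0, 600.0)
    spc_min_amplitude_mv: float = 0.5
    spc_corr_threshold: float = 0.8                # template correlation gate
    spc_snippet_points: int = 128

    # Suppression detection (envelope, 1 Hz)
    suppression_depth_ratio: float = 0.5           # open when env < ratio*baseline
    suppression_recovery_fraction: float = 0.8     # close when env > frac*baseline
    suppression_min_duration_s: float = 120.0
    suppression_baseline_minutes: float = 10.0     # rolling median window
    isoelectric_floor_uv: float = 10.0             # already-suppressed cortex

    # SPC-suppression linking
    link_window_before_s: float = 60.0
    link_window_after_s: float = 300.0

    # Cross-channel assembly
    max_interchannel_delay_s: float = 600.0
    max_event_span_s: float = 3600.0
    simultaneity_window_s: float = 30.0

    # Confidence combination
    participation_floor: float = 0.4
    single_channel_factor: float = 0.5

    # Stereotyping
    cluster_cut_distance: float = 0.25
    major_cluster_min: int = 3
    major_cluster_fraction: float = 0.25
    stereotype_boost: float = 15.0
    outlier_penalty: float = 15.0

    # Thresholding & reporting
    confidence_threshold: float = 30.0
    alt_threshold: float = 60.0
    epoch_minutes: float = 15.0
    sd_cluster_count: int = 3
    sd_cluster_window_minutes: float = 120.0
    stream_history_hours: float = 24.0

    # Evaluation
    tn_period_minutes: float = 20.0
    match_tolerance_s: float = 300.0

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_threshold <= 100.0):
            raise ValueError("confidence_threshold must lie in [0, 100]")
        for lo, hi in (self.low_band, self.high_band):
            if not (0.0 < lo < hi):
                raise ValueError("band edges must be positive and ordered")
        if self.sd_cluster_window_minutes <= 0:
            raise ValueError("cluster window must be positive")
        if self.spc_min_duration_s >= self.spc_max_duration_s:
            raise ValueError("SPC duration bounds must be ordered")

    def replace(self, **kwargs) -> "DetectorConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["low_band"] = list(d["low_band"])
        d["high_band"] = list(d["high_band"])
        d["spc_scan_durations_s"] = list(d["spc_scan_durations_s"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("low_band", "high_band", "spc_scan_durations_s"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path: str | Path) -> DetectorConfig:
    """Read a DetectorConfig from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return DetectorConfig()
    return DetectorConfig.from_dict(data)


def save_config(cfg: DetectorConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
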