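"""Seeded synthetic multichannel ECoG with known SD schedules.

The generator emulates what a DC-coupled subdural strip records:

* spontaneous background activity confined to the 0.5-45 Hz band (Gaussian
  noise shaped by the same band limits the detector assumes), plus a small
  infra-slow drift well below 0.005 Hz;
* scheduled SDs: a biphasic slow potential change (two opposed raised-cosine
  lobes, ~5 min, mV scale) sweeping the contacts along a propagation path
  with per-step delay = contact spacing / speed, accompanied by a
  multiplicative suppression of the background (a gain dip with exponential
  recovery for CSD; for ISD the background is already suppressed when the
  wave arrives and stays down);
* artifacts: the inspired-oxygen (FiO2) bolus signature — an identical
  mV-scale slow transient on *all* channels at once with no change in
  spontaneous activity — and broadband movement bursts;
* degraded signals: slow amplitude decay over the record, or a contact
  whose gain toggles between two levels (strip movement);
* flat (bad) and all-NaN (missing) channels.

Every generated event is returned as ground truth (annotation plus
feature-level onsets per channel), and the same seed reproduces the sample
matrix exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal

from .io import EcogRecording, GroundTruthAnnotation

__all__ = [
    "SdScheduleItem",
    "ArtifactItem",
    "SyntheticSpec",
    "generate_recording",
    "make_stereotyped_train",
    "degrade_signal",
    "default_validation_spec",
    "spc_waveform",
    "load_spec",
    "save_spec",
]


@dataclass
class SdScheduleItem:
    onset_s: float
    type: str = "CSD"  # CSD | ISD
    origin_channel: int = 0
    channel_path: list[int] | None = None
    speed_mm_per_min: float = 5.0  # physiological range ~1-9
    spc_amplitude_mv: list[float] | None = None  # per channel; defaults 2-4
    spc_duration_s: float = 300.0
    suppression_depth: float = 0.2
    suppression_duration_s: float = 1200.0  # ignored for ISD (persistent)
    stereotype_family: int = 0
    time_jitter_s: float = 0.0
    amplitude_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.type not in ("CSD", "ISD"):
            raise ValueError("SD type must be CSD or ISD")
        if self.speed_mm_per_min <= 0:
            raise ValueError("propagation speed must be positive")


@dataclass
class ArtifactItem:
    onset_s: float
    kind: str = "fio2_transient"  # fio2_transient | movement_burst
    amplitude_mv: float = 3.0
    duration_s: float = 120.0

    def __post_init__(self) -> None:
        if self.kind not in ("fio2_transient", "movement_burst"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")


@dataclass
class SyntheticSpec:
    duration_s: float = 24 * 3600.0
    n_channels: int = 6
    contact_spacing_mm: float = 10.0
    sample_rate: float = 256.0
    background_rms_uv: float = 50.0
    drift_rms_uv: float = 5.0
    sd_schedule: list[SdScheduleItem] = field(default_factory=list)
    artifact_schedule: list[ArtifactItem] = field(default_factory=list)
    bad_channels: list[int] = field(default_factory=list)
    missing_channels: list[int] = field(default_factory=list)
    degradation_mode: str | None = None  # amplitude_decay | contact_fluctuation
    decay_floor: float = 0.5
    fluctuation_channel: int = 0
    fluctuation_low_gain: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for item in self.sd_schedule:
            if not (0.0 <= item.onset_s < self.duration_s):
                raise ValueError("SD onset outside the record")
        for art in self.artifact_schedule:
            if not (0.0 <= art.onset_s < self.duration_s):
                raise ValueError("artifact onset outside the record")

    def replace(self, **kwargs) -> "SyntheticSpec":
        return dataclasses.replace(self, **kwargs)


def spc_waveform(
    p2p_mv: float, duration_s: float, rate: float, triphasic: bool = False
) -> np.ndarray:
    """SPC kernel: two opposed raised-cosine lobes (plus an optional third).

    The second lobe is 80% of the first, so the peak-to-peak amplitude is
    1.8x the first lobe; the waveform is scaled so its peak-to-peak equals
    ``p2p_mv`` (returned in microvolts).
    """
    n = max(8, int(round(duration_s * rate)))
    lobes = [1.0, -0.8] + ([0.3] if triphasic else [])
    total = sum(abs(a) for a in lobes)
    bounds = np.cumsum([0.0] + [abs(a) / total for a in lobes])
    w = np.zeros(n)
    for a, lo, hi in zip(lobes, bounds[:-1], bounds[1:]):
        i0, i1 = int(round(lo * n)), int(round(hi * n))
        m = i1 - i0
        if m > 0:
            w[i0:i1] = a * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(m) / m))
    scale = p2p_mv * 1000.0 / np.ptp(w)
    return w * scale


def _default_amplitudes(n_channels: int) -> list[float]:
    # end contacts see larger slow potentials (4 mV) than inner ones (2 mV)
    amps = [2.0] * n_channels
    if n_channels >= 2:
        amps[0] = 4.0
        amps[-1] = 4.0
    return amps


def _default_path(origin: int, n_channels: int) -> list[int]:
    """Spread outward from the origin contact, alternating sides."""
    order = sorted(range(n_channels), key=lambda i: (abs(i - origin), i))
    return order


def _suppression_gain(
    gain: np.ndarray,
    t0: float,
    depth: float,
    hold_s: float,
    rate: float,
    recover: bool,
    ramp_s: float = 30.0,
    tau_s: float = 120.0,
) -> None:
    """Multiply a per-channel gain trace by one suppression profile, in place."""
    n = len(gain)
    i0 = int(round(t0 * rate))
    if i0 >= n:
        return
    i0 = max(i0, 0)
    ramp_n = int(round(ramp_s * rate))
    i1 = min(n, i0 + ramp_n)
    if i1 > i0:
        gain[i0:i1] *= np.linspace(1.0, depth, i1 - i0)
    i2 = min(n, i0 + ramp_n + int(round(hold_s * rate))) if recover else n
    gain[i1:i2] *= depth
    if recover and i2 < n:
        # exponential recovery; beyond 10 tau the factor is 1 to 5 decimals
        i3 = min(n, i2 + int(round(10.0 * tau_s * rate)))
        t = np.arange(i3 - i2) / rate
        gain[i2:i3] *= depth + (1.0 - depth) * (1.0 - np.exp(-t / tau_s))


ISD_PRESUPPRESSION_LEAD_S = 1800.0  # cortex goes isoelectric well before the wave


def generate_recording(
    spec: SyntheticSpec,
) -> tuple[EcogRecording, list[GroundTruthAnnotation], list[dict]]:
    """Render a spec into (recording, annotations, feature-level truth).

    The truth list holds one dict per scheduled event — SDs carry their label,
    channel order and per-channel SPC onsets; artifacts are labelled artifact.
    Annotations mirror the truth with one row per event.
    """
    fs = spec.sample_rate
    n = int(round(spec.duration_s * fs))
    n_ch = spec.n_channels
    ss = np.random.SeedSequence(spec.seed)
    noise_seed, event_seed = ss.spawn(2)
    noise_rng = np.random.default_rng(noise_seed)
    event_rng = np.random.default_rng(event_seed)

    sos = signal.butter(4, [0.5, 45.0], btype="band", fs=fs, output="sos")

    # resolve per-event, per-channel onsets first (independent of noise draws)
    truth: list[dict] = []
    annotations: list[GroundTruthAnnotation] = []
    transients: list[list[tuple[float, np.ndarray]]] = [[] for _ in range(n_ch)]
    suppressions: list[list[tuple[float, float, float, bool]]] = [[] for _ in range(n_ch)]
    for item in spec.sd_schedule:
        path = item.channel_path or _default_path(item.origin_channel, n_ch)
        amps = item.spc_amplitude_mv or _default_amplitudes(n_ch)
        step_s = spec.contact_spacing_mm / item.speed_mm_per_min * 60.0
        onsets: dict[int, float] = {}
        for k, ch in enumerate(path):
            t_ch = item.onset_s + k * step_s
            if item.time_jitter_s > 0:
                t_ch += float(event_rng.normal(0.0, item.time_jitter_s))
            t_ch = min(max(t_ch, 0.0), spec.duration_s - item.spc_duration_s)
            amp = amps[ch]
            if item.amplitude_jitter > 0:
                amp *= 1.0 + float(event_rng.normal(0.0, item.amplitude_jitter))
            onsets[ch] = t_ch
            kernel = spc_waveform(max(amp, 0.1), item.spc_duration_s, fs)
            transients[ch].append((t_ch, kernel))
            if item.type == "CSD":
                suppressions[ch].append(
                    (t_ch, item.suppression_depth, item.suppression_duration_s, True)
                )
            else:  # ISD: pre-suppressed before arrival, persistent afterwards
                suppressions[ch].append(
                    (max(0.0, t_ch - ISD_PRESUPPRESSION_LEAD_S), item.suppression_depth, 0.0, False)
                )
        event_onset = min(onsets.values())
        labels = [f"ch{c + 1}" for c in sorted(onsets, key=onsets.get)]
        annotations.append(GroundTruthAnnotation(event_onset, item.type, labels))
        truth.append(
            {
                "label": item.type,
                "onset_s": event_onset,
                "channel_order": sorted(onsets, key=onsets.get),
                "spc_onsets": onsets,
                "stereotype_family": item.stereotype_family,
            }
        )

    movement_windows: list[tuple[float, float]] = []
    for art in spec.artifact_schedule:
        if art.kind == "fio2_transient":
            kernel = spc_waveform(art.amplitude_mv, art.duration_s, fs)
            for ch in range(n_ch):
                transients[ch].append((art.onset_s, kernel))
            onsets = {ch: art.onset_s for ch in range(n_ch)}
        else:
            movement_windows.append((art.onset_s, art.onset_s + art.duration_s))
            onsets = {ch: art.onset_s for ch in range(n_ch)}
        annotations.append(
            GroundTruthAnnotation(art.onset_s, "artifact", [f"ch{c + 1}" for c in range(n_ch)])
        )
        truth.append(
            {
                "label": "artifact",
                "kind": art.kind,
                "onset_s": art.onset_s,
                "channel_order": list(range(n_ch)),
                "spc_onsets": onsets,
            }
        )

    # contact-fluctuation switching times (seeded, ~every 30 min)
    fluct_edges: np.ndarray | None = None
    if spec.degradation_mode == "contact_fluctuation":
        n_edges = max(2, int(spec.duration_s / 1800.0))
        fluct_edges = np.sort(event_rng.uniform(0.0, spec.duration_s, size=n_edges))

    samples = np.empty((n_ch, n))
    drift_t = np.arange(int(spec.duration_s) + 2)
    for ch in range(n_ch):
        white = noise_rng.standard_normal(n)
        bg = signal.sosfilt(sos, white)
        rms = np.sqrt(np.mean(np.square(bg)))
        bg *= spec.background_rms_uv / rms if rms > 0 else 0.0

        # infra-slow drift, built at 1 Hz and interpolated up
        slow = noise_rng.standard_normal(len(drift_t))
        sos_drift = signal.butter(2, 0.002, btype="low", fs=1.0, output="sos")
        drift1 = signal.sosfilt(sos_drift, slow)
        drms = np.sqrt(np.mean(np.square(drift1)))
        drift1 *= spec.drift_rms_uv / drms if drms > 0 else 0.0
        drift = np.interp(np.arange(n) / fs, drift_t, drift1)

        gain = np.ones(n)
        for t0, depth, hold, recover in suppressions[ch]:
            _suppression_gain(gain, t0, depth, hold, fs, recover)
        for t0, t1 in movement_windows:
            i0, i1 = int(t0 * fs), min(n, int(t1 * fs))
            gain[i0:i1] *= 10.0  # broadband burst: background swamped

        x = bg * gain + drift
        for t0, kernel in transients[ch]:
            i0 = int(round(t0 * fs))
            i1 = min(n, i0 + len(kernel))
            x[i0:i1] += kernel[: i1 - i0]

        if spec.degradation_mode == "amplitude_decay":
            x *= np.linspace(1.0, spec.decay_floor, n)
        elif spec.degradation_mode == "contact_fluctuation" and ch == spec.fluctuation_channel:
            level = np.ones(n)
            state = 1.0
            prev = 0
            for edge in fluct_edges:
                i = int(edge * fs)
                level[prev:i] = state
                state = spec.fluctuation_low_gain if state == 1.0 else 1.0
                prev = i
            level[prev:] = state
            x *= level

        if ch in spec.bad_channels:
            x = np.zeros(n)
        if ch in spec.missing_channels:
            x = np.full(n, np.nan)
        samples[ch] = x

    rec = EcogRecording(
        [f"ch{c + 1}" for c in range(n_ch)], fs, samples, start_time=0.0
    )
    order = np.argsort([t["onset_s"] for t in truth], kind="stable")
    truth = [truth[i] for i in order]
    annotations = sorted(annotations, key=lambda a: a.onset_s)
    return rec, annotations, truth


def make_stereotyped_train(
    spec: SyntheticSpec,
    family: int,
    n: int,
    interval_s: float,
    jitter_s: float = 0.0,
    start_s: float = 0.0,
    amplitude_jitter: float = 0.0,
    **item_kwargs,
) -> SyntheticSpec:
    """Append n SDs sharing one stereotype family at a regular interval.

    All members share kernel shape, path and amplitudes; jitter perturbs
    individual onsets/amplitudes slightly, as repeats in a patient do.
    """
    if n < 1:
        raise ValueError("need n >= 1 repeats")
    schedule = list(spec.sd_schedule)
    for k in range(n):
        schedule.append(
            SdScheduleItem(
                onset_s=start_s + k * interval_s,
                stereotype_family=family,
                time_jitter_s=jitter_s,
                amplitude_jitter=amplitude_jitter,
                **item_kwargs,
            )
        )
    return spec.replace(sd_schedule=schedule)


def degrade_signal(spec: SyntheticSpec, mode: str, **kwargs) -> SyntheticSpec:
    """Return a spec with a signal-degradation mode enabled.

    ``amplitude_decay``: everything ramps linearly to ``decay_floor`` of its
    starting amplitude over the record.  ``contact_fluctuation``: one
    channel's gain toggles between 1 and ``fluctuation_low_gain`` at seeded
    random times (strip losing cortical contact).
    """
    if mode not in ("amplitude_decay", "contact_fluctuation"):
        raise ValueError(f"unknown degradation mode {mode!r}")
    return spec.replace(degradation_mode=mode, **kwargs)


def default_validation_spec(seed: int = 0, duration_h: float = 24.0) -> SyntheticSpec:
    """The reference desk-scale study condition.

    A 24-h, 6-channel record with 20 stereotyped CSDs (40-min interval: the
    1200-s depressions recover fully between events) and two FiO2 bolus
    artifacts.
    """
    spec = SyntheticSpec(duration_s=duration_h * 3600.0, seed=seed)
    spec = make_stereotyped_train(
        spec,
        family=1,
        n=20,
        interval_s=2400.0,
        jitter_s=5.0,
        amplitude_jitter=0.05,
        start_s=3600.0,
        origin_channel=0,
    )
    artifacts = [
        ArtifactItem(onset_s=17.5 * 3600.0),
        ArtifactItem(onset_s=20.0 * 3600.0),
    ]
    return spec.replace(artifact_schedule=artifacts)


# ---------------------------------------------------------------------------
# Spec (de)serialization
# ---------------------------------------------------------------------------

def save_spec(spec: SyntheticSpec, path: str | Path) -> None:
    d = dataclasses.asdict(spec)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_spec(path: str | Path) -> SyntheticSpec:
    d = yaml.safe_load(Path(path).read_text())
    d["sd_schedule"] = [SdScheduleItem(**item) for item in d.get("sd_schedule", [])]
    d["artifact_schedule"] = [ArtifactItem(**item) for item in d.get("artifact_schedule", [])]
    return SyntheticSpec(**d)
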