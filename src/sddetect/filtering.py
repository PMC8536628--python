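"""Dual-waveband decomposition of DC-coupled ECoG.

Each channel of raw full-band data is split into a low (slow potential, by
default 0.005-0.5 Hz) and a high (spontaneous activity, 0.5-45 Hz) waveband
with zero-phase Butterworth band-passes, so neither band lags the original
time axis.  The low band and the high-band amplitude envelope are carried
forward at a reduced working rate (1 Hz): slow potential changes are ~5-min
events and suppressions last tens of minutes, so nothing above 0.5 Hz is
needed downstream and hours-long records stay cheap.

The amplitude envelope is a causal sliding-window RMS of the high band.  The
low-band high-pass corner at 0.005 Hz implies a settling time of a few
hundred seconds; decompositions carry a ``settle_s`` prefix that downstream
detection excludes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import DetectorConfig
from .io import EcogRecording

__all__ = [
    "BandDecomposition",
    "split_bands",
    "compute_envelope",
    "derive_bipolar",
    "screen_channels",
    "design_bandpass",
]

GOOD, BAD, MISSING = "good", "bad", "missing"


@dataclass
class BandDecomposition:
    """Per-channel low band, high band and envelope, on one time origin.

    low_band and envelope are channels x time at ``rate`` (default 1 Hz);
    high_band is channels x time at the acquisition rate.  ``settle_s`` marks
    the filter settling prefix that detection should skip.
    """

    channel_labels: list[str]
    low_band: np.ndarray
    high_band: np.ndarray
    envelope: np.ndarray
    rate: float
    acquisition_rate: float
    settle_s: float = 0.0
    channel_quality: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.channel_quality:
            self.channel_quality = [GOOD] * len(self.channel_labels)
        if np.nanmin(self.envelope) < -1e-9:
            raise ValueError("envelope must be non-negative")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def duration_s(self) -> float:
        return self.low_band.shape[1] / self.rate

    def good_channels(self) -> list[int]:
        return [i for i, q in enumerate(self.channel_quality) if q == GOOD]


def design_bandpass(band: tuple[float, float], fs: float, order: int = 4) -> np.ndarray:
    """Butterworth band-pass in second-order sections.

    Applied forward-backward (zero phase), so the effective magnitude
    response is the square of this design's.
    """
    return signal.butter(order, list(band), btype="band", fs=fs, output="sos")


def settle_time_s(cfg: DetectorConfig) -> float:
    # dominated by the low-band high-pass corner
    return 2.0 / cfg.low_band[0]


def split_bands(rec: EcogRecording, cfg: DetectorConfig | None = None) -> BandDecomposition:
    """Split a recording into low/high wavebands plus the activity envelope.

    Missing channels (all-NaN) are passed through as NaN and flagged; a
    recording shorter than 10x the low-band settling time triggers a warning
    and the whole settling prefix is marked for exclusion.
    """
    cfg = cfg or DetectorConfig()
    fs = rec.sample_rate
    settle = settle_time_s(cfg)
    if rec.duration_s < 10.0 * settle:
        warnings.warn(
            f"recording ({rec.duration_s:.0f} s) is shorter than 10x the "
            f"low-band settling time ({settle:.0f} s); the settling prefix "
            "is excluded from detection",
            stacklevel=2,
        )
    sos_low = design_bandpass(cfg.low_band, fs, cfg.filter_order)
    sos_high = design_bandpass(cfg.high_band, fs, cfg.filter_order)

    step = int(round(fs / cfg.working_rate))
    n_low = rec.n_samples // step
    quality = []
    low = np.empty((rec.n_channels, n_low))
    high = np.empty((rec.n_channels, rec.n_samples))
    env = np.empty((rec.n_channels, n_low))
    for i in range(rec.n_channels):
        x = rec.samples[i]
        if np.isnan(x).all():
            quality.append(MISSING)
            low[i] = np.nan
            high[i] = np.nan
            env[i] = np.nan
            continue
        if np.isnan(x).any():
            raise ValueError(
                f"channel {rec.channel_labels[i]!r} has partial NaN; only "
                "entirely missing channels may contain NaN"
            )
        quality.append(GOOD)
        # low band: zero-phase filter at full rate, then pick every step-th
        # sample (content is band-limited to 0.5 Hz, the working Nyquist)
        xl = signal.sosfiltfilt(sos_low, x)
        low[i] = xl[step - 1 :: step][:n_low]
        high[i] = signal.sosfiltfilt(sos_high, x)
        env[i] = compute_envelope(high[i], cfg.envelope_window_s, fs, cfg.working_rate)

    return BandDecomposition(
        list(rec.channel_labels),
        low,
        high,
        env,
        rate=cfg.working_rate,
        acquisition_rate=fs,
        settle_s=min(settle, rec.duration_s / 2.0),
        channel_quality=quality,
    )


def compute_envelope(
    high_band: np.ndarray,
    window_s: float = 60.0,
    fs: float = 256.0,
    out_rate: float = 1.0,
) -> np.ndarray:
    """Causal sliding-window RMS of one high-band channel, at ``out_rate``.

    The window ends at the output instant; at the start of the record the
    window grows from one output step to the full length.
    """
    if window_s < 1.0:
        raise ValueError("window_s must be >= 1 s")
    step = int(round(fs / out_rate))
    n_out = len(high_band) // step
    # per-output-step mean square, then rolling mean over the window:
    # identical to the full-rate window when it aligns to whole steps
    ms = np.mean(
        np.square(high_band[: n_out * step]).reshape(n_out, step), axis=1
    )
    w = max(1, int(round(window_s * out_rate)))
    c = np.concatenate([[0.0], np.cumsum(ms)])
    idx = np.arange(1, n_out + 1)
    lo = np.maximum(0, idx - w)
    return np.sqrt((c[idx] - c[lo]) / (idx - lo))


def derive_bipolar(rec: EcogRecording) -> EcogRecording:
    """Sequential bipolar montage: channel_i - channel_{i+1}.

    Adjacent-contact differences phase-invert the slow potential profile as a
    wave passes, which is the montage the detector was originally tuned on.
    """
    if rec.montage != "unipolar":
        raise ValueError("bipolar derivation requires a unipolar recording")
    if rec.n_channels < 2:
        raise ValueError("bipolar derivation needs >= 2 channels")
    samples = rec.samples[:-1] - rec.samples[1:]
    labels = [
        f"{a}-{b}" for a, b in zip(rec.channel_labels[:-1], rec.channel_labels[1:])
    ]
    return EcogRecording(
        labels, rec.sample_rate, samples, rec.start_time, montage="sequential_bipolar"
    )


def screen_channels(
    decomp: BandDecomposition, cfg: DetectorConfig | None = None
) -> BandDecomposition:
    """Flag flat or saturated channels as bad.

    Flat: envelope below the floor for more than half the record.  Saturated:
    high-band amplitude beyond the configured fraction of the converter
    range.  Missing (NaN) channels keep their flag.
    """
    cfg = cfg or DetectorConfig()
    ceiling = cfg.bad_channel_ceiling_fraction * cfg.converter_range_uv
    quality = list(decomp.channel_quality)
    for i in range(decomp.n_channels):
        if quality[i] == MISSING:
            continue
        env = decomp.envelope[i]
        flat = np.mean(env < cfg.bad_channel_floor_uv) > 0.5
        saturated = np.max(np.abs(decomp.high_band[i])) > ceiling
        quality[i] = BAD if (flat or saturated) else GOOD
    decomp.channel_quality = quality
    return decomp
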