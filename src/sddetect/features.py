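"""Per-channel low-level feature detection.

Two feature types feed the event assembler:

* **SPC candidates** — biphasic or triphasic slow potential transients of
  roughly 5 min duration in the low waveband, found by normalized
  cross-correlation against a canonical biphasic template (two opposite
  half-sine lobes) over a small set of durations.  Detection uses the
  absolute correlation, so it is agnostic to the display polarity
  convention; the lobe count on the smoothed candidate assigns the
  biphasic/triphasic pattern.
* **Suppression events** — sustained reductions of the high-band amplitude
  envelope below a fraction of the rolling pre-event baseline, plus an
  absolute isoelectric rule so that cortex that is already suppressed when
  the record (or the analysis window) starts is still recognized.

Each feature carries a 0-100 confidence: for an SPC a blend of template
correlation and peak-to-peak amplitude, for a suppression a blend of depth
and duration.  Both are monotone in the feature's salience.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .config import DetectorConfig

__all__ = [
    "SpcCandidate",
    "SuppressionEvent",
    "biphasic_template",
    "detect_spcs",
    "detect_suppressions",
    "score_spc_confidence",
    "score_suppression_confidence",
]


@dataclass
class SpcCandidate:
    """One slow-potential-change detection on a single channel."""

    channel: int
    onset_s: float
    duration_s: float
    polarity_pattern: str  # biphasic | triphasic
    peak_to_peak_mv: float
    snippet: np.ndarray = field(repr=False)
    confidence: float = 0.0
    template_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_to_peak_mv <= 0:
            raise ValueError("peak_to_peak_mv must be positive")
        if not (0.0 <= self.confidence <= 100.0):
            raise ValueError("confidence must lie in [0, 100]")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SuppressionEvent:
    """A sustained drop of the spontaneous-activity envelope on one channel."""

    channel: int
    onset_s: float
    end_s: float | None  # None: still suppressed at record end
    depth_ratio: float
    baseline_uv: float
    confidence: float = 0.0

    def __post_init__(self) -> None:
        if self.end_s is not None and not (self.onset_s < self.end_s):
            raise ValueError("onset must precede end for a closed suppression")
        if not (0.0 <= self.depth_ratio < 1.0):
            raise ValueError("depth_ratio must lie in [0, 1)")

    def duration_s(self, record_end_s: float | None = None) -> float:
        end = self.end_s if self.end_s is not None else record_end_s
        if end is None:
            raise ValueError("open suppression needs the record end to size it")
        return end - self.onset_s

    def open_at(self, t: float) -> bool:
        return self.onset_s <= t and (self.end_s is None or t < self.end_s)


def biphasic_template(duration_s: float, rate: float = 1.0, triphasic: bool = False) -> np.ndarray:
    """Canonical SPC template: opposed raised-cosine lobes, unit peak.

    Two lobes (the second 80% of the first, inverted) for the biphasic form;
    an optional small third lobe for the triphasic form.  Raised-cosine lobes
    have smooth endpoints, which matters because the infra-slow high-pass
    edge leaves mostly lobe-transition structure in the observed low band.
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
    return w


@lru_cache(maxsize=64)
def _filtered_template(
    duration_s: float, rate: float, low_corner: float, order: int
) -> tuple[np.ndarray, int]:
    """The canonical kernel as the zero-phase low-band filter renders it.

    A slow transient loses most of its fundamental to the high-pass corner,
    so the observed SPC is the filter's residual, with symmetric (zero-phase)
    ringing extending ~25% of the duration either side of the kernel.
    Returns (template, offset of the kernel start inside the template).
    """
    from scipy import signal as _sg

    L = max(8, int(round(duration_s * rate)))
    margin = max(1, L // 4)
    pad = max(int(round(4.0 / low_corner * rate)), 4 * L)
    x = np.zeros(2 * pad + L)
    x[pad : pad + L] = biphasic_template(duration_s, rate)
    sos = _sg.butter(order, low_corner, btype="high", fs=rate, output="sos")
    y = _sg.sosfiltfilt(sos, x)
    return y[pad - margin : pad + L + margin], margin


# ---------------------------------------------------------------------------
# SPC detection
# ---------------------------------------------------------------------------

def _sliding_ncc(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of every length-L window of x with kernel.

    The window mean is removed, so a DC offset in x does not register.
    Returns one value per window start.
    """
    k0 = kernel - kernel.mean()
    nk = np.linalg.norm(k0)
    L = len(k0)
    if len(x) < L or nk == 0:
        return np.zeros(0)
    num = np.correlate(x, k0, mode="valid")  # sum(k0)=0 kills the mean term
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(np.square(x))])
    s1 = c1[L:] - c1[:-L]
    s2 = c2[L:] - c2[:-L]
    var = np.maximum(s2 - s1 * s1 / L, 0.0)
    denom = np.sqrt(var) * nk
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    return np.clip(corr, -1.0, 1.0)


def _lobe_count(window: np.ndarray, rate: float) -> int:
    """Count alternating-sign lobes of a smoothed, baseline-removed snippet."""
    w = int(max(1, round(10.0 * rate)))  # 10-s moving average
    sm = np.convolve(window - np.median(window), np.ones(w) / w, mode="same")
    peak = np.max(np.abs(sm))
    if peak == 0:
        return 0
    sign = np.sign(sm)
    lobes = 0
    i = 0
    n = len(sm)
    while i < n:
        j = i
        while j < n and sign[j] == sign[i]:
            j += 1
        seg = sm[i:j]
        if sign[i] != 0 and np.max(np.abs(seg)) > 0.25 * peak:
            lobes += 1
        i = j
    return lobes


def detect_spcs(
    low_band_channel: np.ndarray,
    cfg: DetectorConfig | None = None,
    rate: float = 1.0,
    settle_s: float = 0.0,
    channel: int = 0,
) -> list[SpcCandidate]:
    """Detect non-overlapping SPC candidates on one low-band channel.

    Scans the configured template durations, keeps window starts whose
    absolute template correlation clears the gate and whose peak-to-peak
    amplitude clears the mV gate, then resolves overlaps greedily by
    correlation strength.  Returns an empty list when nothing qualifies.
    """
    cfg = cfg or DetectorConfig()
    x = np.asarray(low_band_channel, dtype=float)
    if np.isnan(x).any():
        return []
    min_amp_uv = cfg.spc_min_amplitude_mv * 1000.0

    # template bank per duration: the raw canonical kernel plus the same
    # kernel as the zero-phase low band renders it (matched filter in the
    # observed domain)
    candidates: list[tuple[float, int, int]] = []  # (|corr|, kernel start, length)
    for dur in cfg.spc_scan_durations_s:
        if not (cfg.spc_min_duration_s <= dur <= cfg.spc_max_duration_s):
            continue
        L = int(round(dur * rate))
        filt_tpl, filt_off = _filtered_template(
            float(dur), float(rate), cfg.low_band[0], cfg.filter_order
        )
        for tpl, offset in ((biphasic_template(dur, rate), 0), (filt_tpl, filt_off)):
            corr = np.abs(_sliding_ncc(x, tpl))
            if corr.size == 0:
                continue
            above = corr >= cfg.spc_corr_threshold
            peaks = np.flatnonzero(
                above & (corr >= np.roll(corr, 1)) & (corr > np.roll(corr, -1))
            )
            for p in peaks:
                s = int(p) + offset  # kernel start on the signal axis
                if s / rate < settle_s or s + L > len(x):
                    continue
                if np.ptp(x[s : s + L]) < min_amp_uv:
                    continue
                candidates.append((float(corr[p]), s, L))

    candidates.sort(key=lambda c: (-c[0], c[1]))
    taken = np.zeros(len(x), dtype=bool)
    margin = int(round(cfg.spc_min_duration_s * rate))
    out: list[SpcCandidate] = []
    for c, s, L in candidates:
        if taken[s : s + L].any():
            continue
        taken[max(0, s - margin) : s + L + margin] = True
        w = x[s : s + L]
        base_lo = max(0, s - int(120 * rate))
        baseline = np.median(x[base_lo:s]) if s > base_lo else np.median(w[: max(1, L // 10)])
        dev = np.abs(w - baseline)
        over = np.flatnonzero(dev > 0.1 * dev.max())
        onset_idx = s + (int(over[0]) if over.size else 0)
        lobes = _lobe_count(w, rate)
        pattern = "triphasic" if lobes >= 3 else "biphasic"
        p2p_mv = float(np.ptp(w)) / 1000.0
        snippet = np.interp(
            np.linspace(0, L - 1, cfg.spc_snippet_points), np.arange(L), w
        )
        spc = SpcCandidate(
            channel=channel,
            onset_s=onset_idx / rate,
            duration_s=L / rate,
            polarity_pattern=pattern,
            peak_to_peak_mv=p2p_mv,
            snippet=snippet,
            template_corr=c,
        )
        spc.confidence = score_spc_confidence(spc, c)
        out.append(spc)
    out.sort(key=lambda e: e.onset_s)
    return out


# ---------------------------------------------------------------------------
# Suppression detection
# ---------------------------------------------------------------------------

def detect_suppressions(
    envelope_channel: np.ndarray,
    cfg: DetectorConfig | None = None,
    rate: float = 1.0,
    settle_s: float = 0.0,
    channel: int = 0,
) -> list[SuppressionEvent]:
    """Detect envelope suppressions on one channel.

    A suppression opens when the envelope stays below
    ``suppression_depth_ratio x baseline`` (or below the absolute isoelectric
    floor) for at least ``suppression_min_duration_s``, with the baseline (the
    rolling median of the preceding 10 min) frozen at the moment the drop
    starts; it closes when the envelope recovers above
    ``suppression_recovery_fraction x baseline``.  A suppression still open at
    the record end is returned open-ended.
    """
    cfg = cfg or DetectorConfig()
    env = np.asarray(envelope_channel, dtype=float)
    if np.isnan(env).any() or len(env) == 0:
        return []
    w = int(round(cfg.suppression_baseline_minutes * 60.0 * rate))
    rolling = (
        pd.Series(env)
        .rolling(w, min_periods=max(1, w // 10))
        .median()
        .shift(1)
        .to_numpy()
    )
    rolling[np.isnan(rolling)] = env[0]
    # reference awake level for records that start already suppressed
    awake = env[env >= cfg.isoelectric_floor_uv]
    awake_level = float(np.median(awake)) if awake.size else 2.0 * cfg.isoelectric_floor_uv

    min_len = int(round(cfg.suppression_min_duration_s * rate))
    start_idx = int(round(settle_s * rate))
    events: list[SuppressionEvent] = []

    i = start_idx
    n = len(env)
    open_onset: int | None = None  # confirmed open suppression
    pend_onset: int | None = None  # drop not yet 120 s long
    baseline = rolling[start_idx] if start_idx < n else 0.0
    while i < n:
        if open_onset is None:
            b = rolling[i]
            below = env[i] < cfg.suppression_depth_ratio * b or env[i] < cfg.isoelectric_floor_uv
            if below and pend_onset is None:
                pend_onset = i
                baseline = max(b, awake_level if env[i] < cfg.isoelectric_floor_uv else 0.0)
            elif not below:
                pend_onset = None
            if pend_onset is not None and i - pend_onset + 1 >= min_len:
                open_onset = pend_onset
                pend_onset = None
        else:
            recovered = (
                env[i] > cfg.suppression_recovery_fraction * baseline
                and env[i] >= cfg.isoelectric_floor_uv
            )
            if recovered:
                events.append(_close_event(env, open_onset, i, baseline, rate, channel, cfg))
                open_onset = None
        i += 1
    if open_onset is not None:
        events.append(_close_event(env, open_onset, None, baseline, rate, channel, cfg))
    return events


def _close_event(
    env: np.ndarray,
    onset_idx: int,
    end_idx: int | None,
    baseline: float,
    rate: float,
    channel: int,
    cfg: DetectorConfig,
) -> SuppressionEvent:
    hi = end_idx if end_idx is not None else len(env)
    depth = float(np.median(env[onset_idx:hi]) / baseline) if baseline > 0 else 0.0
    ev = SuppressionEvent(
        channel=channel,
        onset_s=onset_idx / rate,
        end_s=None if end_idx is None else end_idx / rate,
        depth_ratio=float(np.clip(depth, 0.0, 0.99)),
        baseline_uv=float(baseline),
    )
    ev.confidence = score_suppression_confidence(ev, record_end_s=len(env) / rate)
    return ev


# ---------------------------------------------------------------------------
# Confidence scoring
# ---------------------------------------------------------------------------

def score_spc_confidence(spc: SpcCandidate, template_corr: float) -> float:
    """SPC clarity out of 100: 60% template correlation, 40% amplitude.

    Amplitude saturates at 2 mV peak-to-peak, so a textbook-clean 2 mV SPC
    scores 100 and confidence is monotone in both inputs.
    """
    if not (0.0 <= template_corr <= 1.0):
        raise ValueError("template_corr must lie in [0, 1]")
    amp_term = min(1.0, spc.peak_to_peak_mv / 2.0)
    return float(np.clip(100.0 * (0.6 * template_corr + 0.4 * amp_term), 0.0, 100.0))


def score_suppression_confidence(
    sup: SuppressionEvent, record_end_s: float | None = None
) -> float:
    """Suppression strength out of 100: 70% depth, 30% persistence.

    Persistence saturates at 10 min; an open-ended suppression uses the time
    observed so far.
    """
    try:
        dur = sup.duration_s(record_end_s)
    except ValueError:
        dur = 600.0  # open-ended with unknown record end: treat as saturated
    dur_term = min(1.0, dur / 600.0)
    return float(np.clip(100.0 * (0.7 * (1.0 - sup.depth_ratio) + 0.3 * dur_term), 0.0, 100.0))
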