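"""Shared fixtures: small synthetic recordings and detector configs."""

from __future__ import annotations

import numpy as np
import pytest

from sddetect.config import DetectorConfig
from sddetect.synthetic import (
    ArtifactItem,
    SyntheticSpec,
    generate_recording,
    make_stereotyped_train,
)


@pytest.fixture
def cfg() -> DetectorConfig:
    return DetectorConfig()


def small_spec(seed: int = 7, duration_s: float = 2.5 * 3600.0) -> SyntheticSpec:
    """A 2.5-h, 6-channel record with two stereotyped CSDs and one FiO2 bolus."""
    spec = SyntheticSpec(duration_s=duration_s, seed=seed)
    spec = make_stereotyped_train(spec, family=1, n=2, interval_s=2400.0, start_s=1800.0)
    return spec.replace(artifact_schedule=[ArtifactItem(onset_s=7200.0)])


@pytest.fixture(scope="session")
def small_record():
    """(recording, annotations, truth) for the small reference spec."""
    return generate_recording(small_spec())


def clean_low_band_trace(
    seed: int,
    duration_s: float = 3600.0,
    n_events: int = 3,
    noise_uv: float = 20.0,
    amplitudes_mv: tuple[float, ...] = (3.0, 2.0, 4.0),
    durations_s: tuple[float, ...] = (300.0, 180.0, 300.0),
):
    """A 1-Hz low-band-like trace with injected biphasic kernels.

    Returns (trace, list of (onset_s, duration_s)).  Built directly in the
    test, independent of the package's generator, for oracle work.
    """
    rng = np.random.default_rng(seed)
    n = int(duration_s)
    x = rng.normal(0.0, noise_uv, n)
    events = []
    slot = n // (n_events + 1)
    for k in range(n_events):
        dur = durations_s[k % len(durations_s)]
        amp = amplitudes_mv[k % len(amplitudes_mv)]
        onset = (k + 1) * slot - int(dur) // 2
        L = int(dur)
        # hann biphasic, lobes +1 / -0.8, written out independently
        w = np.zeros(L)
        b1 = int(round(L / 1.8))
        w[:b1] = 0.5 * (1 - np.cos(2 * np.pi * np.arange(b1) / b1))
        w[b1:] = -0.8 * 0.5 * (1 - np.cos(2 * np.pi * np.arange(L - b1) / (L - b1)))
        w *= amp * 1000.0 / np.ptp(w)
        x[onset : onset + L] += w
        events.append((float(onset), dur))
    return x, events


def brute_force_spc_scan(
    trace: np.ndarray,
    durations: tuple[float, ...],
    corr_threshold: float = 0.8,
    min_amp_uv: float = 500.0,
) -> list[tuple[int, int]]:
    """Independent SPC oracle: plain-loop normalized cross-correlation of the
    generator's kernel at every 1-s lag; detections where corr > threshold,
    resolved greedily by correlation.  Returns (start, length) windows.
    """
    hits = []
    for dur in durations:
        L = int(dur)
        b1 = int(round(L / 1.8))
        k = np.zeros(L)
        k[:b1] = 0.5 * (1 - np.cos(2 * np.pi * np.arange(b1) / b1))
        k[b1:] = -0.8 * 0.5 * (1 - np.cos(2 * np.pi * np.arange(L - b1) / (L - b1)))
        k = k - k.mean()
        nk = np.linalg.norm(k)
        for s in range(0, len(trace) - L):
            w = trace[s : s + L]
            wc = w - w.mean()
            nw = np.linalg.norm(wc)
            if nw == 0:
                continue
            c = abs(float(np.dot(wc, k) / (nw * nk)))
            if c > corr_threshold and np.ptp(w) >= min_amp_uv:
                hits.append((c, s, L))
    hits.sort(key=lambda h: (-h[0], h[1]))
    taken = np.zeros(len(trace), dtype=bool)
    out = []
    for c, s, L in hits:
        if taken[max(0, s - 60) : s + L + 60].any():
            continue
        taken[max(0, s - 60) : s + L + 60] = True
        out.append((s, L))
    return sorted(out)
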