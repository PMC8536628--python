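"""Generator contracts: truth fidelity, determinism, phenomenology."""

from __future__ import annotations

import numpy as np
import pytest

from sddetect.filtering import screen_channels, split_bands
from sddetect.synthetic import (
    ArtifactItem,
    SdScheduleItem,
    SyntheticSpec,
    degrade_signal,
    generate_recording,
    load_spec,
    make_stereotyped_train,
    save_spec,
    spc_waveform,
)


def one_csd_spec(seed: int = 0, **item_kwargs) -> SyntheticSpec:
    return SyntheticSpec(
        duration_s=3600.0,
        seed=seed,
        sd_schedule=[SdScheduleItem(onset_s=1200.0, **item_kwargs)],
    )


class TestTruthFidelity:
    def test_schedule_and_truth_agree(self):
        spec = SyntheticSpec(
            duration_s=7200.0,
            sd_schedule=[
                SdScheduleItem(onset_s=1000.0, type="CSD"),
                SdScheduleItem(onset_s=4000.0, type="ISD"),
            ],
            artifact_schedule=[ArtifactItem(onset_s=6000.0)],
        )
        _, annotations, truth = generate_recording(spec)
        assert [t["label"] for t in truth] == ["CSD", "ISD", "artifact"]
        assert [a.label for a in annotations] == ["CSD", "ISD", "artifact"]
        assert [a.onset_s for a in annotations] == sorted(a.onset_s for a in annotations)

    def test_adjacent_channel_delay_from_speed(self):
        # 10 mm spacing at 5 mm/min: 120 s between successive contacts
        spec = one_csd_spec(speed_mm_per_min=5.0, channel_path=[0, 1, 2, 3, 4, 5])
        _, _, truth = generate_recording(spec)
        onsets = truth[0]["spc_onsets"]
        deltas = np.diff([onsets[ch] for ch in truth[0]["channel_order"]])
        assert np.allclose(deltas, 120.0)

    def test_explicit_irregular_path(self):
        path = [4, 5, 3, 1, 2, 0]
        spec = one_csd_spec(channel_path=path)
        _, _, truth = generate_recording(spec)
        assert truth[0]["channel_order"] == path


def test_same_seed_identical_samples():
    a, _, _ = generate_recording(one_csd_spec(seed=42))
    b, _, _ = generate_recording(one_csd_spec(seed=42))
    assert np.array_equal(a.samples, b.samples)
    c, _, _ = generate_recording(one_csd_spec(seed=43))
    assert not np.array_equal(a.samples, c.samples)


def test_fio2_transient_simultaneous_all_channels():
    spec = SyntheticSpec(
        duration_s=3600.0, artifact_schedule=[ArtifactItem(onset_s=1800.0)]
    )
    rec, annotations, truth = generate_recording(spec)
    assert truth[0]["label"] == "artifact"
    onsets = list(truth[0]["spc_onsets"].values())
    assert max(onsets) - min(onsets) <= 1.0
    # the transient rides on every channel with no background modulation:
    # high-band rms around the event stays at baseline
    d = split_bands(rec)
    mid = slice(1700, 2100)
    for ch in range(rec.n_channels):
        before = np.median(d.envelope[ch][1000:1600])
        during = np.median(d.envelope[ch][mid])
        assert during == pytest.approx(before, rel=0.2)


def test_background_spectral_contract():
    from scipy import signal as sg

    rec, _, _ = generate_recording(SyntheticSpec(duration_s=3600.0, seed=5))
    f, p = sg.welch(rec.samples[0], fs=rec.sample_rate, nperseg=1 << 16)
    assert p[f < 0.4].sum() / p.sum() < 0.05


class TestStereotypedTrain:
    def test_regular_train_spans_expected_time(self):
        spec = SyntheticSpec(duration_s=8 * 3600.0)
        spec = make_stereotyped_train(spec, family=2, n=20, interval_s=21 * 60.0)
        _, _, truth = generate_recording(spec)
        sds = [t for t in truth if t["label"] == "CSD"]
        assert len(sds) == 20
        span = sds[-1]["onset_s"] - sds[0]["onset_s"]
        assert span == pytest.approx(19 * 21 * 60.0)  # just under 7 h

    def test_single_repeat_is_direct_schedule(self):
        spec = make_stereotyped_train(
            SyntheticSpec(duration_s=3600.0), family=1, n=1, interval_s=600.0, start_s=1200.0
        )
        direct = one_csd_spec()
        a, _, ta = generate_recording(spec.replace(seed=9))
        b, _, tb = generate_recording(direct.replace(seed=9))
        assert ta[0]["spc_onsets"] == tb[0]["spc_onsets"]
        assert np.array_equal(a.samples, b.samples)

    def test_zero_jitter_identical_kernels(self):
        spec = SyntheticSpec(duration_s=3 * 3600.0)
        spec = make_stereotyped_train(spec, family=1, n=3, interval_s=3000.0, jitter_s=0.0)
        _, _, truth = generate_recording(spec)
        onsets = [t["spc_onsets"][0] for t in truth]
        assert np.allclose(np.diff(onsets), 3000.0)


class TestDegradation:
    def test_amplitude_decay_halves_background(self):
        spec = degrade_signal(SyntheticSpec(duration_s=2 * 3600.0, seed=1), "amplitude_decay",
                              decay_floor=0.5)
        rec, _, _ = generate_recording(spec)
        fs = int(rec.sample_rate)
        first = np.std(rec.samples[0][: 1800 * fs])
        last = np.std(rec.samples[0][-1800 * fs :])
        # linear gain ramp 1 -> 0.5: rms of the first half-hour segment is
        # ~0.94 of nominal, of the last ~0.56, so the ratio is ~0.60
        assert last / first == pytest.approx(0.60, abs=0.05)

    def test_no_degradation_unchanged(self):
        a, _, _ = generate_recording(SyntheticSpec(duration_s=1800.0, seed=2))
        b, _, _ = generate_recording(SyntheticSpec(duration_s=1800.0, seed=2, degradation_mode=None))
        assert np.array_equal(a.samples, b.samples)

    def test_fluctuation_only_on_target_channel(self):
        base = SyntheticSpec(duration_s=2 * 3600.0, seed=3)
        spec = degrade_signal(base, "contact_fluctuation", fluctuation_channel=2)
        a, _, _ = generate_recording(base)
        b, _, _ = generate_recording(spec)
        for ch in range(6):
            same = np.array_equal(a.samples[ch], b.samples[ch])
            assert same == (ch != 2)

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError):
            degrade_signal(SyntheticSpec(), "gremlins")


def test_bad_and_missing_channels_flagged():
    spec = SyntheticSpec(duration_s=1800.0, bad_channels=[1], missing_channels=[4], seed=0)
    rec, _, _ = generate_recording(spec)
    d = screen_channels(split_bands(rec))
    assert d.channel_quality[1] == "bad"
    assert d.channel_quality[4] == "missing"
    assert d.channel_quality[0] == "good"


def test_spc_waveform_scaling():
    w = spc_waveform(3.0, 300.0, 256.0)
    assert np.ptp(w) == pytest.approx(3000.0)
    w3 = spc_waveform(2.0, 300.0, 256.0, triphasic=True)
    assert np.ptp(w3) == pytest.approx(2000.0)


def test_spec_yaml_round_trip(tmp_path):
    spec = one_csd_spec(seed=11)
    save_spec(spec, tmp_path / "spec.yaml")
    back = load_spec(tmp_path / "spec.yaml")
    assert back == spec
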