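"""Linking, cross-channel chaining, artifact rules and classification."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sddetect.assembly import (
    LINK_NEW_ONSET,
    LINK_NONE,
    LINK_PRE_EXISTING,
    SdEvent,
    assemble_events,
    classify_event,
    combine_confidence,
    flag_simultaneous,
    link_channel,
)
from sddetect.config import DetectorConfig
from sddetect.features import SpcCandidate, SuppressionEvent


def spc(channel: int, onset: float, conf: float = 80.0, dur: float = 300.0) -> SpcCandidate:
    return SpcCandidate(channel, onset, dur, "biphasic", 2.0, np.zeros(128), conf)


def sup(onset: float, end: float | None = None, channel: int = 0) -> SuppressionEvent:
    return SuppressionEvent(channel, onset, end, 0.2, 50.0, confidence=80.0)


def event_from(members, links=None, flags=()):
    ev = SdEvent(0, members, links or {m.channel: LINK_NEW_ONSET for m in members})
    ev.flags |= set(flags)
    return ev


class TestLinkChannel:
    def test_suppression_opening_after_spc_is_new_onset(self, cfg):
        links = link_channel([spc(0, 1000.0)], [sup(1120.0, 2500.0)], cfg)
        assert links[0][0] == LINK_NEW_ONSET

    def test_suppression_open_since_before_is_pre_existing(self, cfg):
        links = link_channel([spc(0, 1000.0)], [sup(400.0, None)], cfg)
        assert links[0][0] == LINK_PRE_EXISTING

    def test_no_suppression_in_window_is_none(self, cfg):
        links = link_channel([spc(0, 1000.0)], [sup(2000.0, 3000.0)], cfg)
        assert links[0][0] == LINK_NONE


class TestAssembleEvents:
    def test_irregular_path_preserved(self, cfg):
        # wave passing contacts in the order 5, 6, 4, 2, 3, 1 (1-based),
        # two minutes apart
        path = [4, 5, 3, 1, 2, 0]
        items = [
            (spc(ch, 1000.0 + 120.0 * k), LINK_NEW_ONSET, None)
            for k, ch in enumerate(path)
        ]
        events = assemble_events(items, cfg)
        assert len(events) == 1
        assert events[0].channel_order == path

    def test_distant_trains_split(self, cfg):
        items = [(spc(0, 1000.0), LINK_NEW_ONSET, None), (spc(1, 1000.0 + 3 * 3600), LINK_NEW_ONSET, None)]
        assert len(assemble_events(items, cfg)) == 2

    def test_single_spc_flagged(self, cfg):
        events = assemble_events([(spc(2, 500.0), LINK_NONE, None)], cfg)
        assert len(events) == 1
        assert "single_channel" in events[0].flags

    def test_reused_channel_starts_new_event(self, cfg):
        items = [
            (spc(0, 1000.0), LINK_NEW_ONSET, None),
            (spc(1, 1120.0), LINK_NEW_ONSET, None),
            (spc(0, 1400.0), LINK_NEW_ONSET, None),  # contact 0 again: next SD
            (spc(1, 1520.0), LINK_NEW_ONSET, None),
        ]
        events = assemble_events(items, cfg)
        assert [e.channel_order for e in events] == [[0, 1], [0, 1]]

    def test_every_spc_in_exactly_one_event(self, cfg):
        rng = np.random.default_rng(4)
        items = [
            (spc(int(rng.integers(0, 6)), float(rng.uniform(0, 20000))), LINK_NONE, None)
            for _ in range(40)
        ]
        events = assemble_events(items, cfg)
        assigned = [id(m) for e in events for m in e.members]
        assert sorted(assigned) == sorted(id(t[0]) for t in items)
        assert len(set(assigned)) == len(items)


class TestSimultaneity:
    def test_majority_within_window_flags(self, cfg):
        members = [spc(ch, 1000.0 + ch) for ch in range(5)] + [spc(5, 1500.0)]
        ev = event_from(members)
        flag_simultaneous(ev, cfg)
        assert "simultaneous" in ev.flags
        assert classify_event(ev) == "artifact"

    def test_staggered_onsets_not_flagged(self, cfg):
        members = [spc(ch, 1000.0 + 120.0 * ch) for ch in range(6)]
        ev = event_from(members)
        flag_simultaneous(ev, cfg)
        assert "simultaneous" not in ev.flags

    def test_fio2_signature_is_artifact_both_ways(self, cfg):
        # all-channel simultaneous transient with no suppression anywhere
        members = [spc(ch, 1000.0) for ch in range(6)]
        ev = event_from(members, links={ch: LINK_NONE for ch in range(6)})
        flag_simultaneous(ev, cfg)
        assert "simultaneous" in ev.flags
        assert classify_event(ev) == "artifact"
        ev.flags.discard("simultaneous")
        assert classify_event(ev) == "artifact"  # the no-link rule alone suffices


def reference_classification(link_types: tuple[str, ...], simultaneous: bool) -> str:
    """Independent statement of the classification rules."""
    if simultaneous:
        return "artifact"
    has_new = LINK_NEW_ONSET in link_types
    has_pre = LINK_PRE_EXISTING in link_types
    if not has_new and not has_pre:
        return "artifact"
    if has_new and not has_pre:
        return "CSD"
    if has_pre and not has_new:
        return "ISD"
    return "CSD_ISD"


def test_classification_truth_table_exhaustive(cfg):
    kinds = (LINK_NEW_ONSET, LINK_PRE_EXISTING, LINK_NONE)
    for n in range(1, 7):
        for combo in itertools.combinations_with_replacement(kinds, n):
            for simultaneous_flag in (False, True):
                members = [spc(ch, 1000.0 + 120.0 * ch) for ch in range(n)]
                ev = event_from(
                    members,
                    links={ch: combo[ch] for ch in range(n)},
                    flags={"simultaneous"} if simultaneous_flag else set(),
                )
                assert classify_event(ev) == reference_classification(combo, simultaneous_flag)


class TestCombineConfidence:
    def test_all_good_full_participation(self, cfg):
        ev = event_from([spc(ch, 1000.0 + 120 * ch, conf=80.0) for ch in range(6)],
                        links={ch: LINK_NONE for ch in range(6)})
        assert combine_confidence(ev, ["good"] * 6, cfg) == pytest.approx(80.0)

    def test_bad_channels_halve_confidence(self, cfg):
        ev = event_from([spc(ch, 1000.0 + 120 * ch, conf=80.0) for ch in range(3)],
                        links={ch: LINK_NONE for ch in range(3)})
        quality = ["good"] * 3 + ["bad"] * 3
        assert combine_confidence(ev, quality, cfg) == pytest.approx(40.0)
        assert "bad_channel_penalty" in ev.flags

    def test_single_channel_heavily_penalized(self, cfg):
        ev = event_from([spc(0, 1000.0, conf=80.0)], links={0: LINK_NONE},
                        flags={"single_channel"})
        assert combine_confidence(ev, ["good"] * 6, cfg) == pytest.approx(16.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        confs=st.lists(st.floats(0, 100), min_size=1, max_size=5),
        extra=st.floats(0, 100),
    )
    def test_adding_confident_member_never_lowers(self, confs, extra):
        cfg = DetectorConfig()
        members = [spc(ch, 1000.0 + 120 * ch, conf=c) for ch, c in enumerate(confs)]
        ev = event_from(members, links={m.channel: LINK_NONE for m in members})
        base = combine_confidence(ev, ["good"] * 6, cfg)
        extra = max(extra, float(np.mean(confs)))
        members2 = members + [spc(len(confs), 1000.0 + 120 * len(confs), conf=extra)]
        ev2 = event_from(members2, links={m.channel: LINK_NONE for m in members2})
        if "single_channel" in ev.flags:
            ev2.flags.discard("single_channel")
        assert combine_confidence(ev2, ["good"] * 6, cfg) >= base - 1e-9
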