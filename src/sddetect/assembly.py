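"""Cross-channel assembly and classification of SD events.

Per-channel SPCs are first linked with suppressions on the same channel
(a suppression opening around the SPC marks a *new* depression; one already
open marks *pre-existing*, i.e. isoelectric cortex).  SPCs are then chained
across channels in onset order into high-level events, honoring propagation
timing: a wave crossing a 10-mm-spaced strip at mm/min produces
minutes-scale inter-channel delays, so near-simultaneous multichannel
transients are physiologically implausible and flagged as artifact.

Classification (in order): simultaneous -> artifact; no suppression link on
any channel -> artifact; new-onset suppressions only -> CSD; pre-existing
only -> ISD; both in different channels -> CSD/ISD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DetectorConfig
from .features import SpcCandidate, SuppressionEvent

__all__ = [
    "SdEvent",
    "LINK_NEW_ONSET",
    "LINK_PRE_EXISTING",
    "LINK_NONE",
    "link_channel",
    "assemble_events",
    "flag_simultaneous",
    "classify_event",
    "combine_confidence",
    "assemble",
]

LINK_NEW_ONSET = "new_onset"
LINK_PRE_EXISTING = "pre_existing"
LINK_NONE = "none"

CLASSIFICATIONS = ("CSD", "ISD", "CSD_ISD", "artifact")


@dataclass
class SdEvent:
    """A multichannel SD (or artifact) assembled from per-channel SPCs."""

    id: int
    members: list[SpcCandidate]
    links: dict[int, str]  # channel -> link type
    suppressions: dict[int, SuppressionEvent] = field(default_factory=dict)
    classification: str = "artifact"
    confidence: float = 0.0
    flags: set[str] = field(default_factory=set)

    @property
    def onset_s(self) -> float:
        return min(m.onset_s for m in self.members)

    @property
    def end_s(self) -> float:
        """Last member SPC onset plus that SPC's duration."""
        last = max(self.members, key=lambda m: m.onset_s)
        return last.onset_s + last.duration_s

    @property
    def channel_order(self) -> list[int]:
        return [m.channel for m in sorted(self.members, key=lambda m: m.onset_s)]

    @property
    def n_channels(self) -> int:
        return len(self.members)

    def member_on(self, channel: int) -> SpcCandidate | None:
        for m in self.members:
            if m.channel == channel:
                return m
        return None


def link_channel(
    spcs: list[SpcCandidate],
    suppressions: list[SuppressionEvent],
    cfg: DetectorConfig | None = None,
) -> list[tuple[str, SuppressionEvent | None]]:
    """Link each SPC on one channel with a coincident suppression.

    new_onset: a suppression opens within [onset - link_window_before,
    onset + link_window_after].  pre_existing: a suppression is already open
    at the SPC onset.  Otherwise none.
    """
    cfg = cfg or DetectorConfig()
    out: list[tuple[str, SuppressionEvent | None]] = []
    for spc in spcs:
        lo = spc.onset_s - cfg.link_window_before_s
        hi = spc.onset_s + cfg.link_window_after_s
        new = [s for s in suppressions if lo <= s.onset_s <= hi]
        if new:
            out.append((LINK_NEW_ONSET, min(new, key=lambda s: abs(s.onset_s - spc.onset_s))))
            continue
        pre = [s for s in suppressions if s.open_at(spc.onset_s) and s.onset_s < lo]
        if pre:
            out.append((LINK_PRE_EXISTING, max(pre, key=lambda s: s.onset_s)))
            continue
        out.append((LINK_NONE, None))
    return out


def assemble_events(
    linked_spcs: list[tuple[SpcCandidate, str, SuppressionEvent | None]],
    cfg: DetectorConfig | None = None,
) -> list[SdEvent]:
    """Chain SPCs on distinct channels into events, greedily in onset order.

    Consecutive members must be separated by at most
    ``max_interchannel_delay_s`` and the event must span at most
    ``max_event_span_s``.  An SPC on a channel the open event has already
    consumed starts a new event (this deterministically splits consecutive
    overlapping SDs).  Every SPC ends up in exactly one event; lone SPCs
    become single_channel-flagged events.
    """
    cfg = cfg or DetectorConfig()
    items = sorted(linked_spcs, key=lambda t: (t[0].onset_s, t[0].channel))
    events: list[SdEvent] = []
    current: list[tuple[SpcCandidate, str, SuppressionEvent | None]] = []

    def close() -> None:
        if not current:
            return
        members = [t[0] for t in current]
        links = {t[0].channel: t[1] for t in current}
        sups = {t[0].channel: t[2] for t in current if t[2] is not None}
        ev = SdEvent(id=len(events), members=members, links=links, suppressions=sups)
        if len(members) == 1:
            ev.flags.add("single_channel")
        events.append(ev)
        current.clear()

    for item in items:
        spc = item[0]
        if current:
            first = current[0][0].onset_s
            last = current[-1][0].onset_s
            used = {t[0].channel for t in current}
            fits = (
                spc.channel not in used
                and spc.onset_s - last <= cfg.max_interchannel_delay_s
                and spc.onset_s - first <= cfg.max_event_span_s
            )
            if not fits:
                close()
        current.append(item)
    close()
    return events


def flag_simultaneous(event: SdEvent, cfg: DetectorConfig | None = None) -> SdEvent:
    """Flag an event whose SPCs arrive together on several channels.

    'Several' is a strict majority: the flag is set when more than half of the
    member onsets fall within one simultaneity window.  Flagged events are
    classified artifact regardless of suppression links.
    """
    cfg = cfg or DetectorConfig()
    onsets = np.sort([m.onset_s for m in event.members])
    n = len(onsets)
    if n >= 2:
        counts = np.searchsorted(onsets, onsets + cfg.simultaneity_window_s, side="right") - np.arange(n)
        if counts.max() > n / 2:
            event.flags.add("simultaneous")
    return event


def classify_event(event: SdEvent) -> str:
    """Apply the classification rules in order and set the event's label."""
    link_types = set(event.links.values())
    if "simultaneous" in event.flags:
        cls = "artifact"
    elif link_types <= {LINK_NONE}:
        cls = "artifact"
    elif LINK_NEW_ONSET in link_types and LINK_PRE_EXISTING not in link_types:
        cls = "CSD"
    elif LINK_PRE_EXISTING in link_types and LINK_NEW_ONSET not in link_types:
        cls = "ISD"
    else:
        cls = "CSD_ISD"
    event.classification = cls
    return cls


def combine_confidence(
    event: SdEvent,
    channel_quality: list[str],
    cfg: DetectorConfig | None = None,
) -> float:
    """Propagate low-level confidences to the event.

    Mean of member SPC confidences and linked suppression confidences, scaled
    by a participation factor (members / good channels, floored so sparse but
    genuine events survive), a channel-quality factor (good / total), and a
    penalty for single-channel events.
    """
    cfg = cfg or DetectorConfig()
    vals = [m.confidence for m in event.members]
    vals += [s.confidence for s in event.suppressions.values()]
    base = float(np.mean(vals)) if vals else 0.0

    n_total = len(channel_quality)
    n_good = sum(1 for q in channel_quality if q == "good")
    if n_good == 0:
        event.confidence = 0.0
        event.flags.add("bad_channel_penalty")
        return 0.0
    participation = min(1.0, event.n_channels / n_good)
    participation = max(cfg.participation_floor, participation)
    quality = n_good / n_total
    if quality < 1.0:
        event.flags.add("bad_channel_penalty")
    conf = base * participation * quality
    if "single_channel" in event.flags:
        conf *= cfg.single_channel_factor
    event.confidence = float(np.clip(conf, 0.0, 100.0))
    return event.confidence


def assemble(
    spcs_by_channel: dict[int, list[SpcCandidate]],
    sups_by_channel: dict[int, list[SuppressionEvent]],
    channel_quality: list[str],
    cfg: DetectorConfig | None = None,
) -> list[SdEvent]:
    """Full assembly pass: link, chain, flag, classify, score."""
    cfg = cfg or DetectorConfig()
    linked: list[tuple[SpcCandidate, str, SuppressionEvent | None]] = []
    for ch, spcs in spcs_by_channel.items():
        links = link_channel(spcs, sups_by_channel.get(ch, []), cfg)
        linked.extend((spc, lt, sup) for spc, (lt, sup) in zip(spcs, links))
    events = assemble_events(linked, cfg)
    for ev in events:
        flag_simultaneous(ev, cfg)
        classify_event(ev)
        combine_confidence(ev, channel_quality, cfg)
    return events
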