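"""End-to-end detection pipeline.

Batch order of operations: band split -> channel screening -> per-channel SPC
and suppression detection -> cross-channel assembly and classification ->
stereotyping (confidence adjustment) -> threshold partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .assembly import SdEvent, assemble
from .config import DetectorConfig
from .features import detect_spcs, detect_suppressions
from .filtering import BandDecomposition, screen_channels, split_bands
from .io import EcogRecording, EventLogRecord
from .stereotyping import apply_threshold, stereotype

__all__ = ["PipelineResult", "detect", "events_to_log"]


@dataclass
class PipelineResult:
    decomposition: BandDecomposition
    candidates: list[SdEvent]  # every assembled event, final confidences
    accepted: list[SdEvent]
    rejected: list[SdEvent]
    channel_labels: list[str] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.decomposition.duration_s


def detect(
    rec: EcogRecording,
    cfg: DetectorConfig | None = None,
    threshold: float | None = None,
) -> PipelineResult:
    """Run the full detector on a recording."""
    cfg = cfg or DetectorConfig()
    thr = cfg.confidence_threshold if threshold is None else threshold
    decomp = screen_channels(split_bands(rec, cfg), cfg)

    spcs = {}
    sups = {}
    for ch in decomp.good_channels():
        spcs[ch] = detect_spcs(
            decomp.low_band[ch], cfg, rate=decomp.rate, settle_s=decomp.settle_s, channel=ch
        )
        sups[ch] = detect_suppressions(
            decomp.envelope[ch], cfg, rate=decomp.rate, settle_s=decomp.settle_s, channel=ch
        )
    candidates = assemble(spcs, sups, decomp.channel_quality, cfg)
    candidates = stereotype(candidates, cfg)
    accepted, rejected = apply_threshold(candidates, thr)
    return PipelineResult(
        decomposition=decomp,
        candidates=candidates,
        accepted=accepted,
        rejected=rejected,
        channel_labels=list(rec.channel_labels),
    )


def events_to_log(
    events: list[SdEvent], channel_labels: list[str], comment: str = ""
) -> list[EventLogRecord]:
    """Convert detected events to event-log records (sorted by onset)."""
    records = []
    for ev in sorted(events, key=lambda e: e.onset_s):
        records.append(
            EventLogRecord(
                onset_s=ev.onset_s,
                classification=ev.classification,
                confidence_pct=ev.confidence,
                channel_order=[channel_labels[c] for c in ev.channel_order],
                spc_onsets={channel_labels[m.channel]: m.onset_s for m in ev.members},
                suppression_links={
                    channel_labels[ch]: kind
                    for ch, kind in ev.links.items()
                    if kind != "none"
                },
                comment=comment,
            )
        )
    return records
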