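"""15-min epoch heat-map grid, SD cluster flags and streaming emission.

The bedside display is a grid of 15-min blocks: one row per physiological
variable (block = the 15-min mean, flagged against a clinician-defined target
range) and one electrophysiology row whose block state is the maximum final
confidence of any accepted SD whose interval intersects the block — an event
straddling a block boundary therefore marks both blocks.  Rendering is out of
core: the grid carries numeric states plus a declared state->bin mapping
(green/orange/brown/red confidence quartiles).

Streaming mode re-runs detection and stereotyping after every epoch over a
sliding history, so earlier blocks may be re-graded (up or down) as the
stereotype builds; every revision is logged with the epoch that caused it.
A cluster flag marks any window holding three or more accepted SD onsets
within two hours.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .assembly import SdEvent
from .config import DetectorConfig
from .io import EcogRecording
from .pipeline import PipelineResult, detect, events_to_log

__all__ = [
    "PhysiologySeries",
    "HeatmapGrid",
    "SdClusterFlag",
    "build_heatmap",
    "detect_sd_clusters",
    "stream_epochs",
    "grid_to_csv",
    "grid_to_json",
]

STATE_BINS = {"green": (0, 25), "orange": (25, 50), "brown": (50, 75), "red": (75, 100)}


@dataclass
class PhysiologySeries:
    """One monitored variable: samples at arbitrary instants plus its target range."""

    name: str
    times_s: np.ndarray
    values: np.ndarray
    target_range: tuple[float, float] | None = None


@dataclass
class HeatmapGrid:
    epoch_minutes: float
    n_epochs: int
    sd_row: list[float]  # per-epoch max accepted confidence, 0 if none
    sd_event_ids: list[list[int]]
    physiology_rows: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sd_row) != self.n_epochs:
            raise ValueError("sd_row length must equal the epoch count")


@dataclass
class SdClusterFlag:
    start_s: float
    end_s: float
    event_ids: list[int]

    @property
    def count(self) -> int:
        return len(self.event_ids)


def _epoch_range(onset: float, end: float, epoch_s: float, n_epochs: int) -> range:
    e0 = int(onset // epoch_s)
    e1 = int(math.ceil(end / epoch_s)) - 1 if end > onset else e0
    e1 = max(e1, e0)
    return range(max(0, e0), min(n_epochs - 1, e1) + 1)


def build_heatmap(
    accepted: list[SdEvent],
    physiology: list[PhysiologySeries],
    duration_s: float,
    cfg: DetectorConfig | None = None,
) -> HeatmapGrid:
    """Build the epoch grid for a record.

    An accepted event marks every epoch its [onset, end] interval intersects;
    the epoch state is the maximum confidence among marking events.
    Physiology rows are epoch means flagged in_range/low/high, or missing when
    the variable has no sample in the epoch (or no signal at all).
    """
    cfg = cfg or DetectorConfig()
    epoch_s = cfg.epoch_minutes * 60.0
    n_epochs = int(math.ceil(duration_s / epoch_s))
    sd_row = [0.0] * n_epochs
    ids: list[list[int]] = [[] for _ in range(n_epochs)]
    for ev in accepted:
        for e in _epoch_range(ev.onset_s, ev.end_s, epoch_s, n_epochs):
            sd_row[e] = max(sd_row[e], ev.confidence)
            ids[e].append(ev.id)

    rows: dict[str, dict] = {}
    for series in physiology:
        means: list[float | None] = []
        flags: list[str] = []
        t = np.asarray(series.times_s, dtype=float)
        v = np.asarray(series.values, dtype=float)
        for e in range(n_epochs):
            mask = (t >= e * epoch_s) & (t < (e + 1) * epoch_s) & ~np.isnan(v)
            if not mask.any():
                means.append(None)
                flags.append("missing")
                continue
            m = float(np.mean(v[mask]))
            means.append(m)
            if series.target_range is None:
                flags.append("in_range")
            elif m < series.target_range[0]:
                flags.append("low")
            elif m > series.target_range[1]:
                flags.append("high")
            else:
                flags.append("in_range")
        rows[series.name] = {"means": means, "flags": flags}
    return HeatmapGrid(cfg.epoch_minutes, n_epochs, sd_row, ids, rows)


def detect_sd_clusters(
    accepted: list[SdEvent], cfg: DetectorConfig | None = None
) -> list[SdClusterFlag]:
    """Flag maximal windows holding >= sd_cluster_count onsets within the window."""
    cfg = cfg or DetectorConfig()
    w = cfg.sd_cluster_window_minutes * 60.0
    k = cfg.sd_cluster_count
    events = sorted(accepted, key=lambda e: e.onset_s)
    onsets = [e.onset_s for e in events]
    n = len(onsets)
    spans: list[tuple[int, int]] = []
    for i in range(n):
        j = i
        while j + 1 < n and onsets[j + 1] - onsets[i] <= w:
            j += 1
        if j - i + 1 >= k:
            spans.append((i, j))
    merged: list[tuple[int, int]] = []
    for s in spans:
        if merged and s[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], s[1]))
        else:
            merged.append(s)
    return [
        SdClusterFlag(onsets[i], onsets[j], [events[x].id for x in range(i, j + 1)])
        for i, j in merged
    ]


def stream_epochs(
    rec: EcogRecording,
    cfg: DetectorConfig | None = None,
    physiology: list[PhysiologySeries] | None = None,
) -> Iterator[tuple[int, HeatmapGrid, dict]]:
    """Emit (epoch index, grid, delta) after each 15-min epoch.

    After every epoch the detector and stereotyping re-run over the sliding
    history window, so confidences of earlier epochs may be revised; the delta
    lists new events and every revised epoch.  The final emission covers the
    whole record and matches the batch result for records no longer than the
    history window.
    """
    cfg = cfg or DetectorConfig()
    physiology = physiology or []
    epoch_s = cfg.epoch_minutes * 60.0
    history_s = cfg.stream_history_hours * 3600.0
    n_epochs = int(math.ceil(rec.duration_s / epoch_s))
    prev_row: list[float] = []
    prev_onsets: set[float] = set()
    for e in range(n_epochs):
        t_end = min((e + 1) * epoch_s, rec.duration_s)
        t_start = max(0.0, t_end - history_s)
        i0, i1 = int(t_start * rec.sample_rate), int(round(t_end * rec.sample_rate))
        window = EcogRecording(
            list(rec.channel_labels),
            rec.sample_rate,
            rec.samples[:, i0:i1],
            start_time=rec.start_time + t_start,
            montage=rec.montage,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # short prefixes trip the settle warning
            result = detect(window, cfg)
        for ev in result.candidates:  # re-express on the record time axis
            for m in ev.members:
                m.onset_s += t_start
        accepted = sorted(result.accepted, key=lambda ev: ev.onset_s)
        grid = build_heatmap(accepted, physiology, t_end, cfg)
        onsets = {round(ev.onset_s, 1) for ev in accepted}
        revisions = [
            {"epoch": i, "old": prev_row[i], "new": grid.sd_row[i], "revised_at_epoch": e}
            for i in range(min(len(prev_row), len(grid.sd_row)))
            if grid.sd_row[i] != prev_row[i]
        ]
        delta = {
            "new_events": events_to_log(
                [ev for ev in accepted if round(ev.onset_s, 1) not in prev_onsets],
                list(rec.channel_labels),
            ),
            "revisions": revisions,
        }
        prev_row = list(grid.sd_row)
        prev_onsets = onsets
        yield e, grid, delta


def grid_to_csv(grid: HeatmapGrid, path: str | Path) -> None:
    """Rows = variables (SD row first), columns = epochs."""
    data = {"sd_confidence": grid.sd_row}
    for name, row in grid.physiology_rows.items():
        data[name] = [m if m is not None else np.nan for m in row["means"]]
    df = pd.DataFrame(data).T
    df.columns = [f"epoch_{i}" for i in range(grid.n_epochs)]
    df.to_csv(path)


def grid_to_json(grid: HeatmapGrid, path: str | Path, revisions: list | None = None) -> None:
    payload = {
        "epoch_minutes": grid.epoch_minutes,
        "n_epochs": grid.n_epochs,
        "sd_row": grid.sd_row,
        "sd_event_ids": grid.sd_event_ids,
        "physiology_rows": grid.physiology_rows,
        "state_bins": {k: list(v) for k, v in STATE_BINS.items()},
        "revisions": revisions or [],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
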