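"""Reading and writing ECoG recordings, annotations and event logs.

The canonical in-memory unit is the microvolt: DC-coupled subdural strips see
mV-scale slow potential changes, which therefore appear as thousands of µV.
Time is seconds from recording start (float).

Three on-disk recording dialects are supported:

* **EDF** (continuous): read through MNE; written by the module's own minimal
  EDF writer (16-bit, 1-s data records, wide physical range so mV transients
  do not clip).  NaN samples cannot be represented in EDF and are written as
  zero.
* **CSV**: first column ``time_s``, one column per channel, header row with
  channel labels.
* **HDF5**: dataset ``/samples`` (channels x time) with metadata attributes.

Readers never resample or reorder channels; a sample-rate mismatch between
signals is an error.
"""

from __future__ import annotations

import datetime as _dt
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "EcogRecording",
    "GroundTruthAnnotation",
    "EventLogRecord",
    "ANNOTATION_LABELS",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "read_event_log",
    "write_event_log",
]

ANNOTATION_LABELS = ("CSD", "ISD", "CSD_ISD", "SD_unspecified", "artifact")


@dataclass
class EcogRecording:
    """Multichannel DC-coupled ECoG signal.

    samples are channels x time in microvolts.  NaN is only permitted in
    channels that are entirely missing.
    """

    channel_labels: list[str]
    sample_rate: float
    samples: np.ndarray
    start_time: float = 0.0
    montage: str = "unipolar"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if self.samples.shape[0] < 1:
            raise ValueError("at least one channel required")
        if self.sample_rate < 100.0:
            raise ValueError("sample_rate must be >= 100 Hz to cover the 45 Hz band edge")
        if self.montage not in ("unipolar", "sequential_bipolar"):
            raise ValueError(f"unknown montage {self.montage!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass(order=True)
class GroundTruthAnnotation:
    """A manually scored event: an instant (onset) with a label."""

    onset_s: float
    label: str = field(compare=False)
    channels: list[str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.label not in ANNOTATION_LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {ANNOTATION_LABELS}"
            )


@dataclass
class EventLogRecord:
    """One detected event as written to the event-log CSV."""

    onset_s: float
    classification: str
    confidence_pct: float
    channel_order: list[str]
    spc_onsets: dict[str, float]
    suppression_links: dict[str, str]
    comment: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_pct <= 100.0):
            raise ValueError("confidence must lie in [0, 100]")


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    return {".edf": "edf", ".csv": "csv", ".h5": "hdf5", ".hdf5": "hdf5"}.get(
        suffix, "csv"
    )


def read_recording(path: str | Path, format: str | None = None) -> EcogRecording:
    """Read a recording; format inferred from the extension unless given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def write_recording(rec: EcogRecording, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if rec.n_samples == 0:
        raise ValueError("cannot write an empty-duration recording")
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "hdf5":
        _write_hdf5(rec, path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


def _read_csv(path: Path) -> EcogRecording:
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.columns[0] != "time_s":
        raise ValueError("CSV recording must have a header starting with time_s")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("recording too short to infer a sample rate")
    # infer the rate from the full span (epoch-scale offsets leave only
    # ~1e-7 s of float precision per stamp) and snap near-integer rates
    rate = (len(t) - 1) / (t[-1] - t[0])
    if abs(rate - round(rate)) < 1e-3:
        rate = float(round(rate))
    residual = t - (t[0] + np.arange(len(t)) / rate)
    if np.max(np.abs(residual)) > 0.05 / rate:
        raise ValueError("non-uniform time axis")
    labels = list(df.columns[1:])
    samples = df[labels].to_numpy(dtype=float).T
    return EcogRecording(labels, rate, samples, start_time=float(t[0]))


def _write_csv(rec: EcogRecording, path: Path) -> None:
    t = rec.start_time + rec.times()
    df = pd.DataFrame({"time_s": t})
    for i, label in enumerate(rec.channel_labels):
        df[label] = rec.samples[i]
    df.to_csv(path, index=False, float_format="%.9f")


def _read_hdf5(path: Path) -> EcogRecording:
    with h5py.File(path, "r") as f:
        samples = f["samples"][()]
        meta = f["samples"].attrs
        labels = [str(x) for x in meta["channel_labels"]]
        return EcogRecording(
            labels,
            float(meta["sample_rate"]),
            samples,
            start_time=float(meta.get("start_time", 0.0)),
            montage=str(meta.get("montage", "unipolar")),
        )


def _write_hdf5(rec: EcogRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("samples", data=rec.samples)
        ds.attrs["channel_labels"] = [str(x) for x in rec.channel_labels]
        ds.attrs["sample_rate"] = rec.sample_rate
        ds.attrs["start_time"] = rec.start_time
        ds.attrs["montage"] = rec.montage


# -- EDF ---------------------------------------------------------------------

def _read_edf(path: Path) -> EcogRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # MNE resamples mixed-rate EDF signals on read; reject such files by
    # checking the underlying header instead.
    with open(path, "rb") as f:
        header = f.read(256)
        ns = int(header[252:256].decode("ascii").strip())
        f.seek(256 + ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80))
        nr_field = f.read(ns * 8)
    labels_hdr = _edf_labels(path, ns)
    data_signals = [i for i, lab in enumerate(labels_hdr) if lab != "EDF Annotations"]
    if len({nr_field[i * 8:(i + 1) * 8] for i in data_signals}) > 1:
        raise ValueError("mixed sample rates in EDF are not supported")
    data = raw.get_data() * 1e6  # MNE returns volts
    meas = raw.info["meas_date"]
    start = meas.timestamp() if meas is not None else 0.0
    return EcogRecording(list(raw.ch_names), float(raw.info["sfreq"]), data, start_time=start)


def _edf_labels(path: Path, ns: int) -> list[str]:
    with open(path, "rb") as f:
        f.seek(256)
        raw = f.read(ns * 16)
    return [raw[i * 16:(i + 1) * 16].decode("ascii", "replace").strip() for i in range(ns)]


def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _write_edf(rec: EcogRecording, path: Path) -> None:
    """Minimal continuous EDF writer (16-bit, 1-s records)."""
    rate = rec.sample_rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    spr = int(round(rate))  # samples per 1-s record
    n_rec = math.ceil(rec.n_samples / spr)
    ns = rec.n_channels

    data = np.nan_to_num(rec.samples, nan=0.0)
    # wide symmetric physical range: mV transients must not clip
    phys_max = max(32000.0, float(np.abs(data).max()) * 1.05)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + dig_min).astype("<i2")

    start = _dt.datetime.fromtimestamp(rec.start_time, tz=_dt.timezone.utc)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("X X X X", 80),
            _edf_field(start.strftime("%d.%m.%y"), 8),
            _edf_field(start.strftime("%H.%M.%S"), 8),
            _edf_field(str(256 + ns * 256), 8),
            _edf_field("", 44),
            _edf_field(str(n_rec), 8),
            _edf_field("1", 8),
            _edf_field(str(ns), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_edf_field(lab, 16) for lab in rec.channel_labels),
            b"".join(_edf_field("ECoG subdural", 80) for _ in range(ns)),
            b"".join(_edf_field("uV", 8) for _ in range(ns)),
            b"".join(_edf_field(f"{phys_min:.1f}"[:8], 8) for _ in range(ns)),
            b"".join(_edf_field(f"{phys_max:.1f}"[:8], 8) for _ in range(ns)),
            b"".join(_edf_field(str(dig_min), 8) for _ in range(ns)),
            b"".join(_edf_field(str(dig_max), 8) for _ in range(ns)),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field(str(spr), 8) for _ in range(ns)),
            b"".join(_edf_field("", 32) for _ in range(ns)),
        ]
    )
    pad_value = np.round((0.0 - phys_min) * scale + dig_min).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        f.write(sig)
        for r in range(n_rec):
            lo, hi = r * spr, min((r + 1) * spr, rec.n_samples)
            block = digital[:, lo:hi]
            if hi - lo < spr:  # pad the trailing partial record with baseline
                pad = np.full((ns, spr - (hi - lo)), pad_value, dtype="<i2")
                block = np.concatenate([block, pad], axis=1)
            f.write(block.tobytes())


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[GroundTruthAnnotation]:
    """Read a ground-truth CSV (onset_s,label[,channels]); sorted by onset."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if len(df) == 0:
        return []
    if "onset_s" not in df.columns or "label" not in df.columns:
        raise ValueError("annotation CSV needs onset_s and label columns")
    out = []
    for _, row in df.iterrows():
        channels = None
        if "channels" in df.columns and isinstance(row.get("channels"), str) and row["channels"]:
            channels = row["channels"].split(";")
        out.append(GroundTruthAnnotation(float(row["onset_s"]), str(row["label"]), channels))
    return sorted(out, key=lambda a: a.onset_s)


def write_annotations(annotations: list[GroundTruthAnnotation], path: str | Path) -> None:
    rows = [
        {
            "onset_s": a.onset_s,
            "label": a.label,
            "channels": ";".join(a.channels) if a.channels else "",
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["onset_s", "label", "channels"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Event logs
# ---------------------------------------------------------------------------

_LOG_COLUMNS = [
    "onset_s",
    "classification",
    "confidence_pct",
    "channel_order",
    "spc_onsets",
    "suppression_links",
    "comment",
]


def write_event_log(events: list[EventLogRecord], path: str | Path) -> None:
    """Write the event log CSV, one event per row (empty list: header only)."""
    rows = []
    for ev in events:
        rows.append(
            {
                "onset_s": ev.onset_s,
                "classification": ev.classification,
                "confidence_pct": ev.confidence_pct,
                "channel_order": ";".join(ev.channel_order),
                "spc_onsets": ";".join(f"{ch}:{t:.1f}" for ch, t in ev.spc_onsets.items()),
                "suppression_links": ";".join(
                    f"{ch}:{kind}" for ch, kind in ev.suppression_links.items()
                ),
                "comment": ev.comment,
            }
        )
    pd.DataFrame(rows, columns=_LOG_COLUMNS).to_csv(path, index=False)


def read_event_log(path: str | Path) -> list[EventLogRecord]:
    try:
        df = pd.read_csv(path, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if list(df.columns) != _LOG_COLUMNS:
        raise ValueError("unexpected event-log columns")
    out = []
    for _, row in df.iterrows():
        spc = {}
        if row["spc_onsets"]:
            for item in str(row["spc_onsets"]).split(";"):
                ch, t = item.rsplit(":", 1)
                spc[ch] = float(t)
        links = {}
        if row["suppression_links"]:
            for item in str(row["suppression_links"]).split(";"):
                ch, kind = item.rsplit(":", 1)
                links[ch] = kind
        order = str(row["channel_order"]).split(";") if row["channel_order"] else []
        out.append(
            EventLogRecord(
                float(row["onset_s"]),
                str(row["classification"]),
                float(row["confidence_pct"]),
                order,
                spc,
                links,
                str(row["comment"]),
            )
        )
    return out
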