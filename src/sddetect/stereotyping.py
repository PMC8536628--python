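"""Event stereotyping: similarity, clustering and confidence adjustment.

A patient's genuine SDs tend to repeat with stereotyped SPC shapes, whereas
artifacts are one-offs.  Candidate events are compared pairwise — the
similarity between two events is the mean, over channels they share, of the
normalized cross-correlation of their SPC snippets at the best lag — and the
resulting matrix is clustered by average-linkage agglomeration.  Events in
major clusters gain confidence; outliers lose it.  A final threshold then
partitions candidates into accepted SDs and rejected artifacts (an event
classified artifact is rejected regardless of its confidence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .assembly import SdEvent
from .config import DetectorConfig

__all__ = [
    "SimilarityMatrix",
    "ClusterAssignment",
    "similarity_matrix",
    "cluster_events",
    "adjust_confidence",
    "apply_threshold",
    "stereotype",
]


@dataclass
class SimilarityMatrix:
    values: np.ndarray  # n x n in [0, 1], symmetric, unit diagonal
    event_ids: list[int]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix must have a unit diagonal")


@dataclass
class ClusterAssignment:
    labels: list[int]  # per-event cluster label
    major: dict[int, bool]  # cluster label -> major flag

    def is_major(self, event_index: int) -> bool:
        return self.major[self.labels[event_index]]


def _snippet_similarity(a: np.ndarray, b: np.ndarray, max_lag_frac: float = 0.25) -> float:
    """Cross-correlation of two snippets at the lag of maximal |correlation|.

    Keeping the sign at that lag means a sign-inverted copy scores -1, not
    +1: polarity is part of the stereotype.
    """
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    a, b = a / na, b / nb
    max_lag = int(round(max_lag_frac * len(a)))
    best = 0.0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            c = float(np.dot(a[lag:], b[: len(b) - lag]))
        else:
            c = float(np.dot(a[:lag], b[-lag:]))
        if abs(c) > abs(best):
            best = c
    return float(np.clip(best, -1.0, 1.0))


def similarity_matrix(events: list[SdEvent]) -> SimilarityMatrix:
    """Pairwise SPC-shape similarity in [0, 1].

    Entry (i, j) is the mean over shared channels of the max-|lag|
    cross-correlation, mapped from [-1, 1] to [0, 1]; event pairs sharing no
    channel get the uninformative 0.5.
    """
    if not events:
        raise ValueError("similarity_matrix needs at least one event")
    n = len(events)
    vals = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = []
            for m in events[i].members:
                other = events[j].member_on(m.channel)
                if other is not None:
                    shared.append(_snippet_similarity(m.snippet, other.snippet))
            s = (np.mean(shared) + 1.0) / 2.0 if shared else 0.5
            vals[i, j] = vals[j, i] = float(np.clip(s, 0.0, 1.0))
    return SimilarityMatrix(vals, [e.id for e in events])


def cluster_events(
    matrix: SimilarityMatrix, cfg: DetectorConfig | None = None
) -> ClusterAssignment:
    """Average-linkage clustering on distance 1 - similarity.

    The dendrogram is cut at ``cluster_cut_distance``; a cluster is *major*
    when its size reaches max(major_cluster_min, major_cluster_fraction x n).
    scipy's linkage on the condensed distance matrix breaks ties
    deterministically by event order.
    """
    cfg = cfg or DetectorConfig()
    n = matrix.values.shape[0]
    if n == 1:
        labels = [1]
    else:
        dist = 1.0 - matrix.values
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        Z = linkage(condensed, method="average")
        labels = [int(x) for x in fcluster(Z, t=cfg.cluster_cut_distance, criterion="distance")]
    min_size = max(cfg.major_cluster_min, cfg.major_cluster_fraction * n)
    sizes: dict[int, int] = {}
    for lab in labels:
        sizes[lab] = sizes.get(lab, 0) + 1
    major = {lab: size >= min_size for lab, size in sizes.items()}
    return ClusterAssignment(labels, major)


def adjust_confidence(
    events: list[SdEvent],
    assignment: ClusterAssignment,
    cfg: DetectorConfig | None = None,
) -> list[SdEvent]:
    """Boost major-cluster members, penalize outliers (clamped to [0, 100]).

    Classification is untouched: stereotyping never promotes an artifact into
    an SD, it only moves confidence.
    """
    cfg = cfg or DetectorConfig()
    for idx, ev in enumerate(events):
        delta = cfg.stereotype_boost if assignment.is_major(idx) else -cfg.outlier_penalty
        ev.confidence = float(np.clip(ev.confidence + delta, 0.0, 100.0))
    return events


def apply_threshold(
    events: list[SdEvent], threshold: float
) -> tuple[list[SdEvent], list[SdEvent]]:
    """Partition events into (accepted SDs, rejected artifacts).

    Accepted iff confidence >= threshold and the classification is not
    artifact.  Ordering is preserved.
    """
    accepted = [e for e in events if e.confidence >= threshold and e.classification != "artifact"]
    rejected = [e for e in events if not (e.confidence >= threshold and e.classification != "artifact")]
    return accepted, rejected


def stereotype(events: list[SdEvent], cfg: DetectorConfig | None = None) -> list[SdEvent]:
    """Full stereotyping pass over a candidate list (no-op when empty)."""
    cfg = cfg or DetectorConfig()
    if not events:
        return events
    m = similarity_matrix(events)
    assignment = cluster_events(m, cfg)
    return adjust_confidence(events, assignment, cfg)
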