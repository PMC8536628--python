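"""Scoring detector output against ground truth.

Conventions:

* events match annotations greedily, nearest in time first, one-to-one,
  within a tolerance (default +/-300 s); leftovers are false positives /
  false negatives;
* true negatives: the record is partitioned into 20-min periods (SDs recur
  at most about three per hour, so one SD occupies roughly 20 min of
  sampling time) and each period containing no verified SD onset counts as
  one true negative;
* sensitivity = TP / (TP + FN), explicitly *undefined* (None) when the
  denominator is zero — never silently 0;
* false-positive rate = FP / TN, undefined when TN = 0;
* record-level software counts regress on investigator counts by
  unconstrained ordinary least squares, with t-based 95% CIs;
* the ROC sweeps the confidence threshold 0..100 over the candidate list.
  The detection rate is measured against the annotations, so its ceiling
  sits below 1.0 whenever candidate generation missed events outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .assembly import SdEvent
from .config import DetectorConfig
from .io import GroundTruthAnnotation
from .stereotyping import apply_threshold

__all__ = [
    "MatchResult",
    "RegressionResult",
    "EvalReport",
    "match_events",
    "count_true_negatives",
    "sensitivity",
    "false_positive_rate",
    "regress_counts",
    "roc_curve",
    "evaluate_record",
]


@dataclass
class MatchResult:
    matched: list[tuple[float, float]]  # (software onset, annotation onset)
    false_positives: list[float]
    false_negatives: list[float]
    tn_count: int = 0

    @property
    def tp(self) -> int:
        return len(self.matched)

    @property
    def fp(self) -> int:
        return len(self.false_positives)

    @property
    def fn(self) -> int:
        return len(self.false_negatives)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    r_squared: float


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    fpr: float | None
    roc: list[tuple[float, float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "false_positive_rate": self.fpr,
            "roc": [list(p) for p in self.roc],
        }


def match_events(
    software_onsets: list[float] | np.ndarray,
    annotation_onsets: list[float] | np.ndarray,
    tolerance_s: float = 300.0,
) -> MatchResult:
    """Greedy nearest-in-time one-to-one matching within a tolerance."""
    soft = sorted(float(t) for t in software_onsets)
    truth = sorted(float(t) for t in annotation_onsets)
    pairs = [
        (abs(s - a), i, j)
        for i, s in enumerate(soft)
        for j, a in enumerate(truth)
        if abs(s - a) <= tolerance_s
    ]
    pairs.sort()
    used_s: set[int] = set()
    used_a: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i in used_s or j in used_a:
            continue
        used_s.add(i)
        used_a.add(j)
        matched.append((soft[i], truth[j]))
    fps = [s for i, s in enumerate(soft) if i not in used_s]
    fns = [a for j, a in enumerate(truth) if j not in used_a]
    return MatchResult(sorted(matched, key=lambda p: p[0]), fps, fns)


def count_true_negatives(
    duration_s: float,
    verified_onsets: list[float] | np.ndarray,
    cfg: DetectorConfig | None = None,
) -> int:
    """Number of 20-min periods not occupied by a verified SD onset."""
    cfg = cfg or DetectorConfig()
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    period = cfg.tn_period_minutes * 60.0
    n_periods = int(np.ceil(duration_s / period))
    occupied = {
        int(t // period) for t in verified_onsets if 0.0 <= t < duration_s
    }
    return n_periods - len(occupied)


def sensitivity(tp: int, fn: int) -> float | None:
    """TP / (TP + FN); None (undefined) when the denominator is zero."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        return None
    return tp / (tp + fn)


def false_positive_rate(fp: int, tn: int) -> float | None:
    """FP / TN over the silent 20-min periods; None when TN = 0."""
    if fp < 0 or tn < 0:
        raise ValueError("counts must be non-negative")
    if tn == 0:
        return None
    return fp / tn


def regress_counts(
    pairs: list[tuple[float, float]],
) -> RegressionResult:
    """Unconstrained OLS of software count on investigator count.

    pairs are (truth_count, software_count), one per record.  95% CIs use the
    t distribution on the coefficient standard errors.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 record pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all truth counts are equal")
    res = stats.linregress(x, y)
    dof = len(x) - 2
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.nan
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=(float(res.slope - tcrit * res.stderr), float(res.slope + tcrit * res.stderr)),
        intercept_ci=(
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        r_squared=float(res.rvalue**2),
    )


def roc_curve(
    candidates: list[SdEvent],
    annotations: list[GroundTruthAnnotation],
    duration_s: float,
    cfg: DetectorConfig | None = None,
) -> list[tuple[float, float, float]]:
    """Sweep the confidence threshold 0..100 in steps of 1.

    Returns (threshold, detection rate, false-positive rate) triples.  The
    detection rate denominator is the full annotation list; TN comes from the
    20-min convention on verified (annotated) SDs and does not vary with the
    threshold.
    """
    cfg = cfg or DetectorConfig()
    truth = [a.onset_s for a in annotations if a.label != "artifact"]
    tn = count_true_negatives(duration_s, truth, cfg)
    points = []
    for thr in range(0, 101):
        accepted, _ = apply_threshold(candidates, float(thr))
        m = match_events([e.onset_s for e in accepted], truth, cfg.match_tolerance_s)
        det = m.tp / len(truth) if truth else 0.0
        fpr = m.fp / tn if tn > 0 else 0.0
        points.append((float(thr), det, fpr))
    return points


def evaluate_record(
    accepted: list[SdEvent],
    annotations: list[GroundTruthAnnotation],
    duration_s: float,
    cfg: DetectorConfig | None = None,
    candidates: list[SdEvent] | None = None,
) -> EvalReport:
    """Full per-record report: matching, TN convention, rates, optional ROC."""
    cfg = cfg or DetectorConfig()
    truth = [a.onset_s for a in annotations if a.label != "artifact"]
    m = match_events([e.onset_s for e in accepted], truth, cfg.match_tolerance_s)
    tn = count_true_negatives(duration_s, truth, cfg)
    roc = roc_curve(candidates, annotations, duration_s, cfg) if candidates is not None else []
    return EvalReport(
        tp=m.tp,
        fp=m.fp,
        fn=m.fn,
        tn=tn,
        sensitivity=sensitivity(m.tp, m.fn),
        fpr=false_positive_rate(m.fp, tn),
        roc=roc,
    )
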