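"""Matching, the 20-min true-negative convention, rates, OLS and ROC."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sddetect.config import DetectorConfig
from sddetect.evaluation import (
    count_true_negatives,
    false_positive_rate,
    match_events,
    regress_counts,
    roc_curve,
    sensitivity,
)
from sddetect.io import GroundTruthAnnotation


class TestMatching:
    def test_within_tolerance_matches(self):
        m = match_events([100.0], [150.0], 300.0)
        assert m.tp == 1 and m.fp == 0 and m.fn == 0

    def test_outside_tolerance_fp_and_fn(self):
        m = match_events([100.0], [900.0], 300.0)
        assert m.tp == 0 and m.fp == 1 and m.fn == 1

    def test_two_events_one_annotation(self):
        m = match_events([140.0, 160.0], [150.0], 300.0)
        assert m.tp == 1 and m.fp == 1 and m.fn == 0
        assert m.matched[0] == (140.0, 150.0)  # nearest wins

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        soft=st.lists(st.floats(0, 80000), max_size=8),
        truth=st.lists(st.floats(0, 80000), max_size=8),
        shift=st.floats(-5000, 5000),
    )
    def test_shift_invariance(self, soft, truth, shift):
        a = match_events(soft, truth, 300.0)
        b = match_events([s + shift for s in soft], [t + shift for t in truth], 300.0)
        assert (a.tp, a.fp, a.fn) == (b.tp, b.fp, b.fn)


class TestTrueNegatives:
    def test_silent_24h_is_72(self, cfg):
        assert count_true_negatives(24 * 3600.0, [], cfg) == 72

    def test_occupied_periods_removed(self, cfg):
        onsets = [10 * 60.0, 200 * 60.0, 400 * 60.0]  # three distinct periods
        assert count_true_negatives(10 * 3600.0, onsets, cfg) == 27

    def test_two_sds_one_period_counted_once(self, cfg):
        assert count_true_negatives(3600.0, [60.0, 120.0], cfg) == 2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(onsets=st.lists(st.floats(0, 86399), max_size=20))
    def test_tn_plus_occupied_is_total(self, onsets):
        cfg = DetectorConfig()
        tn = count_true_negatives(86400.0, onsets, cfg)
        occupied = len({int(t // 1200) for t in onsets})
        assert tn + occupied == 72


class TestRates:
    def test_sensitivity_arithmetic(self):
        assert sensitivity(3, 1) == pytest.approx(0.75)
        assert sensitivity(1, 0) == 1.0

    def test_sensitivity_undefined_not_zero(self):
        assert sensitivity(0, 0) is None

    def test_fpr(self):
        assert false_positive_rate(0, 72) == 0.0
        assert false_positive_rate(2, 70) == pytest.approx(0.0286, abs=1e-4)
        assert false_positive_rate(0, 0) is None


class TestRegression:
    def test_identity_data(self):
        r = regress_counts([(0, 0), (5, 5), (10, 10), (20, 20)])
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)
        assert r.r_squared == pytest.approx(1.0)

    def test_hand_computed_design(self):
        # normal equations for (0,1),(10,9),(20,17): slope 0.8, intercept 1.0
        r = regress_counts([(0, 1), (10, 9), (20, 17)])
        assert r.slope == pytest.approx(0.8)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.uniform(0, 30, 12)
            y = 0.7 * x + rng.normal(0, 2, 12)
            r = regress_counts(list(zip(x, y)))
            X = np.column_stack([np.ones_like(x), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert r.intercept == pytest.approx(beta[0], abs=1e-9)
            assert r.slope == pytest.approx(beta[1], abs=1e-9)

    def test_degenerate_design_errors(self):
        with pytest.raises(ValueError):
            regress_counts([(5, 1), (5, 2), (5, 3)])
        with pytest.raises(ValueError):
            regress_counts([(1, 1), (2, 2)])


class TestRoc:
    def make_candidates(self, confs, onsets):
        from sddetect.assembly import LINK_NEW_ONSET, SdEvent
        from sddetect.features import SpcCandidate

        out = []
        for i, (c, t) in enumerate(zip(confs, onsets)):
            m = SpcCandidate(0, t, 300.0, "biphasic", 2.0, np.zeros(128), c)
            ev = SdEvent(i, [m], {0: LINK_NEW_ONSET})
            ev.confidence = c
            ev.classification = "CSD"
            out.append(ev)
        return out

    def test_sweep_shape_and_monotonicity(self, cfg):
        rng = np.random.default_rng(1)
        onsets = np.arange(10) * 3600.0 + 100.0
        cands = self.make_candidates(rng.uniform(0, 100, 10), onsets)
        anns = [GroundTruthAnnotation(t, "CSD") for t in onsets[:7]]
        roc = roc_curve(cands, anns, 12 * 3600.0, cfg)
        assert len(roc) == 101
        det = [p[1] for p in roc]
        fpr = [p[2] for p in roc]
        assert all(a >= b for a, b in zip(det, det[1:]))
        assert all(a >= b for a, b in zip(fpr, fpr[1:]))
        assert det[0] == max(det) and fpr[0] == max(fpr)

    def test_all_confidence_100_flat_sweep(self, cfg):
        onsets = [1000.0, 5000.0, 9000.0]
        cands = self.make_candidates([100.0] * 3, onsets)
        anns = [GroundTruthAnnotation(t, "CSD") for t in onsets]
        roc = roc_curve(cands, anns, 4 * 3600.0, cfg)
        assert roc[0][1] == roc[100][1] == 1.0

    def test_ceiling_below_one_when_candidates_missing(self, cfg):
        onsets = [1000.0, 5000.0, 9000.0, 13000.0]
        cands = self.make_candidates([90.0, 80.0], onsets[:2])  # two never generated
        anns = [GroundTruthAnnotation(t, "CSD") for t in onsets]
        roc = roc_curve(cands, anns, 5 * 3600.0, cfg)
        assert max(p[1] for p in roc) == pytest.approx(0.5)
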