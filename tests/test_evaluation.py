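"""Threshold-conditioned metrics: labeling, confusion, ROC/Youden, penalty."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st
from sklearn.metrics import roc_auc_score

from helpers import brute_force_youden, make_matches

from callrec import (
    ConfusionCounts,
    Match,
    SymbolicMatchConfig,
    TrueCall,
    conditional_metrics,
    confusion_at_threshold,
    label_matches,
    point_metrics,
    roc_and_threshold,
    subsample_penalty,
    synth_match_table,
)


def _call(rid="r0", start=0.0, end=1.0, n=2):
    return TrueCall(rid, start, end, n, "s0", "Y1")


class TestLabelMatches:
    def test_exact_cover_is_tp_and_silence_is_fp(self):
        calls = [_call(start=5.0, end=5.5)]
        matches = [Match("r0", 5.0, 5.5, 80.0), Match("r0", 20.0, 20.3, 40.0)]
        labeled = label_matches(matches, calls)
        assert [m.label for m in labeled] == ["TP", "FP"]

    def test_two_syllable_hits_per_match_vs_per_call(self):
        calls = [_call(start=5.0, end=5.5)]
        matches = [Match("r0", 5.0, 5.2, 80.0), Match("r0", 5.3, 5.5, 70.0)]
        per_match = label_matches(matches, calls, "per-match")
        assert [m.label for m in per_match] == ["TP", "TP"]
        per_call = label_matches(matches, calls, "per-call")
        assert sorted(m.label for m in per_call) == ["FP", "TP"]
        # the higher-scoring match claims the call
        assert next(m for m in per_call if m.label == "TP").score == 80.0

    def test_unknown_recording_rejected(self):
        with pytest.raises(ValueError, match="unknown recording"):
            label_matches(
                [Match("rX", 0.0, 1.0, 50.0)], [_call()], recording_ids={"r0"}
            )

    def test_match_in_known_callfree_recording_is_fp(self):
        labeled = label_matches(
            [Match("r1", 0.0, 1.0, 50.0)], [_call()], recording_ids={"r0", "r1"}
        )
        assert labeled[0].label == "FP"


class TestConfusion:
    def test_threshold_above_all_scores(self):
        calls = [_call(start=i * 2.0, end=i * 2.0 + 1) for i in range(3)]
        labeled = [Match("r0", 0.0, 1.0, 50.0, "TP"), Match("r0", 10.0, 10.5, 40.0, "FP")]
        c = confusion_at_threshold(labeled, calls, 99.0)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 3, 1)

    def test_zero_threshold_one_tp_per_call(self):
        calls = [_call(start=i * 2.0, end=i * 2.0 + 1) for i in range(2)]
        labeled = [
            Match("r0", 0.0, 1.0, 50.0, "TP"),
            Match("r0", 2.0, 3.0, 60.0, "TP"),
        ]
        c = confusion_at_threshold(labeled, calls, 0.0)
        assert c.fn == 0

    def test_worked_example_counts(self):
        """TP {80,70,65} on 3 distinct calls of 4, FP {60,20}, t=65."""
        calls = [_call(start=i * 10.0, end=i * 10.0 + 1) for i in range(4)]
        labeled = [
            Match("r0", 0.0, 1.0, 80.0, "TP"),
            Match("r0", 10.0, 11.0, 70.0, "TP"),
            Match("r0", 20.0, 21.0, 65.0, "TP"),
            Match("r0", 50.0, 50.5, 60.0, "FP"),
            Match("r0", 60.0, 60.5, 20.0, "FP"),
        ]
        c = confusion_at_threshold(labeled, calls, 65.0)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 0, 1, 2)
        cm = conditional_metrics(labeled, calls, 65.0)
        assert cm.precision == 1.0
        assert cm.sensitivity == 0.75

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


class TestPointMetrics:
    def test_precision_arithmetic(self):
        p, _ = point_metrics(ConfusionCounts(9, 1, 0, 0), 9)
        assert p == pytest.approx(0.9)

    def test_sensitivity_above_one_with_syllable_hits(self):
        """1500 TP matches over 1000 true calls -> sensitivity 1.5."""
        _, s = point_metrics(ConfusionCounts(1500, 0, 0, 0), 1000)
        assert s == pytest.approx(1.5)

    def test_undefined_marked_not_zero(self):
        p, s = point_metrics(ConfusionCounts(0, 0, 0, 0), 0)
        assert p is None and s is None


class TestROC:
    def test_complete_separation(self):
        roc = roc_and_threshold(make_matches([80, 70], [20]))
        assert roc.auroc == pytest.approx(1.0)
        assert roc.optimal_threshold == 70.0

    def test_indistinguishable_sets(self):
        roc = roc_and_threshold(make_matches([40, 60], [40, 60]))
        assert roc.auroc == pytest.approx(0.5)
        assert roc.youden_j.max() == pytest.approx(0.0)

    def test_mixed_example_max_j(self):
        roc = roc_and_threshold(make_matches([80, 30], [50]))
        assert roc.youden_j.max() == pytest.approx(0.5)
        assert roc.optimal_threshold == 80.0

    def test_requires_both_classes(self):
        with pytest.raises(ValueError, match="at least one TP and one FP"):
            roc_and_threshold(make_matches([80, 70], []))

    def test_curve_invariants(self):
        roc = roc_and_threshold(make_matches([90, 75, 60, 55], [70, 50, 20]))
        # thresholds descending -> tpr non-decreasing along the array
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.tnr) <= 0)
        np.testing.assert_allclose(roc.youden_j, roc.tpr + roc.tnr - 1.0)

    @hsettings(max_examples=120, derandomize=True, deadline=None)
    @given(
        tp=st.lists(st.integers(0, 100), min_size=1, max_size=25),
        fp=st.lists(st.integers(0, 100), min_size=1, max_size=25),
    )
    def test_matches_exhaustive_sweep_and_sklearn(self, tp, fp):
        labeled = make_matches(tp, fp)
        roc = roc_and_threshold(labeled)
        j_oracle, t_oracle = brute_force_youden(tp, fp)
        assert roc.youden_j.max() == j_oracle
        assert roc.optimal_threshold == t_oracle
        y = [1] * len(tp) + [0] * len(fp)
        assert roc.auroc == pytest.approx(
            roc_auc_score(y, list(map(float, tp + fp))), abs=1e-12
        )


class TestConditionalMetrics:
    def test_perfect_recognizer(self):
        calls = [_call(start=i * 3.0, end=i * 3.0 + 1) for i in range(3)]
        labeled = [
            Match("r0", i * 3.0, i * 3.0 + 1, 90.0, "TP") for i in range(3)
        ] + [Match("r0", 20.0, 20.5, 10.0, "FP")]
        t = roc_and_threshold(labeled).optimal_threshold
        cm = conditional_metrics(labeled, calls, t)
        assert cm.precision == 1.0 and cm.sensitivity == 1.0
        assert cm.type1_error == 0.0 and cm.type2_error == 0.0

    def test_symbolic_miss_rate_recovered(self):
        """miss_prob 0.5 with no FPs -> sensitivity about 0.5 at t=0."""
        calls = [
            TrueCall("r0", i * 3.0, i * 3.0 + 0.3, 1, "s0", "Y1") for i in range(400)
        ]
        cfg = SymbolicMatchConfig(miss_prob=0.5, fp_per_min=0.0, extra_hit_prob=0.0)
        labeled = synth_match_table(cfg, calls, 7, duration_s=1300.0)
        cm = conditional_metrics(labeled, calls, 0.0)
        sd = np.sqrt(400 * 0.25) / 400
        assert abs(cm.sensitivity - 0.5) < 3 * sd


def _enumerate_penalty(tp_scores, fp_scores, n_calls):
    """Exact mean of the subsampling penalty over all C(|TP|, N) subsets."""
    precs, senss = [], []
    for sub in itertools.combinations(tp_scores, n_calls):
        _, t = brute_force_youden(sub, fp_scores)
        tp_ret = sum(s >= t for s in sub)
        fp_ret = sum(s >= t for s in fp_scores)
        if tp_ret + fp_ret:
            precs.append(tp_ret / (tp_ret + fp_ret))
        senss.append(tp_ret / n_calls)
    return float(np.mean(precs)), float(np.mean(senss))


class TestSubsamplePenalty:
    def test_no_subsampling_branch_identity(self):
        calls = [_call(start=i * 3.0, end=i * 3.0 + 1) for i in range(5)]
        labeled = [
            Match("r0", i * 3.0, i * 3.0 + 1, 60.0 + i, "TP") for i in range(4)
        ] + [Match("r0", 40.0, 40.5, 30.0, "FP")]
        cm = subsample_penalty(labeled, calls, n_reps=50, seed=0)
        assert cm.penalized_precision == cm.precision
        assert cm.penalized_sensitivity == cm.sensitivity

    def test_worked_example_scales_sensitivity_to_one(self):
        """1000 calls, 1500 equal-score TPs, no FPs -> penalized sensitivity
        exactly 1."""
        calls = [
            TrueCall("r0", i * 2.0, i * 2.0 + 0.5, 2, "s0", "Y1") for i in range(1000)
        ]
        labeled = [Match("r0", i * 1.5, i * 1.5 + 0.4, 75.0, "TP") for i in range(1500)]
        cm = subsample_penalty(labeled, calls, n_reps=20, seed=1)
        assert cm.sensitivity == pytest.approx(1.5)
        assert cm.penalized_sensitivity == pytest.approx(1.0, abs=0)

    def test_matches_exhaustive_enumeration(self):
        """Two TP score strata with FPs in between: the randomized penalty
        converges to the exact mean over all C(6,4) subsets."""
        calls = [_call(start=i * 3.0, end=i * 3.0 + 1) for i in range(4)]
        tp_scores = [90.0, 88.0, 86.0, 40.0, 38.0, 36.0]
        fp_scores = [60.0, 55.0]
        labeled = [
            Match("r0", (i % 4) * 3.0, (i % 4) * 3.0 + 1, s, "TP")
            for i, s in enumerate(tp_scores)
        ] + [Match("r0", 30.0 + i, 30.5 + i, s, "FP") for i, s in enumerate(fp_scores)]
        exact_p, exact_s = _enumerate_penalty(tp_scores, fp_scores, 4)
        cm = subsample_penalty(labeled, calls, n_reps=5000, seed=3)
        assert cm.penalized_precision == pytest.approx(exact_p, abs=0.02)
        assert cm.penalized_sensitivity == pytest.approx(exact_s, abs=0.02)

    def test_penalized_sensitivity_never_exceeds_one(self, rng):
        for trial in range(10):
            n_calls = int(rng.integers(2, 6))
            n_tp = int(rng.integers(n_calls, 3 * n_calls))
            calls = [_call(start=i * 3.0, end=i * 3.0 + 1) for i in range(n_calls)]
            labeled = [
                Match("r0", (i % n_calls) * 3.0, (i % n_calls) * 3.0 + 1,
                      float(rng.uniform(10, 95)), "TP")
                for i in range(n_tp)
            ] + [
                Match("r0", 200.0 + i, 200.5 + i, float(rng.uniform(5, 90)), "FP")
                for i in range(int(rng.integers(0, 4)))
            ]
            cm = subsample_penalty(labeled, calls, n_reps=200, seed=trial)
            assert cm.penalized_sensitivity <= 1.0 + 1e-12

    def test_zero_calls_rejected(self):
        with pytest.raises(ValueError, match="zero true calls"):
            subsample_penalty([Match("r0", 0.0, 1.0, 50.0, "TP")], [], n_reps=10)

    def test_deterministic_given_seed(self):
        calls = [_call(start=i * 3.0, end=i * 3.0 + 1) for i in range(3)]
        labeled = [
            Match("r0", (i % 3) * 3.0, (i % 3) * 3.0 + 1, float(20 + 10 * i), "TP")
            for i in range(7)
        ] + [Match("r0", 50.0, 50.5, 45.0, "FP")]
        a = subsample_penalty(labeled, calls, n_reps=100, seed=9)
        b = subsample_penalty(labeled, calls, n_reps=100, seed=9)
        assert a == b


class TestInvariants:
    def test_per_call_conservation(self, rng):
        """In per-call mode tp + fn = n_calls at every threshold."""
        calls = [_call(start=i * 4.0, end=i * 4.0 + 1) for i in range(5)]
        matches = []
        for _ in range(15):
            start = float(rng.uniform(0, 20))
            matches.append(
                Match("r0", start, start + 1.0, float(rng.uniform(0, 100)))
            )
        labeled = label_matches(matches, calls, "per-call")
        for t in (0.0, 25.0, 50.0, 75.0, 101.0):
            c = confusion_at_threshold(labeled, calls, t)
            assert c.tp + c.fn == len(calls)

    def test_auroc_grows_with_score_gap(self):
        aurocs = []
        for gap in (0.0, 20.0, 60.0):
            rng = np.random.default_rng(5)
            tp = np.clip(rng.normal(40 + gap, 8, 60), 0, 100)
            fp = np.clip(rng.normal(40 - gap / 4, 8, 60), 0, 100)
            aurocs.append(roc_and_threshold(make_matches(tp, fp)).auroc)
        assert aurocs[0] < aurocs[1] < aurocs[2]
        assert aurocs[2] > 0.99

    def test_precision_sensitivity_monotone_when_separated(self):
        """When TP scores dominate FP scores, raising the threshold never
        lowers precision nor raises sensitivity."""
        calls = [_call(start=i * 3.0, end=i * 3.0 + 1) for i in range(4)]
        labeled = [
            Match("r0", i * 3.0, i * 3.0 + 1, 70.0 + 5 * i, "TP") for i in range(4)
        ] + [Match("r0", 100.0 + i, 100.5 + i, 20.0 + 5 * i, "FP") for i in range(4)]
        prev_p, prev_s = 0.0, np.inf
        for t in (0.0, 22.0, 40.0, 72.0, 80.0, 90.0):
            c = confusion_at_threshold(labeled, calls, t)
            p, s = point_metrics(c, len(calls))
            if p is not None:
                assert p >= prev_p
                prev_p = p
            assert s <= prev_s
            prev_s = s
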