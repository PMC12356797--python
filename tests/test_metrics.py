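"""Diagnostic accuracy metrics against brute-force oracles, and the
behaviour of the case-resampling bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asbestriage import (
    ConfusionCounts,
    bootstrap_ci,
    compare_auc_paired,
    confusion,
    point_metrics,
    pr_auc,
    roc_auc,
)

# ---------------------------------------------------------------------------
# oracles


def _confusion_loop(pred, ref):
    tp = fp = tn = fn = 0
    for p, r in zip(pred, ref):
        if p == 1 and r == 1:
            tp += 1
        elif p == 1 and r == 0:
            fp += 1
        elif p == 0 and r == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def _auc_pairwise(scores, ref):
    pos = [s for s, r in zip(scores, ref) if r == 1]
    neg = [s for s, r in zip(scores, ref) if r == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def _average_precision_enum(scores, ref):
    """Stepwise AP over descending unique-score thresholds."""
    scores = np.asarray(scores, float)
    ref = np.asarray(ref, int)
    n_pos = ref.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        called = scores >= t
        tp = int(ref[called].sum())
        precision = tp / called.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


# ---------------------------------------------------------------------------
# confusion and point metrics


@given(
    st.lists(
        st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=60
    )
)
@settings(max_examples=200, deadline=None)
def test_confusion_matches_loop_oracle(pairs):
    pred, ref = zip(*pairs)
    c = confusion(pred, ref)
    assert (c.tp, c.fp, c.tn, c.fn) == _confusion_loop(pred, ref)
    assert c.n == len(pairs)


def test_confusion_validates_input():
    with pytest.raises(ValueError):
        confusion([1, 0], [1])
    with pytest.raises(ValueError):
        confusion([], [])


def test_perfect_agreement_has_no_errors(rng):
    labels = rng.integers(0, 2, size=30)
    c = confusion(labels, labels)
    assert c.fp == c.fn == 0


def test_point_metrics_formulas(rng):
    for _ in range(20):
        tp, fp, tn, fn = (int(v) for v in rng.integers(1, 50, size=4))
        m = point_metrics(ConfusionCounts(tp, fp, tn, fn))
        assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
        assert m["specificity"] == pytest.approx(tn / (tn + fp))
        assert m["accuracy"] == pytest.approx((tp + tn) / (tp + fp + tn + fn))
        assert m["ppv"] == pytest.approx(tp / (tp + fp))
        assert m["npv"] == pytest.approx(tn / (tn + fn))
        # accuracy identity: prevalence-weighted mix of sens and spec
        prev = (tp + fn) / (tp + fp + tn + fn)
        assert m["accuracy"] == pytest.approx(
            prev * m["sensitivity"] + (1 - prev) * m["specificity"]
        )


def test_balanced_table_gives_half():
    m = point_metrics(ConfusionCounts(7, 7, 7, 7))
    assert all(v == pytest.approx(0.5) for v in m.values())


def test_zero_denominator_flagged_not_zero():
    m = point_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=0))
    assert math.isnan(m["sensitivity"])
    assert math.isnan(m["ppv"])
    assert m["specificity"] == 1.0


# ---------------------------------------------------------------------------
# ranking metrics


def test_roc_auc_trivials():
    assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
    assert roc_auc([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5
    assert math.isnan(roc_auc([1, 2], [1, 1]))


@given(
    scores=st.lists(st.integers(0, 5), min_size=2, max_size=40),
    data=st.data(),
)
@settings(max_examples=200, deadline=None)
def test_roc_auc_matches_pairwise_oracle(scores, data):
    n = len(scores)
    ref = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    if len(set(ref)) < 2:
        ref = [0] * (n // 2) + [1] * (n - n // 2)
    assert roc_auc(scores, ref) == pytest.approx(_auc_pairwise(scores, ref))


def test_roc_auc_invariant_under_monotone_transform(rng):
    scores = rng.uniform(0, 100, size=50)
    ref = rng.integers(0, 2, size=50)
    ref[:2] = [0, 1]
    a = roc_auc(scores, ref)
    assert roc_auc(np.exp(scores / 25.0), ref) == pytest.approx(a)
    assert roc_auc(np.argsort(np.argsort(scores)).astype(float), ref) == pytest.approx(a)


def test_pr_auc_trivials():
    assert pr_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
    assert math.isnan(pr_auc([1, 2], [0, 0]))


def test_pr_auc_matches_enumeration_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(5, 40))
        scores = rng.integers(0, 8, size=n).astype(float)  # force ties
        ref = rng.integers(0, 2, size=n)
        ref[0] = 1
        assert pr_auc(scores, ref) == pytest.approx(
            _average_precision_enum(scores, ref)
        )


def test_pr_auc_of_uninformative_scores_approaches_prevalence(rng):
    n, p = 20_000, 0.3
    ref = (rng.random(n) < p).astype(int)
    scores = rng.random(n)
    assert pr_auc(scores, ref) == pytest.approx(p, abs=0.02)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_constant_statistic_zero_width():
    est = bootstrap_ci(lambda x: 0.7, [np.ones(30)], name="const", n_boot=200, seed=1)
    assert est.ci_low == est.ci_high == est.point == 0.7
    assert est.n_skipped == 0


def test_bootstrap_deterministic_under_seed(rng):
    pred = rng.integers(0, 2, size=80)
    ref = rng.integers(0, 2, size=80)
    stat = lambda p, r: point_metrics(confusion(p, r))["sensitivity"]  # noqa: E731
    e1 = bootstrap_ci(stat, (pred, ref), n_boot=500, seed=9)
    e2 = bootstrap_ci(stat, (pred, ref), n_boot=500, seed=9)
    assert e1 == e2
    assert 0.0 <= e1.ci_low <= e1.point <= e1.ci_high <= 1.0


def test_bootstrap_counts_degenerate_resamples():
    # one positive in 8 cases: many resamples lack positives entirely
    ref = np.array([1, 0, 0, 0, 0, 0, 0, 0])
    pred = ref.copy()
    stat = lambda p, r: point_metrics(confusion(p, r))["sensitivity"]  # noqa: E731
    est = bootstrap_ci(stat, (pred, ref), n_boot=2000, seed=3)
    assert est.n_skipped > 0
    assert est.point == 1.0


def test_bootstrap_all_degenerate_is_error():
    ref = np.zeros(5, dtype=int)
    stat = lambda p, r: point_metrics(confusion(p, r))["sensitivity"]  # noqa: E731
    with pytest.raises(ValueError, match="all"):
        bootstrap_ci(stat, (ref, ref), n_boot=50, seed=0)


# ---------------------------------------------------------------------------
# paired AUC comparison


def test_identical_scores_give_null_comparison(rng):
    scores = rng.uniform(0, 1, size=40)
    ref = rng.integers(0, 2, size=40)
    ref[:2] = [0, 1]
    cmp = compare_auc_paired(scores, scores, ref)
    assert cmp.diff == 0.0
    assert cmp.p_value == 1.0


def test_delong_auc_matches_mann_whitney(rng):
    for _ in range(10):
        scores = rng.uniform(0, 1, size=30)
        other = rng.uniform(0, 1, size=30)
        ref = rng.integers(0, 2, size=30)
        ref[:2] = [0, 1]
        cmp = compare_auc_paired(scores, other, ref)
        assert cmp.auc_a == pytest.approx(roc_auc(scores, ref))
        assert cmp.auc_b == pytest.approx(roc_auc(other, ref))


def test_delong_type_one_error_near_nominal(rng):
    """Independent uninformative score pairs reject H0 at about the nominal
    5% rate (two-sided DeLong)."""
    rejections = 0
    n_sim = 400
    for _ in range(n_sim):
        ref = rng.integers(0, 2, size=120)
        ref[:2] = [0, 1]
        a = rng.standard_normal(120)
        b = rng.standard_normal(120)
        if compare_auc_paired(a, b, ref).p_value < 0.05:
            rejections += 1
    assert rejections / n_sim == pytest.approx(0.05, abs=0.03)


def test_paired_bootstrap_method(rng):
    scores = rng.uniform(0, 1, size=40)
    shifted = scores + rng.normal(0, 0.05, size=40)
    ref = (scores + rng.normal(0, 0.3, size=40) > 0.5).astype(int)
    ref[:2] = [0, 1]
    cmp = compare_auc_paired(scores, shifted, ref, method="bootstrap",
                             n_boot=500, seed=11)
    assert cmp.method == "bootstrap"
    assert 0.0 <= cmp.p_value <= 1.0
    with pytest.raises(ValueError):
        compare_auc_paired(scores, shifted, ref, method="wilcoxon")


def test_single_class_comparison_rejected():
    with pytest.raises(ValueError):
        compare_auc_paired([1, 2], [2, 1], [1, 1])
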