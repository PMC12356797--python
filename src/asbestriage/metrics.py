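"""Diagnostic accuracy of the index test against the reference standard.

Point metrics from the 2x2 table, ranking metrics (ROC-AUC as the
Mann-Whitney probability with half-credit for ties, PR-AUC as average
precision), case-resampling percentile bootstrap confidence intervals, and a
paired comparison of two correlated AUCs (DeLong, with a paired-bootstrap
alternative).

Undefined quantities (a metric with a zero denominator, an AUC on a
single-class sample) are returned as ``nan`` rather than silently coerced to
zero; bootstrap resamples on which the statistic is undefined are skipped and
counted in the estimate's ``n_skipped``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricEstimate",
    "confusion",
    "point_metrics",
    "roc_auc",
    "pr_auc",
    "bootstrap_ci",
    "compare_auc_paired",
    "AucComparison",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricEstimate:
    """A point estimate with its percentile-bootstrap confidence interval."""

    name: str
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_skipped: int = 0

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_skipped": self.n_skipped,
        }


def confusion(pred: Sequence[int], ref: Sequence[int]) -> ConfusionCounts:
    """2x2 cross-tabulation of index verdicts against reference labels."""
    p = np.asarray(pred, dtype=int)
    r = np.asarray(ref, dtype=int)
    if p.shape != r.shape or p.ndim != 1 or p.size == 0:
        raise ValueError(
            f"pred and ref must be equal-length 1-d arrays, got {p.shape} vs {r.shape}"
        )
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (r == 1))),
        fp=int(np.sum((p == 1) & (r == 0))),
        tn=int(np.sum((p == 0) & (r == 0))),
        fn=int(np.sum((p == 0) & (r == 1))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def point_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, PPV and NPV from a 2x2 table.

    A metric whose denominator is zero is reported as ``nan``.
    """
    return {
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "accuracy": _ratio(c.tp + c.tn, c.n),
        "ppv": _ratio(c.tp, c.tp + c.fp),
        "npv": _ratio(c.tn, c.tn + c.fn),
    }


def roc_auc(scores: Sequence[float], ref: Sequence[int]) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney probability that a random positive outscores a
    random negative, with ties counted half.  Returns ``nan`` when only one
    class is present.
    """
    s = np.asarray(scores, dtype=float)
    r = np.asarray(ref, dtype=int)
    if s.shape != r.shape:
        raise ValueError("scores and ref must have equal length")
    if len(np.unique(r)) < 2:
        return math.nan
    return float(roc_auc_score(r, s))


def pr_auc(scores: Sequence[float], ref: Sequence[int]) -> float:
    """Area under the precision-recall curve as average precision.

    Step-wise sum of precision times recall increments over descending score
    thresholds (no linear interpolation).  Returns ``nan`` without positives.
    """
    s = np.asarray(scores, dtype=float)
    r = np.asarray(ref, dtype=int)
    if s.shape != r.shape:
        raise ValueError("scores and ref must have equal length")
    if not np.any(r == 1):
        return math.nan
    return float(average_precision_score(r, s))


def bootstrap_ci(
    statistic: Callable[..., float],
    data: Sequence[Sequence],
    name: str = "statistic",
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> MetricEstimate:
    """Case-resampling percentile bootstrap CI for an arbitrary statistic.

    Parameters
    ----------
    statistic
        Callable receiving one resampled array per element of ``data`` and
        returning a float; ``nan`` marks the statistic undefined on that
        resample (e.g. a class missing), in which case the resample is
        skipped and counted.
    data
        Equal-length per-case arrays (e.g. predictions and reference labels)
        resampled jointly with replacement.
    n_boot, seed, alpha
        Resample count (default 10,000), RNG seed, and two-sided level.

    Raises
    ------
    ValueError
        If every resample is degenerate.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    arrays = [np.asarray(a) for a in data]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all data arrays must have equal length")
    point = float(statistic(*arrays))

    rng = np.random.default_rng(seed)
    indices = rng.integers(0, n, size=(n_boot, n))
    values = np.empty(n_boot)
    for b in range(n_boot):
        idx = indices[b]
        values[b] = statistic(*(a[idx] for a in arrays))
    ok = ~np.isnan(values)
    n_skipped = int(n_boot - ok.sum())
    if not ok.any():
        raise ValueError(f"{name}: statistic undefined on all {n_boot} resamples")
    lo, hi = np.percentile(values[ok], [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return MetricEstimate(
        name=name,
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# paired AUC comparison

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_placements(scores: np.ndarray, ref: np.ndarray):
    """Per-case placement values whose means are the AUC (DeLong construction)."""
    pos = scores[ref == 1]
    neg = scores[ref == 0]
    m, k = len(pos), len(neg)
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    v_pos = (all_ranks[:m] - pos_ranks) / k
    v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = (all_ranks[:m].sum() / m - (m + 1) / 2.0) / k
    return auc, v_pos, v_neg


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    diff: float
    p_value: float
    method: str


def compare_auc_paired(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    ref: Sequence[int],
    method: str = "delong",
    n_boot: int = 10_000,
    seed: int = 0,
) -> AucComparison:
    """Two-sided comparison of two correlated ROC-AUCs on the same cases.

    ``method="delong"`` uses the DeLong covariance of the paired placement
    values; ``method="bootstrap"`` resamples cases jointly and reports the
    two-sided bootstrap p-value of the AUC difference.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    r = np.asarray(ref, dtype=int)
    if not (a.shape == b.shape == r.shape):
        raise ValueError("scores_a, scores_b and ref must have equal length")
    if len(np.unique(r)) < 2:
        raise ValueError("paired AUC comparison needs both classes present")

    auc_a, pa, na = _delong_placements(a, r)
    auc_b, pb, nb = _delong_placements(b, r)
    diff = auc_a - auc_b

    if method == "delong":
        m, k = len(pa), len(na)
        s_pos = np.cov(np.vstack([pa, pb])) if m > 1 else np.zeros((2, 2))
        s_neg = np.cov(np.vstack([na, nb])) if k > 1 else np.zeros((2, 2))
        cov = s_pos / m + s_neg / k
        var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
        if var <= 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            z = diff / math.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
        return AucComparison(float(auc_a), float(auc_b), float(diff), float(p), "delong")

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(r)
        diffs = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            rr = r[idx]
            if len(np.unique(rr)) < 2:
                continue
            diffs.append(roc_auc(a[idx], rr) - roc_auc(b[idx], rr))
        diffs = np.asarray(diffs)
        if diffs.size == 0:
            raise ValueError("all bootstrap resamples were single-class")
        # two-sided p: twice the smaller tail of the centred resample
        # distribution against zero difference
        p_low = np.mean(diffs - diff <= -abs(diff))
        p_high = np.mean(diffs - diff >= abs(diff))
        p = float(min(1.0, 2.0 * min(p_low, p_high)))
        return AucComparison(float(auc_a), float(auc_b), float(diff), p, "bootstrap")

    raise ValueError(f"unknown method {method!r}; use 'delong' or 'bootstrap'")
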