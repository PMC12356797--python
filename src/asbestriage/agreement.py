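"""Interobserver agreement statistics.

The free-marginal (Randolph) kappa corrects observed pairwise agreement by a
fixed chance level of 1/c (0.5 for binary verdicts), making it insensitive
to how skewed the observed verdict marginals are — appropriate when raters
are not constrained to a quota of positives.  The Fleiss kappa, provided for
contrast, estimates chance agreement from the empirical category marginals
and is undefined when all ratings fall in one category.

Items with a missing rating are excluded listwise (with a count) rather than
imputed, mirroring how incomplete panels are handled in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

if TYPE_CHECKING:  # pragma: no cover
    from .cohort_sim import CaseRecord

__all__ = [
    "RatingsMatrix",
    "randolph_kappa",
    "fleiss_kappa",
    "subgroup_kappas",
    "kappa_bootstrap_ci",
    "kendall_tau",
    "KappaEstimate",
]


class RatingsMatrix:
    """Items x raters matrix of categorical ratings.

    Parameters
    ----------
    ratings
        2-d array-like, one row per item, one column per rater.  Rows
        containing a missing rating (``None`` / ``nan``) are dropped and
        counted in ``n_excluded``.
    n_categories
        Number of nominal categories (default 2, binary verdicts).
    """

    def __init__(self, ratings, n_categories: int = 2):
        arr = np.asarray(ratings, dtype=object)
        if arr.ndim != 2:
            raise ValueError(f"ratings must be 2-d (items x raters), got ndim={arr.ndim}")
        missing = np.array(
            [
                any(v is None or (isinstance(v, float) and math.isnan(v)) for v in row)
                for row in arr
            ],
            dtype=bool,
        )
        kept = arr[~missing]
        self.values = kept.astype(int) if kept.size else np.empty((0, arr.shape[1]), int)
        self.n_excluded = int(missing.sum())
        self.n_categories = n_categories
        if self.values.size and (
            self.values.min() < 0 or self.values.max() >= n_categories
        ):
            raise ValueError(
                f"ratings must lie in 0..{n_categories - 1}, got range "
                f"[{self.values.min()}, {self.values.max()}]"
            )

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_cases(
        cls, cohort: Iterable["CaseRecord"], include_index_reviewers: bool = False
    ) -> "RatingsMatrix":
        """Reference-panel ratings of a cohort; optionally the five-rater
        matrix joining the two escalation reviewers (cases without escalation
        verdicts are then excluded as incomplete)."""
        rows = []
        for case in cohort:
            row = list(case.ref_verdicts)
            if include_index_reviewers:
                row += list(case.index_verdicts) if len(case.index_verdicts) == 2 else [None, None]
            rows.append(row)
        return cls(rows)


def _mean_pairwise_agreement(values: np.ndarray) -> float:
    """Mean over items of the fraction of agreeing rater pairs."""
    n, m = values.shape
    pairs = m * (m - 1) / 2.0
    agree = np.zeros(n)
    for c in range(int(values.max(initial=0)) + 1):
        k = (values == c).sum(axis=1)
        agree += k * (k - 1) / 2.0
    return float(np.mean(agree / pairs))


def randolph_kappa(R: RatingsMatrix) -> float:
    """Free-marginal multirater kappa.

    ``(Po - 1/c) / (1 - 1/c)`` where ``Po`` is the mean per-item proportion
    of agreeing rater pairs and ``c`` the number of categories; for binary
    verdicts the chance term is 0.5.
    """
    if R.n_items < 1:
        raise ValueError("randolph_kappa needs at least one complete item")
    if R.n_raters < 2:
        raise ValueError("randolph_kappa needs at least two raters")
    po = _mean_pairwise_agreement(R.values)
    pe = 1.0 / R.n_categories
    return (po - pe) / (1.0 - pe)


def fleiss_kappa(R: RatingsMatrix) -> float:
    """Fleiss multirater kappa with empirical-marginal chance correction.

    Returns ``nan`` when the marginals are degenerate (all ratings in one
    category), where chance agreement is 1 and the statistic is undefined.
    """
    if R.n_items < 1 or R.n_raters < 2:
        raise ValueError("fleiss_kappa needs >= 1 item and >= 2 raters")
    counts, _ = aggregate_raters(R.values, n_cat=R.n_categories)
    marginals = counts.sum(axis=0) / counts.sum()
    if np.max(marginals) >= 1.0:
        return math.nan
    return float(_sm_fleiss(counts))


def subgroup_kappas(
    R: RatingsMatrix, groups: Sequence
) -> dict:
    """Randolph kappa per stratum plus the pooled value.

    ``groups`` assigns a stratum label to each *complete* item of ``R`` (in
    row order).  Returns ``{label: (kappa, n_items)}`` with key ``"overall"``
    for the pooled matrix; empty strata are simply absent.
    """
    groups = np.asarray(groups, dtype=object)
    if len(groups) != R.n_items:
        raise ValueError(
            f"groups length {len(groups)} != number of complete items {R.n_items}"
        )
    out = {"overall": (randolph_kappa(R), R.n_items)}
    for g in dict.fromkeys(groups):  # preserve first-appearance order
        mask = groups == g
        sub = RatingsMatrix(R.values[mask], n_categories=R.n_categories)
        out[g] = (randolph_kappa(sub), int(mask.sum()))
    return out


@dataclass(frozen=True)
class KappaEstimate:
    point: float
    ci_low: float
    ci_high: float
    n_items: int
    n_boot: int
    seed: int


def kappa_bootstrap_ci(
    R: RatingsMatrix,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    statistic=randolph_kappa,
) -> KappaEstimate:
    """Percentile bootstrap CI for a multirater kappa, resampling items."""
    if R.n_items < 2:
        raise ValueError("kappa bootstrap needs at least two items")
    rng = np.random.default_rng(seed)
    point = statistic(R)
    values = np.empty(n_boot)
    idx = rng.integers(0, R.n_items, size=(n_boot, R.n_items))
    for b in range(n_boot):
        values[b] = statistic(RatingsMatrix(R.values[idx[b]], R.n_categories))
    ok = ~np.isnan(values)
    lo, hi = np.percentile(values[ok], [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return KappaEstimate(
        point=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        n_items=R.n_items,
        n_boot=n_boot,
        seed=seed,
    )


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall tau-b rank correlation (tie-corrected).

    Returns ``nan`` when either vector has zero variance.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 2:
        raise ValueError("kendall_tau needs two equal-length vectors of length >= 2")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return math.nan
    tau, _ = _sps.kendalltau(xa, ya)
    return float(tau)
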