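"""Reference standard and blinded reviewer allocation.

The reference standard is the majority verdict of a three-pulmonologist
panel: a case is reference-positive when at least two of the three verdicts
are positive.  The allocation simulator mimics the blinded draw used to
assign reviewers: per case, five distinct form numbers are drawn uniformly
without replacement from the pool — the first three go to the reference
panel, the remaining two to the escalation (index) reviewers — while the
mapping from form numbers to actual reviewers is reshuffled at fixed period
boundaries, emulating the periodic regrouping of the pool.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional, Sequence, Tuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .cohort_sim import CaseRecord

__all__ = [
    "PanelAssignment",
    "MissingVerdictError",
    "adjudicate_panel",
    "allocate_reviewers",
    "reference_labels",
]


class MissingVerdictError(ValueError):
    """A reference panel is incomplete; the case cannot be adjudicated."""


@dataclass(frozen=True)
class PanelAssignment:
    """Reviewer allocation for one case: three reference + two index
    reviewers, all distinct, drawn from a pool of ``n_rater_pool``."""

    case_id: str
    reference_reviewers: Tuple[int, int, int]
    index_reviewers: Tuple[int, int]
    period: int

    def __post_init__(self) -> None:
        ids = self.reference_reviewers + self.index_reviewers
        if len(set(ids)) != 5:
            raise ValueError(f"case {self.case_id}: reviewer indices not distinct: {ids}")


def adjudicate_panel(verdicts: Sequence[Optional[int]]) -> int:
    """Majority verdict of a three-member panel (positive iff >= 2 positives)."""
    if len(verdicts) != 3:
        raise MissingVerdictError(
            f"reference panel needs exactly three verdicts, got {len(verdicts)}"
        )
    if any(v is None for v in verdicts):
        raise MissingVerdictError(f"missing reviewer verdict in panel {verdicts!r}")
    if any(v not in (0, 1) for v in verdicts):
        raise ValueError(f"verdicts must be 0 or 1, got {verdicts!r}")
    return int(sum(verdicts) >= 2)


def allocate_reviewers(
    case_ids: Sequence[str],
    n_pool: int = 13,
    period_length: int = 12,
    seed: int = 0,
) -> list[PanelAssignment]:
    """Simulate the blinded reviewer draw for a sequence of cases.

    Parameters
    ----------
    case_ids
        Cases in accrual order.
    n_pool
        Reviewer pool size (must allow 3 + 2 distinct reviewers).
    period_length
        Number of consecutive cases per regrouping period; the form-number
        to reviewer mapping is re-drawn at each period boundary.  The study
        design regroups on calendar time (three months); the simulator has
        no calendar, so periods are counted in cases.
    seed
        Makes the whole assignment table reproducible.
    """
    if n_pool < 5:
        raise ValueError(f"n_pool must be >= 5, got {n_pool}")
    if period_length < 1:
        raise ValueError(f"period_length must be >= 1, got {period_length}")
    rng = np.random.default_rng(seed)
    assignments: list[PanelAssignment] = []
    mapping = np.arange(n_pool)
    for i, cid in enumerate(case_ids):
        period = i // period_length
        if i % period_length == 0:
            mapping = rng.permutation(n_pool)
        draw = rng.choice(n_pool, size=5, replace=False)
        reviewers = mapping[draw]
        assignments.append(
            PanelAssignment(
                case_id=str(cid),
                reference_reviewers=tuple(int(r) for r in reviewers[:3]),
                index_reviewers=tuple(int(r) for r in reviewers[3:]),
                period=period,
            )
        )
    return assignments


def reference_labels(
    cohort: Iterable["CaseRecord"],
) -> tuple[np.ndarray, dict[int, int]]:
    """Per-case majority labels and the distribution of positive-verdict counts.

    Returns
    -------
    labels
        Integer array of majority verdicts, one per case.
    verdict_count_distribution
        Mapping ``{0: n0, 1: n1, 2: n2, 3: n3}`` of cases by their number of
        positive panel verdicts; reference positives are ``n2 + n3``.

    Raises
    ------
    MissingVerdictError
        If any case has an incomplete panel, naming the case.
    """
    labels = []
    dist: Counter = Counter({0: 0, 1: 0, 2: 0, 3: 0})
    for case in cohort:
        try:
            labels.append(adjudicate_panel(case.ref_verdicts))
        except MissingVerdictError as err:
            raise MissingVerdictError(f"case {case.case_id}: {err}") from err
        dist[sum(case.ref_verdicts)] += 1
    return np.asarray(labels, dtype=int), dict(sorted(dist.items()))
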