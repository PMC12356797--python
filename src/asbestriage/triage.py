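"""The AI-driven index test: score triage, escalation, final verdict.

The index test maps an AI asbestosis probability score (0-100) to one of
three categories: scores below the lower cutoff (default 35) are immediately
negative, scores at or above the upper cutoff (default 66) immediately
positive, and scores in between are *uncertain* and escalated to two
independent reviewers.  For escalated cases the final asbestosis score is the
mean of the AI score and the two reviewer verdicts on a common 0-100 scale::

    final = (ai_score + 100 * r1 + 100 * r2) / 3

and the case is called positive when the final score is >= 50.  Two
consequences of this arithmetic, asserted by the test suite: when the two
reviewers agree they always decide the case (both positive forces
final >= (35 + 200)/3 > 50; both negative forces final <= 66/3 < 50), and
when they split the verdict reduces to ``ai_score >= 50``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING, Callable, Iterable, Optional

if TYPE_CHECKING:  # pragma: no cover - import cycle with cohort_sim
    from .cohort_sim import CaseRecord

__all__ = [
    "Category",
    "TriageThresholds",
    "IndexOutcome",
    "TriageSummary",
    "EscalationIncompleteError",
    "DEFAULT_THRESHOLDS",
    "categorize_score",
    "final_score",
    "run_index_test",
    "apply_index_test",
    "triage_summary",
]


class Category(str, Enum):
    """Triage category of the AI probability score."""

    NEGATIVE = "negative"
    UNCERTAIN = "uncertain"
    POSITIVE = "positive"


class EscalationIncompleteError(ValueError):
    """An uncertain case reached final scoring without two reviewer verdicts."""


@dataclass(frozen=True)
class TriageThresholds:
    """Cutoffs of the index test.

    ``negative_below`` and ``positive_at_or_above`` bound the uncertain band
    ``[negative_below, positive_at_or_above)``; ``final_positive_at_or_above``
    thresholds the final asbestosis score of escalated cases.  The upper
    cutoff is inclusive (a score of exactly 66.0 is auto-positive).
    """

    negative_below: float = 35.0
    positive_at_or_above: float = 66.0
    final_positive_at_or_above: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.negative_below < self.positive_at_or_above <= 100.0:
            raise ValueError(
                "need 0 <= negative_below < positive_at_or_above <= 100, got "
                f"{self.negative_below}, {self.positive_at_or_above}"
            )
        if not 0.0 < self.final_positive_at_or_above < 100.0:
            raise ValueError(
                f"final threshold must be in (0, 100), got "
                f"{self.final_positive_at_or_above}"
            )


DEFAULT_THRESHOLDS = TriageThresholds()


@dataclass(frozen=True)
class IndexOutcome:
    """Result of the index test for one case.

    ``final_score`` is present only for uncertain (escalated) cases; for
    auto-negative and auto-positive cases the verdict is forced by the
    category.
    """

    category: Category
    final_score: Optional[float]
    verdict: int

    def __post_init__(self) -> None:
        if self.category is Category.UNCERTAIN:
            if self.final_score is None:
                raise ValueError("uncertain outcome requires a final score")
        else:
            if self.final_score is not None:
                raise ValueError(f"{self.category.value} outcome carries no final score")
            forced = 1 if self.category is Category.POSITIVE else 0
            if self.verdict != forced:
                raise ValueError(
                    f"{self.category.value} category forces verdict {forced}"
                )


def categorize_score(
    ai_score: float, thresholds: TriageThresholds = DEFAULT_THRESHOLDS
) -> Category:
    """Triage an AI probability score into negative / uncertain / positive."""
    if not 0.0 <= ai_score <= 100.0:
        raise ValueError(f"ai_score {ai_score} outside [0, 100]")
    if ai_score < thresholds.negative_below:
        return Category.NEGATIVE
    if ai_score >= thresholds.positive_at_or_above:
        return Category.POSITIVE
    return Category.UNCERTAIN


def final_score(ai_score: float, r1: Optional[int], r2: Optional[int]) -> float:
    """Final asbestosis score of an escalated case.

    Reviewer verdicts enter on the same 0-100 scale as the AI score
    (negative -> 0, positive -> 100), so the result is the plain mean of the
    three assessments.
    """
    if r1 is None or r2 is None:
        raise EscalationIncompleteError(
            "escalation incomplete: both reviewer verdicts are required, got "
            f"({r1!r}, {r2!r})"
        )
    if r1 not in (0, 1) or r2 not in (0, 1):
        raise ValueError(f"reviewer verdicts must be 0 or 1, got ({r1!r}, {r2!r})")
    return (float(ai_score) + 100.0 * r1 + 100.0 * r2) / 3.0


def run_index_test(
    case: "CaseRecord",
    thresholds: TriageThresholds = DEFAULT_THRESHOLDS,
    fallback: Optional[Callable[["CaseRecord"], float]] = None,
) -> IndexOutcome:
    """Run the full index test on one case.

    ``fallback`` is a hook producing a substitute score for cases where the
    AI score is absent (e.g. incompatible CT or missing DLCO handled by a
    site-specific formula).  Without it, a case lacking a score is an error.
    """
    score = case.ai_score
    if score is None:
        if fallback is None:
            missing = []
            if not case.ct_compatible:
                missing.append("compatible CT")
            if not case.dlco_available:
                missing.append("DLCO")
            detail = f" (missing: {', '.join(missing)})" if missing else ""
            raise ValueError(
                f"case {case.case_id}: no AI score and no fallback configured{detail}"
            )
        score = float(fallback(case))
        if not 0.0 <= score <= 100.0:
            raise ValueError(
                f"case {case.case_id}: fallback score {score} outside [0, 100]"
            )

    category = categorize_score(score, thresholds)
    if category is Category.NEGATIVE:
        return IndexOutcome(category, None, 0)
    if category is Category.POSITIVE:
        return IndexOutcome(category, None, 1)

    if len(case.index_verdicts) != 2:
        raise EscalationIncompleteError(
            f"case {case.case_id}: uncertain score {score:.1f} requires two "
            f"index reviewer verdicts, got {len(case.index_verdicts)}"
        )
    fs = final_score(score, *case.index_verdicts)
    verdict = int(fs >= thresholds.final_positive_at_or_above)
    return IndexOutcome(category, fs, verdict)


def apply_index_test(
    cohort: Iterable["CaseRecord"],
    thresholds: TriageThresholds = DEFAULT_THRESHOLDS,
    fallback: Optional[Callable[["CaseRecord"], float]] = None,
) -> list[IndexOutcome]:
    """Index-test outcome for every case, in cohort order."""
    return [run_index_test(c, thresholds, fallback) for c in cohort]


@dataclass(frozen=True)
class TriageSummary:
    """Counts and one-decimal percentages per category and final verdict."""

    n_cases: int
    category_counts: dict
    verdict_counts: dict

    @property
    def category_percent(self) -> dict:
        return {
            k: round(100.0 * v / self.n_cases, 1) if self.n_cases else 0.0
            for k, v in self.category_counts.items()
        }

    @property
    def verdict_percent(self) -> dict:
        return {
            k: round(100.0 * v / self.n_cases, 1) if self.n_cases else 0.0
            for k, v in self.verdict_counts.items()
        }


def triage_summary(
    cohort: Iterable["CaseRecord"],
    thresholds: TriageThresholds = DEFAULT_THRESHOLDS,
    fallback: Optional[Callable[["CaseRecord"], float]] = None,
) -> TriageSummary:
    """Cohort-level triage bookkeeping.

    Category counts always sum to the cohort size; verdict counts split the
    escalated cases into approved/denied alongside the automatic decisions.
    """
    outcomes = apply_index_test(cohort, thresholds, fallback)
    cat = Counter(o.category.value for o in outcomes)
    ver = Counter(o.verdict for o in outcomes)
    return TriageSummary(
        n_cases=len(outcomes),
        category_counts={c.value: cat.get(c.value, 0) for c in Category},
        verdict_counts={0: ver.get(0, 0), 1: ver.get(1, 0)},
    )
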