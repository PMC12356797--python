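"""Synthetic cohort generator for the triage-validation pipeline.

Real applicant data behind the study design this package supports cannot be
shared, so every downstream stage (triage, adjudication, accuracy metrics,
agreement statistics) is exercised on simulated cohorts with the same
statistical structure: a latent binary disease status, class-conditional AI
probability scores on a 0-100 scale, correlated binary rater verdicts with
tunable marginal sensitivity/specificity, and missing-data flags for
incompatible CT scans and absent DLCO measurements.

Rater model
-----------
Each case carries a standard-normal latent difficulty ``Z``.  Rater ``j``
observes ``U_j = sqrt(rho) * Z + sqrt(1 - rho) * E_j`` with independent
standard-normal noise ``E_j`` and calls the case positive when
``U_j < Phi^{-1}(p)``, where ``p`` is the rater's marginal positive-call
probability given the latent truth (sensitivity for true positives,
1 - specificity for true negatives).  This preserves the marginal error
rates exactly while ``rho`` (``latent_correlation``) induces positive
within-case correlation between raters, which is what drives chance-corrected
agreement above its independence level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .triage import DEFAULT_THRESHOLDS, TriageThresholds, categorize_score, Category

__all__ = [
    "SimulationConfig",
    "CaseRecord",
    "generate_cohort",
    "rater_agreement_of_config",
]

#: parameters of a Beta distribution, scaled to the 0-100 score range
BetaParams = Tuple[float, float]
ScoreDistribution = Union[BetaParams, "stats.distributions.rv_frozen"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults are calibrated so that a cohort of 92 cases reproduces the
    aggregate structure the pipeline is validated against: a disease
    prevalence of 57/92, mean triage fractions of about 8.7% auto-negative /
    67.4% uncertain / 23.9% auto-positive under the default 35/66 cutoffs,
    a raw-score ROC-AUC near 0.87, and a three-rater free-marginal kappa
    near 0.59.

    Parameters
    ----------
    n_cases
        Cohort size (default 92).
    prevalence
        Probability that a case is truly positive.
    score_params_pos, score_params_neg
        Class-conditional AI score distributions.  Either ``(a, b)`` shape
        parameters of a Beta distribution scaled to [0, 100], or any frozen
        scipy distribution whose support lies within [0, 100].
    rater_sensitivity, rater_specificity
        Marginal per-rater probabilities of a correct call, shared by all
        raters (reference and escalation reviewers alike).
    latent_correlation
        Correlation ``rho`` in [0, 1) of the rater latent variables within a
        case; 0 gives conditionally independent raters.
    p_ct_incompatible, p_dlco_missing
        Missing-completely-at-random probabilities for the two availability
        flags (defaults 3/92 and 5/92).
    n_rater_pool
        Size of the reviewer pool the allocation simulator draws from.
    seed
        Base seed; identical config + seed yields a bit-identical cohort.
    """

    n_cases: int = 92
    prevalence: float = 57 / 92
    score_params_pos: ScoreDistribution = (21.05, 12.58)
    score_params_neg: ScoreDistribution = (6.32, 7.69)
    rater_sensitivity: float = 0.86
    rater_specificity: float = 0.85
    latent_correlation: float = 0.335
    p_ct_incompatible: float = 3 / 92
    p_dlco_missing: float = 5 / 92
    n_rater_pool: int = 13
    seed: int = 0
    thresholds: TriageThresholds = field(default=DEFAULT_THRESHOLDS)

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError(f"n_cases must be >= 1, got {self.n_cases}")
        for name in (
            "prevalence",
            "rater_sensitivity",
            "rater_specificity",
            "p_ct_incompatible",
            "p_dlco_missing",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.latent_correlation < 1.0:
            raise ValueError(
                f"latent_correlation must be in [0, 1), got {self.latent_correlation}"
            )
        if self.n_rater_pool < 5:
            raise ValueError("n_rater_pool must be at least 5 (3 reference + 2 index)")
        _check_score_distribution(self.score_params_pos, "score_params_pos")
        _check_score_distribution(self.score_params_neg, "score_params_neg")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class CaseRecord:
    """One applicant: AI score, availability flags, verdicts, optional truth.

    ``ref_verdicts`` holds the three reference-panel verdicts (``None``
    marks a missing verdict, which downstream agreement code excludes with a
    count).  ``index_verdicts`` holds the two escalation-reviewer verdicts
    and is non-empty only for cases triaged as uncertain.  ``true_status``
    exists only for synthetic cohorts.
    """

    case_id: str
    ai_score: Optional[float]
    ct_compatible: bool = True
    dlco_available: bool = True
    ref_verdicts: Tuple[Optional[int], ...] = ()
    index_verdicts: Tuple[int, ...] = ()
    true_status: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ai_score is not None and not 0.0 <= self.ai_score <= 100.0:
            raise ValueError(
                f"case {self.case_id}: ai_score {self.ai_score} outside [0, 100]"
            )
        for v in tuple(self.ref_verdicts) + tuple(self.index_verdicts):
            if v is not None and v not in (0, 1):
                raise ValueError(f"case {self.case_id}: verdict {v!r} not in {{0, 1}}")


def _check_score_distribution(params: ScoreDistribution, name: str):
    """Validate and normalize a score distribution spec; return a frozen dist
    on the [0, 100] scale."""
    if isinstance(params, tuple):
        if len(params) != 2:
            raise ValueError(f"{name}: Beta spec must be (a, b), got {params}")
        a, b = params
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            raise ValueError(f"{name}: Beta shape parameters must be finite and > 0")
        return stats.beta(a, b, loc=0.0, scale=100.0)
    dist = params
    lo, hi = dist.support()
    if lo < -1e-9 or hi > 100.0 + 1e-9:
        raise ValueError(f"{name}: support [{lo}, {hi}] not within [0, 100]")
    std = dist.std()
    if not std > 0:  # catches zero variance and invalid (nan) parameters
        raise ValueError(f"{name}: degenerate (zero-variance) score distribution")
    return dist


def _rater_verdicts(
    rng: np.random.Generator, p_positive: float, n_raters: int, rho: float
) -> np.ndarray:
    """Correlated binary verdicts with marginal positive-call rate ``p_positive``."""
    z = rng.standard_normal()
    eps = rng.standard_normal(n_raters)
    latent = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
    # marginal of `latent` is standard normal, so thresholding at the normal
    # quantile of p reproduces the marginal exactly for any rho
    threshold = stats.norm.ppf(p_positive)
    return (latent < threshold).astype(int)


def generate_cohort(config: SimulationConfig) -> list[CaseRecord]:
    """Draw a synthetic cohort of ``config.n_cases`` applicants.

    Each case uses its own RNG substream spawned deterministically from the
    base seed, so record ``i`` is identical no matter how many cases are
    generated: cohorts of different sizes share a common prefix.

    All five potential reviewers of a case (three reference, two escalation)
    share the same latent difficulty, so index reviewers correlate with the
    reference panel just as reference reviewers correlate with each other.
    Escalation verdicts are drawn only when the AI score falls in the
    uncertain band of ``config.thresholds``.
    """
    config.validate()
    dist_pos = _check_score_distribution(config.score_params_pos, "score_params_pos")
    dist_neg = _check_score_distribution(config.score_params_neg, "score_params_neg")

    streams = np.random.SeedSequence(config.seed).spawn(config.n_cases)
    width = len(str(config.n_cases))
    records: list[CaseRecord] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        truth = int(rng.random() < config.prevalence)
        dist = dist_pos if truth else dist_neg
        score = float(np.clip(dist.rvs(random_state=rng), 0.0, 100.0))
        ct_ok = bool(rng.random() >= config.p_ct_incompatible)
        dlco_ok = bool(rng.random() >= config.p_dlco_missing)
        p_call = (
            config.rater_sensitivity if truth else 1.0 - config.rater_specificity
        )
        verdicts = _rater_verdicts(rng, p_call, 5, config.latent_correlation)
        uncertain = (
            categorize_score(score, config.thresholds) is Category.UNCERTAIN
        )
        records.append(
            CaseRecord(
                case_id=f"case-{i:0{width}d}",
                ai_score=score,
                ct_compatible=ct_ok,
                dlco_available=dlco_ok,
                ref_verdicts=tuple(int(v) for v in verdicts[:3]),
                index_verdicts=tuple(int(v) for v in verdicts[3:]) if uncertain else (),
                true_status=truth,
            )
        )
    return records


def rater_agreement_of_config(config: SimulationConfig, n_mc: int = 10_000) -> float:
    """Monte-Carlo estimate of the three-rater free-marginal kappa implied by
    ``config``'s rater model.

    Simulates ``n_mc`` cases (truth, then three correlated verdicts) and
    returns the Randolph free-marginal kappa of the resulting ratings matrix.
    Used to calibrate simulation configs to a target agreement level.
    """
    if n_mc < 1:
        raise ValueError(f"n_mc must be >= 1, got {n_mc}")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    rho = config.latent_correlation
    truth = rng.random(n_mc) < config.prevalence
    p_call = np.where(
        truth, config.rater_sensitivity, 1.0 - config.rater_specificity
    )
    z = rng.standard_normal(n_mc)[:, None]
    eps = rng.standard_normal((n_mc, 3))
    latent = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
    ratings = (latent < stats.norm.ppf(p_call)[:, None]).astype(int)

    from .agreement import RatingsMatrix, randolph_kappa

    return randolph_kappa(RatingsMatrix(ratings))
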