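"""Exact binomial power design for one-sided sensitivity validation.

The validation design asks: among the first ``n`` reference-positive cases,
how many must the index test call positive for the study to succeed?  Given
an anticipated true sensitivity ``p`` and a power target, the acceptance
threshold ``k`` is the largest count whose binomial upper-tail probability
``P(X >= k)``, ``X ~ Binomial(n, p)``, still meets the power target; the
smallest ``n`` is then chosen so that the exact (Clopper-Pearson) lower
confidence bound of ``k/n`` clears the prespecified sensitivity floor.

With the conventional inputs — anticipated sensitivity 0.98, power 0.99,
lower bound 0.85 and a one-sided 95% exact interval — the design lands on
requiring 55 successes out of 59 positives (point sensitivity 93%).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = [
    "PowerDesign",
    "exact_power",
    "max_threshold",
    "clopper_pearson",
    "design_study",
]


@dataclass(frozen=True)
class PowerDesign:
    """A resolved (n, k) success criterion with its design inputs."""

    p_true: float
    power_target: float
    lower_bound: float
    ci_method: str
    n_positives: int
    k_threshold: int
    achieved_power: float
    point_sensitivity: float
    ci_low: float
    ci_high: float

    def as_dict(self) -> dict:
        return {
            "p_true": self.p_true,
            "power_target": self.power_target,
            "lower_bound": self.lower_bound,
            "ci_method": self.ci_method,
            "n_positives": self.n_positives,
            "k_threshold": self.k_threshold,
            "achieved_power": self.achieved_power,
            "point_sensitivity": self.point_sensitivity,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def exact_power(n: int, k: int, p: float) -> float:
    """``P(X >= k)`` for ``X ~ Binomial(n, p)`` by exact upper-tail summation."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def max_threshold(n: int, p: float, power_target: float) -> int:
    """Largest ``k`` with ``exact_power(n, k, p) >= power_target``.

    ``exact_power`` is non-increasing in ``k`` and equals 1 at ``k = 0``, so
    for any target in (0, 1) a threshold exists; the scan walks down from
    ``n``.
    """
    if not 0.0 < power_target < 1.0:
        raise ValueError(f"power_target must be in (0, 1), got {power_target}")
    for k in range(n, -1, -1):
        if exact_power(n, k, p) >= power_target:
            return k
    raise AssertionError("unreachable: exact_power(n, 0, p) == 1")


def clopper_pearson(
    k: int, n: int, alpha: float = 0.05, sided: str = "two"
) -> tuple[float, float]:
    """Exact binomial confidence interval for ``k`` successes in ``n`` trials.

    ``sided="two"`` gives the usual equal-tailed interval from beta
    quantiles; ``sided="one"`` gives ``[lower, 1]`` with the full ``alpha``
    in the lower tail.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if sided == "two":
        a_lo, a_hi = alpha / 2.0, alpha / 2.0
    elif sided == "one":
        a_lo, a_hi = alpha, None
    else:
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    lower = 0.0 if k == 0 else float(stats.beta.ppf(a_lo, k, n - k + 1))
    if a_hi is None:
        upper = 1.0
    else:
        upper = 1.0 if k == n else float(stats.beta.ppf(1 - a_hi, k + 1, n - k))
    return lower, upper


def design_study(
    p_true: float = 0.98,
    lower_bound: float = 0.85,
    power_target: float = 0.99,
    ci_method: str = "one-sided",
    alpha: float = 0.05,
    n_max: int = 10_000,
) -> PowerDesign:
    """Smallest ``n`` whose power-derived threshold ``k`` clears the floor.

    For each candidate ``n``, ``k = max_threshold(n, p_true, power_target)``;
    the design is accepted once the Clopper-Pearson lower bound of ``k/n``
    (per ``ci_method``, ``"one-sided"`` or ``"two-sided"`` at level
    ``alpha``) is at or above ``lower_bound``.  A plain linear scan keeps the
    search exact.

    Raises
    ------
    ValueError
        If the inputs are inconsistent (e.g. ``lower_bound >= p_true``) or
        no ``n`` up to ``n_max`` satisfies both constraints.
    """
    if not 0.0 < lower_bound < p_true < 1.0:
        raise ValueError(
            f"need 0 < lower_bound < p_true < 1, got {lower_bound}, {p_true}"
        )
    if not 0.0 < power_target < 1.0:
        raise ValueError(f"power_target must be in (0, 1), got {power_target}")
    sided = {"one-sided": "one", "two-sided": "two"}.get(ci_method)
    if sided is None:
        raise ValueError(f"ci_method must be 'one-sided' or 'two-sided', got {ci_method!r}")

    for n in range(1, n_max + 1):
        k = max_threshold(n, p_true, power_target)
        if k == 0:
            continue
        lo, hi = clopper_pearson(k, n, alpha=alpha, sided=sided)
        if lo >= lower_bound:
            return PowerDesign(
                p_true=p_true,
                power_target=power_target,
                lower_bound=lower_bound,
                ci_method=ci_method,
                n_positives=n,
                k_threshold=k,
                achieved_power=exact_power(n, k, p_true),
                point_sensitivity=k / n,
                ci_low=lo,
                ci_high=hi,
            )
    raise ValueError(
        f"no n <= {n_max} meets both the power target {power_target} and the "
        f"lower bound {lower_bound}; the bounds may be inconsistent with "
        f"p_true={p_true} under a {ci_method} interval"
    )
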