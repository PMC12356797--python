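# Methods

This note documents the statistical model behind `asbestriage`, the
conventions adopted where the procedure leaves room, and what the synthetic
cohorts do and do not establish about real applicant data.

## The index test and its algebra

The index test is sequential: an AI asbestosis probability score
`s ∈ [0, 100]` triages each case, and only uncertain cases
(`35 ≤ s < 66` by default) are escalated to two independent reviewers.
The final asbestosis score of an escalated case is the equally weighted
mean of the three assessments on a common 0–100 scale,
`f = (s + 100·r₁ + 100·r₂)/3`, thresholded at 50.

Two conventions deserve note:

- **Boundary at the upper cutoff.** The upper cutoff is inclusive: a score
  of exactly 66.0 is auto-positive, so the uncertain band is `[35, 66)`.
  The operational rule "positive if ≥ 66.0" is taken as authoritative over
  the looser band description "35–66".
- **Reviewer verdict scale.** Verdicts enter the mean as 0 or 100, not 0 or
  1. Mixing a 0–100 AI score with 0/1 verdicts and a threshold of 50 would
  make the reviewers arithmetically irrelevant (max contribution 2/3 of a
  point), which contradicts the purpose of escalation; the common-scale
  normalization is the only reading under which the stated threshold is
  meaningful. Under it the rule has two provable properties, asserted
  exhaustively in the tests: unanimous reviewers always decide the case
  (bounds `(35+200)/3 ≈ 78.3 ≥ 50` and `66/3 = 22 < 50`), and split
  reviewers reduce the rule to `s ≥ 50`.

Final scores are kept at full precision and compared with exact `≥`;
nothing is rounded before thresholding. Cases without an AI score
(incompatible CT, missing DLCO) are handled by a user-pluggable fallback
hook mapping the case to a substitute score; no specific alternative formula
is assumed, and the default is an explicit error.

## Reference standard and reviewer allocation

The reference standard is the majority of a three-member panel (positive iff
at least two positive verdicts); a case with a missing panel verdict cannot
be adjudicated and is excluded with a count wherever agreement statistics
are computed. The allocation simulator draws, per case, five distinct form
numbers uniformly without replacement (three reference, two index) and
re-shuffles the mapping from form numbers to reviewers at fixed period
boundaries. Periods are counted in cases (default 12) rather than calendar
months, since the simulator has no calendar; the scheme preserves the
properties that matter — blinding, uniform workload (each reviewer serves
on the reference panel for 3/13 of cases in expectation with a 13-member
pool), and periodic regrouping.

## Synthetic cohort generator

Each case draws a latent true status `T ~ Bernoulli(prevalence)`, an AI
score from a class-conditional distribution, two
missing-completely-at-random availability flags, and five correlated binary
verdicts. The rater model is a shared latent difficulty: case difficulty
`Z ~ N(0,1)` is common to all five potential reviewers, rater `j` observes
`U_j = √ρ·Z + √(1−ρ)·E_j` and calls positive when `U_j < Φ⁻¹(p)` with `p`
the marginal positive-call rate given `T` (sensitivity for positives,
1 − specificity for negatives). Because `U_j` is marginally standard
normal, the per-rater error rates are exact for any correlation `ρ`; `ρ`
only moves the within-case dependence, hence the chance-corrected
agreement. This is the simplest construction with exactly tunable marginals
and a single correlation knob. Escalation verdicts are generated only for
cases whose score falls in the uncertain band, so record-level invariants
hold by construction.

Defaults (the study conditions the pipeline is exercised under):

| parameter | default | rationale |
|---|---|---|
| `n_cases` | 92 | cohort size of the validation setting |
| `prevalence` | 57/92 | reference-positive fraction |
| `score_params_pos` | Beta(21.05, 12.58) × 100 | calibration, see below |
| `score_params_neg` | Beta(6.32, 7.69) × 100 | calibration, see below |
| `rater_sensitivity` | 0.86 | observed index-test sensitivity, reused as the rater-level convention |
| `rater_specificity` | 0.85 | observed index-test specificity, likewise |
| `latent_correlation` | 0.335 | solved so the 3-rater κ_free ≈ 0.59 |
| `p_ct_incompatible` | 3/92 | observed count |
| `p_dlco_missing` | 5/92 | observed count |
| `n_rater_pool` | 13 | reviewer pool size |

The Beta shapes were fitted once, by least squares, to three aggregate
targets: mean triage fractions 8.7% / 67.4% / 23.9%
(negative/uncertain/positive under the 35/66 cutoffs) and a raw-score
ROC-AUC of 0.87. Class separation is not identifiable from the triage
fractions alone (a fit to the fractions only can invert the classes), which
is why the AUC target is part of the calibration. The latent correlation
was solved analytically from the bivariate-normal pairwise-agreement
formula: with marginals (0.86, 0.85) and prevalence 57/92, independent
raters give κ_free ≈ 0.51 and ρ = 0.335 raises it to 0.59.

Per-rater error rates and the correlation structure of the real panel are
not published anywhere; these defaults are conventions chosen to reproduce
the published aggregates, not estimates of rater behaviour. Consequences of
that, and of MCAR missingness and a single shared difficulty dimension, are
limitations: passing tests show the pipeline's statistics are correct and
calibrated *under this generative model*, not that the real panel behaves
like it (e.g. real verdict dependence may be case-mix driven and
asymmetric between classes, and real missingness need not be random).

Reproducibility: each case consumes its own RNG substream spawned
deterministically from the base seed, so record `i` is identical whatever
the cohort size, and identical config + seed gives a byte-identical cohort
after a CSV round-trip (scores are written with `repr` and parsed in
round-trip mode).

## Accuracy metrics and the bootstrap

Point metrics come from the 2×2 table of index verdict against reference
majority. ROC-AUC is the Mann–Whitney probability with half-credit for
ties; PR-AUC is average precision (stepwise, no linear interpolation, which
is optimistic for PR curves). Confidence intervals are case-resampling
percentile bootstrap with 10,000 iterations by default; resamples on which
a statistic is undefined (a class absent) are skipped and counted in the
estimate's provenance rather than silently dropped — an error is raised
only if every resample is degenerate. BCa corrections are deliberately not
used; the percentile method is the documented convention here, and its
modest undercoverage for a proportion at n ≈ 92 (true coverage ≈ 94% for a
95% interval in the pipeline's own coverage experiment) is accepted rather
than corrected.

The effect of adding reviewers is tested as a paired comparison of
correlated AUCs on the same cases: the composite score (final score where
escalation occurred, raw score otherwise) against the raw score. The
variance of the AUC difference uses DeLong's placement-value covariance
with a normal two-sided p-value; a paired case-resampling bootstrap p-value
is available behind a method flag. Kendall τ-b (tie-corrected, since final
scores tie by construction) summarizes the rank correlation between the two
scores.

## Agreement statistics

Randolph's free-marginal kappa is used throughout:
`κ_free = (P̄ₒ − 1/c)/(1 − 1/c)` with `P̄ₒ` the mean per-item fraction of
agreeing rater pairs. For binary verdicts chance is fixed at 0.5 —
appropriate because reviewers face no quota on positive verdicts. Fleiss
kappa (empirical-marginal chance) is reported for contrast and flagged
undefined when all ratings fall in one category. Subgroup kappas stratify
the panel by the AI triage category; the five-rater kappa pools reference
and escalation reviewers on the escalated stratum. Kappa CIs resample items
with replacement (percentile, seeded). No p-values are attached to kappas:
the convention here is interval reporting only.

## Power design

`exact_power(n, k, p)` is the exact binomial upper tail; `max_threshold`
scans `k` downward from `n`; `design_study` scans `n` upward (exactness
over speed; the scan is capped and errors with a diagnostic when the
constraints are unreachable). The Clopper–Pearson interval is computed from
beta quantiles; **one-sided is the default convention** because the design
is one-sided and only the one-sided 95% bound reproduces the canonical
(n = 59, k = 55) criterion: the one-sided lower bound of 55/59 is 0.8515
(≥ 0.85) while the two-sided bound is 0.8354, and at n = 58 the one-sided
bound is 0.8491, so 59 is minimal. A two-sided variant is available and
yields a larger design.

## Problem sizes used in the test suite

Marginal-recovery checks run at n = 10,000 cases (tolerance 0.02, several
Monte-Carlo standard errors); agreement calibration at 60,000–120,000
simulated panels; the bootstrap coverage experiment at 500 cohorts of
n = 92 with 10,000 resamples each; triage-fraction calibration at 1,000
cohorts of n = 92; allocation frequencies at 20,000 cases (tolerance
placed ≥ 5σ so the check is stable across seeds). All stochastic tests fix
their seeds.
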