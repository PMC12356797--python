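"""Shared fixtures: deterministic cohorts built to the published marginal
counts, so bookkeeping invariants can be checked exactly."""

import numpy as np
import pytest
from hypothesis import settings

from asbestriage import CaseRecord, SimulationConfig, generate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def _panel(n_pos: int):
    """A three-verdict panel with the given number of positives."""
    return tuple([1] * n_pos + [0] * (3 - n_pos))


@pytest.fixture(scope="session")
def printed_counts_cohort():
    """A 92-case cohort matching the published aggregate counts.

    Triage: 8 auto-negative, 22 auto-positive, 62 uncertain; of the 62
    escalated cases 28 end with a positive final verdict and 34 negative.
    Reference panels follow the published positive-verdict distribution
    19/16/12/45 (57 reference positives).
    """
    panels = [_panel(0)] * 19 + [_panel(1)] * 16 + [_panel(2)] * 12 + [_panel(3)] * 45
    assert len(panels) == 92

    cases = []

    def add(ai_score, index_verdicts):
        cases.append(
            CaseRecord(
                case_id=f"fx-{len(cases):02d}",
                ai_score=ai_score,
                ref_verdicts=panels[len(cases)],
                index_verdicts=index_verdicts,
            )
        )

    for _ in range(8):
        add(20.0, ())  # auto-negative
    for _ in range(22):
        add(80.0, ())  # auto-positive
    for _ in range(28):
        add(55.0, (1, 1))  # escalated, final (55+200)/3 = 85 -> positive
    for _ in range(34):
        add(45.0, (0, 0))  # escalated, final 15 -> negative
    assert len(cases) == 92
    return cases


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-case simulated cohort for fast end-to-end checks."""
    return generate_cohort(SimulationConfig(n_cases=60, seed=20260919))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
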