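"""Cohort CSV schema, YAML configuration, and the end-to-end pipeline.

The cohort file is a plain comma-separated, UTF-8, '.'-decimal table with
one row per applicant::

    case_id, true_status, ai_score, ct_compatible, dlco_available,
    ref_verdict_1..3, index_verdict_1..2

Empty cells mean "not applicable" (no escalation reviewers for automatic
decisions, no latent truth for real data, a missing panel verdict).

``run_pipeline`` chains every stage — simulate (or load) a cohort, run the
index test, adjudicate the reference panels, compute accuracy metrics with
bootstrap CIs, agreement statistics, and the power design — into a single
self-contained, seed-reproducible JSON report.  One structured log line per
stage records counts in and out.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjudication import reference_labels
from .agreement import (
    RatingsMatrix,
    fleiss_kappa,
    kappa_bootstrap_ci,
    kendall_tau,
    randolph_kappa,
    subgroup_kappas,
)
from .cohort_sim import CaseRecord, SimulationConfig, generate_cohort
from .metrics import (
    bootstrap_ci,
    compare_auc_paired,
    confusion,
    point_metrics,
    pr_auc,
    roc_auc,
)
from .power_design import design_study
from .triage import (
    DEFAULT_THRESHOLDS,
    Category,
    TriageThresholds,
    apply_index_test,
    triage_summary,
)

logger = logging.getLogger("asbestriage")

__all__ = [
    "COHORT_COLUMNS",
    "SCHEMA_VERSION",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "PipelineConfig",
    "run_pipeline",
    "validate_report",
    "load_config",
]

COHORT_COLUMNS = [
    "case_id",
    "true_status",
    "ai_score",
    "ct_compatible",
    "dlco_available",
    "ref_verdict_1",
    "ref_verdict_2",
    "ref_verdict_3",
    "index_verdict_1",
    "index_verdict_2",
]

SCHEMA_VERSION = "1"


def _fmt_opt(v) -> str:
    return "" if v is None else str(v)


def cohort_to_frame(cohort: Sequence[CaseRecord]) -> pd.DataFrame:
    rows = []
    for c in cohort:
        ref = tuple(c.ref_verdicts) + (None,) * (3 - len(c.ref_verdicts))
        idx = tuple(c.index_verdicts) + (None,) * (2 - len(c.index_verdicts))
        rows.append(
            {
                "case_id": c.case_id,
                "true_status": c.true_status,
                "ai_score": c.ai_score,
                "ct_compatible": int(c.ct_compatible),
                "dlco_available": int(c.dlco_available),
                "ref_verdict_1": ref[0],
                "ref_verdict_2": ref[1],
                "ref_verdict_3": ref[2],
                "index_verdict_1": idx[0],
                "index_verdict_2": idx[1],
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(cohort: Sequence[CaseRecord], path) -> None:
    rows = []
    for c in cohort:
        ref = tuple(c.ref_verdicts) + (None,) * (3 - len(c.ref_verdicts))
        idx = tuple(c.index_verdicts) + (None,) * (2 - len(c.index_verdicts))
        cells = [
            c.case_id,
            _fmt_opt(c.true_status),
            "" if c.ai_score is None else repr(float(c.ai_score)),
            str(int(c.ct_compatible)),
            str(int(c.dlco_available)),
            *(_fmt_opt(v) for v in ref),
            *(_fmt_opt(v) for v in idx),
        ]
        rows.append(cells)
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def _parse_verdict(raw, row: int, column: str) -> Optional[int]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    try:
        v = int(float(raw))
    except (TypeError, ValueError):
        v = -1
    if v not in (0, 1) or float(raw) != v:
        raise ValueError(
            f"row {row}, column {column!r}: verdict {raw!r} is not binary (0/1)"
        )
    return v


def read_cohort(path, strict: bool = True) -> list[CaseRecord]:
    """Read a cohort CSV into typed records.

    Malformed cells are reported with their row number (1-based, excluding
    the header) and column name.  In strict mode unknown columns are
    rejected; otherwise extra columns pass through unread.
    """
    df = pd.read_csv(
        path, dtype={"case_id": str}, keep_default_na=True,
        float_precision="round_trip",
    )
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file {path} lacks required columns: {missing_cols}")
    if strict:
        extra = [c for c in df.columns if c not in COHORT_COLUMNS]
        if extra:
            raise ValueError(f"cohort file {path} has unknown columns: {extra}")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        score = row["ai_score"]
        score = None if score is None or (isinstance(score, float) and math.isnan(score)) else float(score)
        if score is not None and not 0.0 <= score <= 100.0:
            raise ValueError(f"row {i}, column 'ai_score': {score} outside [0, 100]")
        ts = _parse_verdict(row["true_status"], i, "true_status")
        ref = tuple(
            _parse_verdict(row[f"ref_verdict_{j}"], i, f"ref_verdict_{j}")
            for j in (1, 2, 3)
        )
        idx = tuple(
            v
            for j in (1, 2)
            if (v := _parse_verdict(row[f"index_verdict_{j}"], i, f"index_verdict_{j}"))
            is not None
        )
        records.append(
            CaseRecord(
                case_id=str(row["case_id"]),
                ai_score=score,
                ct_compatible=bool(int(row["ct_compatible"])),
                dlco_available=bool(int(row["dlco_available"])),
                ref_verdicts=ref,
                index_verdicts=idx,
                true_status=ts,
            )
        )
    return records


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one full analysis run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: TriageThresholds = field(default=DEFAULT_THRESHOLDS)
    n_boot: int = 10_000
    seed: int = 0
    cohort_csv: Optional[str] = None  # when set, load instead of simulating

    def as_dict(self) -> dict:
        sim = self.simulation
        return {
            "simulation": {
                "n_cases": sim.n_cases,
                "prevalence": sim.prevalence,
                "score_params_pos": list(sim.score_params_pos)
                if isinstance(sim.score_params_pos, tuple)
                else "custom-distribution",
                "score_params_neg": list(sim.score_params_neg)
                if isinstance(sim.score_params_neg, tuple)
                else "custom-distribution",
                "rater_sensitivity": sim.rater_sensitivity,
                "rater_specificity": sim.rater_specificity,
                "latent_correlation": sim.latent_correlation,
                "p_ct_incompatible": sim.p_ct_incompatible,
                "p_dlco_missing": sim.p_dlco_missing,
                "n_rater_pool": sim.n_rater_pool,
                "seed": sim.seed,
            },
            "thresholds": {
                "negative_below": self.thresholds.negative_below,
                "positive_at_or_above": self.thresholds.positive_at_or_above,
                "final_positive_at_or_above": self.thresholds.final_positive_at_or_above,
            },
            "n_boot": self.n_boot,
            "seed": self.seed,
            "cohort_csv": self.cohort_csv,
        }


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file mirroring its fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_kwargs = dict(raw.get("simulation", {}))
    for key in ("score_params_pos", "score_params_neg"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    thr_kwargs = raw.get("thresholds", {})
    return PipelineConfig(
        simulation=SimulationConfig(**sim_kwargs),
        thresholds=TriageThresholds(**thr_kwargs),
        n_boot=int(raw.get("n_boot", 10_000)),
        seed=int(raw.get("seed", 0)),
        cohort_csv=raw.get("cohort_csv"),
    )


def _stage(name: str, n_in: int, n_out: int, **extra) -> None:
    detail = " ".join(f"{k}={v}" for k, v in extra.items())
    logger.info("stage=%s n_in=%d n_out=%d %s", name, n_in, n_out, detail)


def _composite_score(case: CaseRecord, outcome) -> float:
    """Score used for ranking the full index test: final asbestosis score for
    escalated cases, raw AI score otherwise."""
    return outcome.final_score if outcome.final_score is not None else case.ai_score


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> triage -> adjudicate -> evaluate -> agreement ->
    power and return the full JSON-serializable run report."""
    if config.n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {config.n_boot}")
    seed_rng = np.random.default_rng(config.seed)
    stage_seed = lambda: int(seed_rng.integers(2**31))  # noqa: E731

    # --- cohort ---
    if config.cohort_csv is not None:
        cohort = read_cohort(config.cohort_csv)
        sim_seed = None
    else:
        sim = replace(
            config.simulation, seed=stage_seed(), thresholds=config.thresholds
        )
        cohort = generate_cohort(sim)
        sim_seed = sim.seed
    n = len(cohort)
    _stage("cohort", n, n, source="csv" if config.cohort_csv else "simulated")
    if n == 0:
        raise ValueError("empty cohort: nothing to analyse")

    # --- triage ---
    outcomes = apply_index_test(cohort, config.thresholds)
    summary = triage_summary(cohort, config.thresholds)
    _stage("triage", n, n, **summary.category_counts)

    # --- adjudication ---
    ref, verdict_dist = reference_labels(cohort)
    _stage("adjudicate", n, n, positives=int(ref.sum()))

    # --- diagnostic accuracy ---
    pred = np.array([o.verdict for o in outcomes])
    ai_scores = np.array([c.ai_score for c in cohort], dtype=float)
    comp_scores = np.array(
        [_composite_score(c, o) for c, o in zip(cohort, outcomes)], dtype=float
    )
    conf = confusion(pred, ref)

    def metric_ci(name, stat, *arrays):
        return bootstrap_ci(
            stat, arrays, name=name, n_boot=config.n_boot, seed=stage_seed()
        )

    def _point(which):
        return lambda p, r: point_metrics(confusion(p, r))[which]

    estimates = [
        metric_ci(m, _point(m), pred, ref)
        for m in ("sensitivity", "specificity", "accuracy", "ppv", "npv")
    ]
    estimates.append(metric_ci("roc_auc", roc_auc, comp_scores, ref))
    estimates.append(metric_ci("pr_auc", pr_auc, comp_scores, ref))
    auc_cmp = compare_auc_paired(comp_scores, ai_scores, ref)
    tau = kendall_tau(ai_scores, comp_scores)
    _stage("evaluate", n, len(estimates), n_boot=config.n_boot)

    # --- agreement ---
    panel = RatingsMatrix.from_cases(cohort)
    cats = [o.category.value for o in outcomes]
    kept_cats = [
        c
        for c, case in zip(cats, cohort)
        if all(v is not None for v in case.ref_verdicts)
    ]
    kappas = subgroup_kappas(panel, kept_cats)
    panel_ci = kappa_bootstrap_ci(panel, n_boot=config.n_boot, seed=stage_seed())
    uncertain_cases = [
        case
        for case, o in zip(cohort, outcomes)
        if o.category is Category.UNCERTAIN
    ]
    five = RatingsMatrix.from_cases(uncertain_cases, include_index_reviewers=True)
    kappa_five = randolph_kappa(five) if five.n_items else None
    _stage("agreement", n, panel.n_items, excluded=panel.n_excluded)

    # --- power design ---
    design = design_study()
    _stage("power", n, 1, n_positives=design.n_positives)

    report = {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config.as_dict(),
        "seeds": {"base": config.seed, "simulation": sim_seed},
        "cohort": {"n_cases": n, "n_reference_positive": int(ref.sum())},
        "triage": {
            "category_counts": summary.category_counts,
            "category_percent": summary.category_percent,
            "verdict_counts": {str(k): v for k, v in summary.verdict_counts.items()},
            "verdict_percent": {str(k): v for k, v in summary.verdict_percent.items()},
        },
        "adjudication": {
            "verdict_count_distribution": {str(k): v for k, v in verdict_dist.items()},
            "n_reference_positive": int(ref.sum()),
        },
        "metrics": {
            "confusion": {"tp": conf.tp, "fp": conf.fp, "tn": conf.tn, "fn": conf.fn},
            "estimates": [e.as_dict() for e in estimates],
            "auc_comparison": {
                "auc_composite": auc_cmp.auc_a,
                "auc_score_only": auc_cmp.auc_b,
                "diff": auc_cmp.diff,
                "p_value": auc_cmp.p_value,
                "method": auc_cmp.method,
            },
            "kendall_tau_score_vs_final": tau,
        },
        "agreement": {
            "n_items": panel.n_items,
            "n_excluded": panel.n_excluded,
            "randolph_kappa": {
                "point": panel_ci.point,
                "ci_low": panel_ci.ci_low,
                "ci_high": panel_ci.ci_high,
                "n_boot": panel_ci.n_boot,
                "seed": panel_ci.seed,
            },
            "fleiss_kappa": fleiss_kappa(panel),
            "subgroup_kappas": {
                str(k): {"kappa": v[0], "n": v[1]} for k, v in kappas.items()
            },
            "five_rater_kappa_uncertain": kappa_five,
            "n_uncertain_complete": five.n_items,
        },
        "power_design": design.as_dict(),
    }
    validate_report(report)
    return report


# ---------------------------------------------------------------------------
# report schema


def _schema() -> dict:
    with resources.files("asbestriage").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict) -> None:
    """Structural validation of a run report against the shipped schema.

    Checks required keys and primitive types recursively; raises
    ``ValueError`` naming the offending path.
    """
    schema = _schema()
    _validate_node(report, schema["report"], schema, path="report")


_PRIMITIVES = {
    "string": str,
    "number": (int, float),
    "integer": int,
    "object": dict,
    "array": list,
}


def _validate_node(value, spec, schema, path):
    kind = spec["type"] if isinstance(spec, dict) else spec
    if isinstance(kind, str) and kind.startswith("$"):
        _validate_node(value, schema[kind[1:]], schema, path)
        return
    if kind == "number?":
        if value is not None and not isinstance(value, (int, float)):
            raise ValueError(f"{path}: expected number or null, got {type(value).__name__}")
        return
    expected = _PRIMITIVES.get(kind)
    if expected is None:
        raise ValueError(f"schema error at {path}: unknown type {kind!r}")
    if kind == "number" and isinstance(value, bool):
        raise ValueError(f"{path}: expected number, got bool")
    if not isinstance(value, expected):
        raise ValueError(f"{path}: expected {kind}, got {type(value).__name__}")
    if isinstance(spec, dict):
        for key, sub in spec.get("keys", {}).items():
            if key not in value:
                raise ValueError(f"{path}: missing required key {key!r}")
            _validate_node(value[key], sub, schema, f"{path}.{key}")
        if "items" in spec:
            for i, item in enumerate(value):
                _validate_node(item, spec["items"], schema, f"{path}[{i}]")
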