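"""End-to-end validation runs and report bundles.

:func:`run_validation` chains, per score: eligibility filtering -> scoring ->
per-parameter summary table -> cut-point sweep -> recommended cut-points ->
AUC with discrimination label -> ROC points -> predictiveness curve.  A score
whose eligible cohort has a single outcome class yields a partial result
(parameter table and eligibility only) rather than an error.

:func:`write_report` writes per-score CSVs plus a machine-readable
``summary.json``; re-running with the same cohort, config and seed
reproduces byte-identical CSVs and JSON (timestamps go only to ``run.log``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    ALL_SCORES,
    EligibilityReport,
    PatientRecord,
    ScoreSpec,
    filter_eligible,
    get_spec,
)
from .discrimination import (
    AucEstimate,
    PredictivenessCurve,
    RocCurve,
    auc,
    discrimination_label,
    predictiveness_curve,
    roc_points,
)
from .metrics import (
    CutpointTable,
    build_parameter_table,
    cutpoint_sweep,
    recommend_cutpoints,
)
from .scores import PerchConfig, score_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Run-wide options: score adaptations and interval methods."""

    perch: PerchConfig = field(default_factory=PerchConfig)
    risc_age_window: str = "0-24"
    auc_ci_method: str = "delong"       # or "bootstrap"
    lr_haldane: bool = False
    ci_level: float = 0.95

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ScoreReport:
    """Everything the validation computes for one score."""

    spec: ScoreSpec
    eligibility: EligibilityReport
    parameter_table: pd.DataFrame | None
    cutpoints: CutpointTable | None
    recommended_cutpoints: list[int]
    auc: AucEstimate | None
    label: str | None
    roc: RocCurve | None
    predictiveness: PredictivenessCurve | None
    available: bool
    note: str = ""


@dataclass
class ValidationReport:
    per_score: dict[str, ScoreReport]
    seed: int
    config: AnalysisConfig


def run_validation(cohort: Sequence[PatientRecord],
                   specs: Sequence[str | ScoreSpec] | None = None,
                   config: AnalysisConfig | None = None,
                   seed: int = 0) -> ValidationReport:
    """Run the full external-validation pipeline on a cohort."""
    if not cohort:
        raise ValueError("empty cohort")
    config = config or AnalysisConfig()
    specs = specs or ALL_SCORES
    resolved = [
        s if isinstance(s, ScoreSpec)
        else get_spec(s, risc_age_window=config.risc_age_window)
        for s in specs]
    per_score: dict[str, ScoreReport] = {}
    for spec in resolved:
        eligible, report = filter_eligible(cohort, spec)
        logger.info(
            "%s: %d input, %d eligible, %d excluded by age, %d by missingness",
            spec.name, report.n_input, report.n_eligible,
            report.n_excluded_age, report.n_excluded_missing)
        if not eligible:
            per_score[spec.name] = ScoreReport(
                spec, report, None, None, [], None, None, None, None,
                available=False, note="no eligible records")
            continue
        results = score_cohort(eligible, spec.name, config.perch)
        totals = np.array([r.total for r in results])
        outcomes = np.array([r.died for r in eligible], dtype=bool)
        ptable = build_parameter_table(eligible, spec, config.ci_level)
        if outcomes.all() or not outcomes.any():
            per_score[spec.name] = ScoreReport(
                spec, report, ptable, None, [], None, None, None,
                predictiveness_curve(totals, outcomes), available=False,
                note="single outcome class; AUC and cut-point sweep unavailable")
            continue
        table = cutpoint_sweep(totals, outcomes, spec, config.perch,
                               config.ci_level, config.lr_haldane)
        est = auc(totals, outcomes, method=config.auc_ci_method,
                  level=config.ci_level, seed=seed)
        per_score[spec.name] = ScoreReport(
            spec=spec, eligibility=report, parameter_table=ptable,
            cutpoints=table, recommended_cutpoints=recommend_cutpoints(table),
            auc=est, label=discrimination_label(est.auc),
            roc=roc_points(totals, outcomes, spec.name),
            predictiveness=predictiveness_curve(totals, outcomes),
            available=True)
    return ValidationReport(per_score, seed, config)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def write_report(report: ValidationReport, out_dir: str | Path) -> list[Path]:
    """Write the report bundle; returns the files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {"seed": report.seed,
                     "config_hash": report.config.digest(),
                     "scores": {}}
    for name, sr in report.per_score.items():
        d = out / name
        d.mkdir(exist_ok=True)
        if sr.parameter_table is not None:
            _write_csv(sr.parameter_table, d / "parameter_table.csv")
            written.append(d / "parameter_table.csv")
        if sr.cutpoints is not None:
            _write_csv(sr.cutpoints.to_frame(), d / "cutpoints.csv")
            written.append(d / "cutpoints.csv")
        if sr.roc is not None:
            roc_df = pd.DataFrame({
                "cutpoint": [c if c is not None else math.nan
                             for c in sr.roc.cutpoints],
                "fpr": [p[0] for p in sr.roc.points],
                "tpr": [p[1] for p in sr.roc.points]})
            _write_csv(roc_df, d / "roc.csv")
            written.append(d / "roc.csv")
        if sr.predictiveness is not None:
            pred_df = pd.DataFrame(sr.predictiveness.points,
                                   columns=["cum_fraction", "predicted_risk"])
            _write_csv(pred_df, d / "predictiveness.csv")
            written.append(d / "predictiveness.csv")
        summary["scores"][name] = {
            "age_window_months": list(sr.spec.age_window_months),
            "eligibility": {
                "n_input": sr.eligibility.n_input,
                "n_eligible": sr.eligibility.n_eligible,
                "n_excluded_age": sr.eligibility.n_excluded_age,
                "n_excluded_missing": sr.eligibility.n_excluded_missing,
            },
            "available": sr.available,
            "note": sr.note,
            "auc": None if sr.auc is None else {
                "auc": sr.auc.auc, "ci_low": sr.auc.ci_low,
                "ci_high": sr.auc.ci_high, "method": sr.auc.method,
                "n_pos": sr.auc.n_pos, "n_neg": sr.auc.n_neg},
            "discrimination_label": sr.label,
            "recommended_cutpoints": sr.recommended_cutpoints,
        }
    spath = out / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n",
                     encoding="utf-8")
    written.append(spath)
    log = out / "run.log"
    with open(log, "a", encoding="utf-8") as fh:
        fh.write(f"{datetime.now(timezone.utc).isoformat()} seed={report.seed} "
                 f"config={report.config.digest()} "
                 f"scores={sorted(report.per_score)}\n")
    written.append(log)
    return written
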