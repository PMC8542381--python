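"""Case-fatality ratios, 2x2 tables, and cut-point test characteristics.

Proportion confidence intervals are Clopper-Pearson exact intervals (beta
quantiles).  Likelihood-ratio intervals use the standard log-variance
method: ``SE(ln LR+) = sqrt(1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn))`` and the
symmetric formula for LR-, with normal bounds exponentiated back.  Zero
cells yield flagged infinite/undefined LRs rather than exceptions; an
optional Haldane correction (0.5 added to every cell) is available.

Classification at a cut-point ``c`` is positive iff ``score >= c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta
from scipy.stats import norm as _norm

from .cohort import PatientRecord, ScoreSpec
from .scores import PerchConfig, score_range
from ._util import round_half_away


@dataclass
class Proportion:
    """A count proportion with an exact (Clopper-Pearson) interval."""

    numerator: int
    denominator: int
    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError("need 0 <= numerator <= denominator")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("interval does not bracket the estimate")

    @property
    def pct(self) -> float:
        return 100.0 * self.estimate


def exact_binomial_ci(numerator: int, denominator: int,
                      level: float = 0.95) -> Proportion:
    """Clopper-Pearson exact interval for a binomial proportion."""
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not (0 <= numerator <= denominator):
        raise ValueError("need 0 <= numerator <= denominator")
    alpha = 1.0 - level
    k, n = numerator, denominator
    lo = float(_beta.ppf(alpha / 2, k, n - k + 1)) if k > 0 else 0.0
    hi = float(_beta.ppf(1 - alpha / 2, k + 1, n - k)) if k < n else 1.0
    return Proportion(k, n, k / n, lo, hi, level)


def case_fatality_ratio(records: Sequence[PatientRecord],
                        level: float = 0.95) -> Proportion:
    """Deaths / patients with an exact interval."""
    if not records:
        raise ValueError("empty cohort")
    deaths = sum(1 for r in records if r.died)
    return exact_binomial_ci(deaths, len(records), level)


@dataclass
class TwoByTwo:
    """Counts at a cut-point: positive classification iff score >= cutpoint."""

    tp: int
    fp: int
    fn: int
    tn: int
    cutpoint: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_pos(self) -> int:  # deaths
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:  # survivors
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def two_by_two(scores: Sequence[int], outcomes: Sequence[bool],
               cutpoint: int) -> TwoByTwo:
    """Cross-classify scores against outcomes at one cut-point."""
    s = np.asarray(scores)
    y = np.asarray(outcomes, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    pos = s >= cutpoint
    return TwoByTwo(
        tp=int(np.sum(pos & y)), fp=int(np.sum(pos & ~y)),
        fn=int(np.sum(~pos & y)), tn=int(np.sum(~pos & ~y)),
        cutpoint=int(cutpoint))


#: LikelihoodRatio.flag values
LR_OK = "ok"
LR_INFINITE = "infinite"
LR_UNDEFINED = "undefined"


@dataclass
class LikelihoodRatio:
    value: float            # may be math.inf or nan
    ci_low: float
    ci_high: float
    flag: str = LR_OK


def _lr(num: float, den: float) -> tuple[float, str]:
    if den > 0:
        return num / den, LR_OK
    if num > 0:
        return math.inf, LR_INFINITE
    return math.nan, LR_UNDEFINED


def _lr_ci(value: float, a: int, m1: int, b: int, m2: int,
           level: float) -> tuple[float, float]:
    # log-variance method; requires all four quantities positive and finite LR
    if not (math.isfinite(value) and value > 0 and a > 0 and b > 0
            and a < m1 and b < m2):
        return math.nan, math.nan
    se = math.sqrt(1 / a - 1 / m1 + 1 / b - 1 / m2)
    z = float(_norm.ppf(0.5 + level / 2))
    return value * math.exp(-z * se), value * math.exp(z * se)


@dataclass
class Characteristics:
    """Test characteristics derived from one 2x2 table."""

    sensitivity: Proportion
    specificity: Proportion
    lr_pos: LikelihoodRatio
    lr_neg: LikelihoodRatio
    correctly_classified_pct: float


def characteristics(table: TwoByTwo, level: float = 0.95,
                    haldane: bool = False) -> Characteristics:
    """Sensitivity, specificity, LRs and correct-classification percentage.

    With ``haldane=True`` a continuity correction of 0.5 per cell is applied
    to the LR point estimates and intervals (never to sensitivity or
    specificity) whenever a zero cell would otherwise make them degenerate.
    """
    if table.n_pos < 1 or table.n_neg < 1:
        raise ValueError("both outcome classes must be present")
    sens = exact_binomial_ci(table.tp, table.n_pos, level)
    spec = exact_binomial_ci(table.tn, table.n_neg, level)

    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    if haldane and 0 in (tp, fp, fn, tn):
        tp, fp, fn, tn = (x + 0.5 for x in (tp, fp, fn, tn))
    m1, m2 = tp + fn, fp + tn
    lrp_val, lrp_flag = _lr(tp / m1, fp / m2)
    lrn_val, lrn_flag = _lr(fn / m1, tn / m2)
    lrp = LikelihoodRatio(lrp_val, *_lr_ci(lrp_val, tp, m1, fp, m2, level), lrp_flag)
    lrn = LikelihoodRatio(lrn_val, *_lr_ci(lrn_val, fn, m1, tn, m2, level), lrn_flag)
    pct = 100.0 * (table.tp + table.tn) / table.total
    return Characteristics(sens, spec, lrp, lrn, pct)


@dataclass
class CutpointRow:
    """One row of a cut-point table (the supplementary-table layout)."""

    cutpoint: int
    cfr_at_point: Proportion | None   # deaths among score == cutpoint
    correctly_classified_pct: float
    sensitivity: Proportion
    specificity: Proportion
    lr_pos: LikelihoodRatio
    lr_neg: LikelihoodRatio


@dataclass
class CutpointTable:
    score_name: str
    rows: list[CutpointRow]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({
                "cutpoint": r.cutpoint,
                "n_at_point": r.cfr_at_point.denominator if r.cfr_at_point else 0,
                "deaths_at_point": r.cfr_at_point.numerator if r.cfr_at_point else 0,
                "cfr_at_point_pct": r.cfr_at_point.pct if r.cfr_at_point else math.nan,
                "correctly_classified_pct": r.correctly_classified_pct,
                "sensitivity_pct": r.sensitivity.pct,
                "sensitivity_ci_low_pct": 100 * r.sensitivity.ci_low,
                "sensitivity_ci_high_pct": 100 * r.sensitivity.ci_high,
                "specificity_pct": r.specificity.pct,
                "specificity_ci_low_pct": 100 * r.specificity.ci_low,
                "specificity_ci_high_pct": 100 * r.specificity.ci_high,
                "lr_pos": r.lr_pos.value,
                "lr_pos_ci_low": r.lr_pos.ci_low,
                "lr_pos_ci_high": r.lr_pos.ci_high,
                "lr_neg": r.lr_neg.value,
                "lr_neg_ci_low": r.lr_neg.ci_low,
                "lr_neg_ci_high": r.lr_neg.ci_high,
            })
        return pd.DataFrame(recs)


def cutpoint_sweep(scores: Sequence[int], outcomes: Sequence[bool],
                   spec: ScoreSpec | tuple[int, int],
                   config: PerchConfig | None = None,
                   level: float = 0.95, haldane: bool = False) -> CutpointTable:
    """One :class:`CutpointRow` per integer cut-point over the score's range.

    The range comes from exhaustive enumeration of the score named by
    ``spec`` (or an explicit ``(min, max)`` tuple).  Requires both outcome
    classes.
    """
    s = np.asarray(scores)
    y = np.asarray(outcomes, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present for a sweep")
    if isinstance(spec, ScoreSpec):
        lo, hi = score_range(spec.name, config)
        name = spec.name
    else:
        lo, hi = spec
        name = "score"
    rows = []
    for c in range(lo, hi + 1):
        tab = two_by_two(s, y, c)
        ch = characteristics(tab, level, haldane)
        at = s == c
        n_at = int(at.sum())
        cfr = exact_binomial_ci(int(y[at].sum()), n_at, level) if n_at else None
        rows.append(CutpointRow(
            cutpoint=c, cfr_at_point=cfr,
            correctly_classified_pct=ch.correctly_classified_pct,
            sensitivity=ch.sensitivity, specificity=ch.specificity,
            lr_pos=ch.lr_pos, lr_neg=ch.lr_neg))
    return CutpointTable(name, rows)


def recommend_cutpoints(table: CutpointTable) -> list[int]:
    """Cut-points with sensitivity in [60%, 80%] and specificity >= 40%.

    The rule trades maximum sensitivity against a floor on specificity so
    that low-risk children can be identified without flagging most of the
    cohort; all bounds are inclusive.
    """
    return [r.cutpoint for r in table.rows
            if 0.60 <= r.sensitivity.estimate <= 0.80
            and r.specificity.estimate >= 0.40]


# ---------------------------------------------------------------------------
# Per-parameter summary tables

def _strata(spec_name: str):
    # (label, predicate); strata are deliberately NOT mutually exclusive —
    # a child appears in every row whose condition it meets.
    if spec_name == "risc_hiv_negative":
        return [
            ("SpO2 <= 90%", lambda r: r.spo2 <= 90),
            ("Chest indrawing (with SpO2 > 90%)",
             lambda r: r.chest_indrawing and r.spo2 > 90),
            ("Wheezing", lambda r: r.wheeze),
            ("Refusal to feed", lambda r: r.refusal_to_feed),
            ("WAZ <= -3", lambda r: r.waz <= -3),
            ("WAZ > -3 to <= -2", lambda r: -3 < r.waz <= -2),
        ]
    if spec_name == "risc_malawi_waz":
        return [
            ("SpO2 >= 93%", lambda r: r.spo2 >= 93),
            ("SpO2 90%-92%", lambda r: 90 <= r.spo2 < 93),
            ("SpO2 < 90%", lambda r: r.spo2 < 90),
            ("WAZ >= -2", lambda r: r.waz >= -2),
            ("WAZ >= -3 to < -2", lambda r: -3 <= r.waz < -2),
            ("WAZ < -3", lambda r: r.waz < -3),
            ("Female", lambda r: r.sex == "female"),
            ("Wheezing", lambda r: r.wheeze),
            ("Unconscious", lambda r: r.unconscious),
        ]
    if spec_name == "perch_adapted":
        return [
            ("Age 1-11 months", lambda r: r.age_months < 12),
            ("Female", lambda r: r.sex == "female"),
            ("Unresponsiveness", lambda r: r.unconscious),
            ("Cough (history)", lambda r: r.cough_history),
            ("Grunting (observed)", lambda r: r.grunting),
            ("SpO2 < 92%", lambda r: r.spo2 < 92),
            ("Max duration of illness >= 3 d",
             lambda r: r.illness_duration_days >= 3),
            ("WAZ < -3", lambda r: r.waz < -3),
            ("WAZ >= -3 to < -2", lambda r: -3 <= r.waz < -2),
        ]
    raise ValueError(f"unknown score {spec_name!r}")


def build_parameter_table(records: Sequence[PatientRecord], spec: ScoreSpec,
                          level: float = 0.95) -> pd.DataFrame:
    """Per-parameter n, % of cohort, deaths, and CFR with exact CI.

    Mirrors the published per-parameter summary layout: one row per score
    parameter stratum plus a Total row (whose ``pct`` is blank).  The cohort
    must already be eligibility-filtered for ``spec``.
    """
    if not records:
        raise ValueError("empty cohort")
    n_total = len(records)
    out = []
    for label, pred in _strata(spec.name):
        members = [r for r in records if pred(r)]
        n = len(members)
        deaths = sum(1 for r in members if r.died)
        if n:
            cfr = exact_binomial_ci(deaths, n, level)
            cfr_pct, lo, hi = cfr.pct, 100 * cfr.ci_low, 100 * cfr.ci_high
        else:
            cfr_pct = lo = hi = math.nan
        out.append({"parameter": label, "n": n, "pct": 100.0 * n / n_total,
                    "deaths": deaths, "cfr_pct": cfr_pct,
                    "cfr_ci_low_pct": lo, "cfr_ci_high_pct": hi})
    total = case_fatality_ratio(records, level)
    out.append({"parameter": "Total", "n": n_total, "pct": math.nan,
                "deaths": total.numerator, "cfr_pct": total.pct,
                "cfr_ci_low_pct": 100 * total.ci_low,
                "cfr_ci_high_pct": 100 * total.ci_high})
    return pd.DataFrame(out)


def format_parameter_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display form: percentages rounded half-away-from-zero to 1 decimal."""
    disp = table.copy()
    for col in ("pct", "cfr_pct", "cfr_ci_low_pct", "cfr_ci_high_pct"):
        disp[col] = [round_half_away(v, 1) if not math.isnan(v) else math.nan
                     for v in disp[col]]
    return disp
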