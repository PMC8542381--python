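"""The three weighted point scores, with score-range enumeration.

Weights implemented here (all integers):

RISC, HIV-negative children (range -2..6)
    SpO2 <= 90%                        +3
    chest indrawing (only if SpO2>90)  +2
    wheezing                           -2
    refusal to feed                    +1
    WAZ <= -3 / -3 < WAZ <= -2         +2 / +1

RISC-Malawi, WAZ variant (range -1..17)
    SpO2 >= 93 / 90-92 / < 90          0 / +1 / +5
    WAZ >= -2 / [-3,-2) / < -3         0 / +3 / +6
    female                             +1
    wheezing                           -1
    unconscious                        +5

PERCH, as externally adapted (range -1..12 with default config)
    age 1-11 months / 12-59 months     +2 / 0
    female                             +1
    history of cough                   -1
    grunting (observed)                +2
    SpO2 < 92%                         +2
    illness duration 3-5 d / > 5 d     +2 / +2 (distinct labels, equal weight)
    WAZ >= -2 / [-3,-2) / < -3         0 / +2 / +3
    unconsciousness                    +0 by default (configurable to +2)

The two WAZ category conventions differ at the band edges: the RISC bands
are severe iff WAZ <= -3 and moderate iff -3 < WAZ <= -2, whereas RISC-Malawi
and PERCH use severe iff WAZ < -3 and moderate iff -3 <= WAZ < -2, so a child
with WAZ exactly -3 is severe under RISC but moderate under the others.

Score ranges are always found by exhaustive enumeration over category
combinations (:func:`score_range`), never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

from .cohort import (
    ALL_SCORES,
    FEMALE,
    MALE,
    PERCH_ADAPTED,
    RISC_HIV_NEGATIVE,
    RISC_MALAWI_WAZ,
    PatientRecord,
)

#: WAZ category conventions.
WAZ_RISC = "risc"          # severe iff waz <= -3; moderate iff -3 < waz <= -2
WAZ_MALAWI = "malawi"      # severe iff waz < -3; moderate iff -3 <= waz < -2

SEVERE, MODERATE, NORMAL = "severe", "moderate", "normal"


@dataclass
class ScoreResult:
    """Total points plus the per-parameter contribution breakdown."""

    score_name: str
    total: int
    components: list[tuple[str, int]]
    record_id: str

    def __post_init__(self) -> None:
        if self.total != sum(p for _, p in self.components):
            raise ValueError("total does not equal the sum of components")


@dataclass(frozen=True)
class PerchConfig:
    """Options for the adapted PERCH score.

    ``unresponsive_weight`` is 0 by default so the enumerated maximum equals
    the published external-application maximum of 12; setting it to 2 restores
    the original derivation weight for sensitivity analyses.
    """

    unresponsive_weight: int = 0

    def __post_init__(self) -> None:
        if self.unresponsive_weight not in (0, 2):
            raise ValueError("unresponsive_weight must be 0 or 2")


def categorize_waz(waz: float, convention: str) -> str:
    """Map a weight-for-age z-score onto {severe, moderate, normal}."""
    if waz is None:
        raise ValueError("waz is null; filter the cohort before scoring")
    if convention == WAZ_RISC:
        if waz <= -3:
            return SEVERE
        if waz <= -2:
            return MODERATE
        return NORMAL
    if convention == WAZ_MALAWI:
        if waz < -3:
            return SEVERE
        if waz < -2:
            return MODERATE
        return NORMAL
    raise ValueError(f"unknown WAZ convention {convention!r}")


def _require(record: PatientRecord, fields: Iterable[str]) -> None:
    for f in fields:
        if getattr(record, f) is None:
            raise ValueError(f"{record.patient_id}: required field {f!r} is null")


def score_risc_hiv_negative(record: PatientRecord) -> ScoreResult:
    """RISC score for HIV-negative children.

    Hypoxemia dominates the conditional rule: 3 points for SpO2 <= 90%;
    chest indrawing only enters (2 points) when SpO2 > 90%.
    """
    _require(record, ("spo2", "chest_indrawing", "wheeze", "refusal_to_feed", "waz"))
    components: list[tuple[str, int]] = []
    if record.spo2 <= 90:
        components.append(("SpO2 <= 90%", 3))
        components.append(("chest indrawing (not scored, SpO2 <= 90%)", 0))
    else:
        components.append(("SpO2 > 90%", 0))
        components.append(
            ("chest indrawing (SpO2 > 90%)", 2 if record.chest_indrawing else 0))
    components.append(("wheezing", -2 if record.wheeze else 0))
    components.append(("refusal to feed", 1 if record.refusal_to_feed else 0))
    cat = categorize_waz(record.waz, WAZ_RISC)
    components.append((f"WAZ {cat}", {SEVERE: 2, MODERATE: 1, NORMAL: 0}[cat]))
    return ScoreResult(
        RISC_HIV_NEGATIVE, sum(p for _, p in components), components,
        record.patient_id)


def score_risc_malawi_waz(record: PatientRecord) -> ScoreResult:
    """RISC-Malawi score, weight-for-age z-score variant."""
    _require(record, ("spo2", "sex", "wheeze", "unconscious", "waz"))
    components: list[tuple[str, int]] = []
    if record.spo2 >= 93:
        components.append(("SpO2 >= 93%", 0))
    elif record.spo2 >= 90:
        components.append(("SpO2 90%-92%", 1))
    else:
        components.append(("SpO2 < 90%", 5))
    cat = categorize_waz(record.waz, WAZ_MALAWI)
    components.append((f"WAZ {cat}", {SEVERE: 6, MODERATE: 3, NORMAL: 0}[cat]))
    components.append(("female", 1 if record.sex == FEMALE else 0))
    components.append(("wheezing", -1 if record.wheeze else 0))
    components.append(("unconscious", 5 if record.unconscious else 0))
    return ScoreResult(
        RISC_MALAWI_WAZ, sum(p for _, p in components), components,
        record.patient_id)


def score_perch_adapted(
    record: PatientRecord, config: PerchConfig | None = None
) -> ScoreResult:
    """PERCH score as adapted for external application.

    Adaptations relative to the original derivation: history of cough stands
    in for observed cough, unconsciousness for unresponsiveness, WAZ for
    weight-for-height z-score; the "deep breathing" qualifier is unavailable,
    so unresponsiveness carries weight ``config.unresponsive_weight``
    (default 0, giving the external maximum of 12).
    """
    config = config or PerchConfig()
    _require(record, ("age_months", "sex", "cough_history", "grunting", "spo2",
                      "illness_duration_days", "waz", "unconscious"))
    components: list[tuple[str, int]] = []
    if record.age_months < 12:
        components.append(("age 1-11 months", 2))
    else:
        components.append(("age 12-59 months", 0))
    components.append(("female", 1 if record.sex == FEMALE else 0))
    components.append(("history of cough", -1 if record.cough_history else 0))
    components.append(("grunting (observed)", 2 if record.grunting else 0))
    components.append(("SpO2 < 92%", 2 if record.spo2 < 92 else 0))
    d = record.illness_duration_days
    if d < 3:
        components.append(("duration of illness < 3 d", 0))
    elif d <= 5:
        components.append(("duration of illness 3-5 d", 2))
    else:
        components.append(("duration of illness > 5 d", 2))
    cat = categorize_waz(record.waz, WAZ_MALAWI)
    components.append((f"WAZ {cat}", {SEVERE: 3, MODERATE: 2, NORMAL: 0}[cat]))
    components.append(
        ("unconscious", config.unresponsive_weight if record.unconscious else 0))
    return ScoreResult(
        PERCH_ADAPTED, sum(p for _, p in components), components,
        record.patient_id)


def score_record(
    record: PatientRecord, score_name: str, config: PerchConfig | None = None
) -> ScoreResult:
    """Dispatch a single record to one of the three scoring functions."""
    if score_name == RISC_HIV_NEGATIVE:
        return score_risc_hiv_negative(record)
    if score_name == RISC_MALAWI_WAZ:
        return score_risc_malawi_waz(record)
    if score_name == PERCH_ADAPTED:
        return score_perch_adapted(record, config)
    raise ValueError(f"unknown score {score_name!r}; expected one of {ALL_SCORES}")


def score_cohort(
    records: Sequence[PatientRecord], score_name: str,
    config: PerchConfig | None = None,
) -> list[ScoreResult]:
    """Score every record in an (eligible) cohort."""
    return [score_record(r, score_name, config) for r in records]


# ---------------------------------------------------------------------------
# Range enumeration

# Representative values for each parameter category; scoring functions are
# piecewise-constant on these categories, so enumerating representatives
# enumerates all achievable totals.
_WAZ_REPS = (-3.5, -2.5, 0.0)
_BOOL = (True, False)


def _enumeration_records(score_name: str):
    if score_name == RISC_HIV_NEGATIVE:
        for spo2, ind, wheeze, refusal, waz in product(
                (85.0, 95.0), _BOOL, _BOOL, _BOOL, (-3.0, -2.5, 0.0)):
            yield PatientRecord(
                "enum", 6.0, False, spo2=spo2, chest_indrawing=ind,
                wheeze=wheeze, refusal_to_feed=refusal, waz=waz)
    elif score_name == RISC_MALAWI_WAZ:
        for spo2, waz, sex, wheeze, unconscious in product(
                (85.0, 91.0, 95.0), _WAZ_REPS, (MALE, FEMALE), _BOOL, _BOOL):
            yield PatientRecord(
                "enum", 12.0, False, spo2=spo2, waz=waz, sex=sex,
                wheeze=wheeze, unconscious=unconscious)
    elif score_name == PERCH_ADAPTED:
        for age, sex, cough, grunt, spo2, dur, waz, unconscious in product(
                (6.0, 24.0), (MALE, FEMALE), _BOOL, _BOOL, (90.0, 95.0),
                (1.0, 4.0, 7.0), _WAZ_REPS, _BOOL):
            yield PatientRecord(
                "enum", age, False, sex=sex, cough_history=cough,
                grunting=grunt, spo2=spo2, illness_duration_days=dur,
                waz=waz, unconscious=unconscious)
    else:
        raise ValueError(f"unknown score {score_name!r}")


def enumerate_scores(
    score_name: str, config: PerchConfig | None = None
) -> list[int]:
    """Totals over every parameter category combination (with duplicates)."""
    return [score_record(r, score_name, config).total
            for r in _enumeration_records(score_name)]


def score_range(
    score_name: str, config: PerchConfig | None = None
) -> tuple[int, int]:
    """(min, max) achievable total, by exhaustive enumeration."""
    totals = enumerate_scores(score_name, config)
    return min(totals), max(totals)
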