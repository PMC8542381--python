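"""Patient record data model, cohort CSV I/O, and eligibility filtering.

A cohort is a list of :class:`PatientRecord`.  Each of the three risk scores
is described by a :class:`ScoreSpec` carrying its age window (half-open, in
completed months) and the set of record fields it requires.  Validation is
complete-case: :func:`filter_eligible` drops records outside the age window
first, then records missing any required field, and reports the partition.

Missing values are explicit ``None``s, never sentinel numerics.  The
canonical on-disk form is a UTF-8 CSV with one header row; empty cells are
nulls and booleans serialize as ``1``/``0``.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, fields as _dc_fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"

RISC_HIV_NEGATIVE = "risc_hiv_negative"
RISC_MALAWI_WAZ = "risc_malawi_waz"
PERCH_ADAPTED = "perch_adapted"
ALL_SCORES = (RISC_HIV_NEGATIVE, RISC_MALAWI_WAZ, PERCH_ADAPTED)

#: Canonical cohort CSV column order.
CANONICAL_COLUMNS = [
    "patient_id", "age_months", "sex", "spo2", "chest_indrawing", "wheeze",
    "refusal_to_feed", "grunting", "cough_history", "unconscious",
    "illness_duration_days", "waz", "died",
]

MANDATORY_COLUMNS = ("patient_id", "age_months", "died")

_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f"}
_SEX_TOKENS = {"male": MALE, "m": MALE, "female": FEMALE, "f": FEMALE}

# nullable float fields with plausibility windows; values outside become null
_FLOAT_RANGES = {
    "spo2": (0.0, 100.0),
    "illness_duration_days": (0.0, math.inf),
    "waz": (-10.0, 10.0),
}
_BOOL_FIELDS = (
    "chest_indrawing", "wheeze", "refusal_to_feed", "grunting",
    "cough_history", "unconscious",
)


@dataclass
class PatientRecord:
    """One hospitalized child: demographics, clinical signs, WAZ, outcome.

    All clinical fields are nullable to model missingness; ``age_months``,
    ``patient_id`` and the outcome ``died`` are always present.
    """

    patient_id: str
    age_months: float
    died: bool
    sex: str | None = None
    spo2: float | None = None
    chest_indrawing: bool | None = None
    wheeze: bool | None = None
    refusal_to_feed: bool | None = None
    grunting: bool | None = None
    cough_history: bool | None = None
    unconscious: bool | None = None
    illness_duration_days: float | None = None
    waz: float | None = None

    def __post_init__(self) -> None:
        if self.died is None:
            raise ValueError(f"{self.patient_id}: outcome 'died' may not be null")
        if self.age_months is None or self.age_months < 0:
            raise ValueError(f"{self.patient_id}: age_months must be a non-negative number")
        if self.sex is not None and self.sex not in (MALE, FEMALE):
            raise ValueError(f"{self.patient_id}: sex must be 'male' or 'female', got {self.sex!r}")
        for name, (lo, hi) in _FLOAT_RANGES.items():
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise ValueError(f"{self.patient_id}: {name}={v} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class ScoreSpec:
    """A risk score's eligibility contract: age window and required fields."""

    name: str
    age_window_months: tuple[float, float]  # half-open [lo, hi)
    required_fields: frozenset[str]


_REQUIRED = {
    RISC_HIV_NEGATIVE: frozenset(
        {"spo2", "chest_indrawing", "wheeze", "refusal_to_feed", "waz"}),
    RISC_MALAWI_WAZ: frozenset(
        {"spo2", "sex", "wheeze", "unconscious", "waz"}),
    PERCH_ADAPTED: frozenset(
        {"age_months", "sex", "cough_history", "grunting", "spo2",
         "illness_duration_days", "waz", "unconscious"}),
}

_DEFAULT_WINDOWS = {
    RISC_HIV_NEGATIVE: (0.0, 25.0),
    RISC_MALAWI_WAZ: (2.0, 60.0),
    PERCH_ADAPTED: (1.0, 60.0),
}


def get_spec(name: str, *, risc_age_window: str = "0-24") -> ScoreSpec:
    """Return the :class:`ScoreSpec` for one of the three scores.

    ``risc_age_window`` switches the RISC HIV-negative score between its
    primary 0-24 month application (``"0-24"``, window [0, 25)) and the
    supplementary 0-59 month application (``"0-59"``, window [0, 60)).
    """
    if name not in _REQUIRED:
        raise ValueError(f"unknown score {name!r}; expected one of {ALL_SCORES}")
    window = _DEFAULT_WINDOWS[name]
    if name == RISC_HIV_NEGATIVE:
        if risc_age_window == "0-59":
            window = (0.0, 60.0)
        elif risc_age_window != "0-24":
            raise ValueError("risc_age_window must be '0-24' or '0-59'")
    return ScoreSpec(name, window, _REQUIRED[name])


@dataclass
class EligibilityReport:
    """Partition of an input cohort under one score's eligibility rule."""

    n_input: int
    n_eligible: int
    n_excluded_age: int
    n_excluded_missing: int
    excluded_reasons: dict[str, str]

    def __post_init__(self) -> None:
        if self.n_input != self.n_eligible + self.n_excluded_age + self.n_excluded_missing:
            raise ValueError("eligibility counts do not partition the input")


def filter_eligible(
    records: Sequence[PatientRecord], spec: ScoreSpec
) -> tuple[list[PatientRecord], EligibilityReport]:
    """Apply the complete-case, age-window eligibility rule for one score.

    A record is eligible iff its age lies in the spec's half-open window and
    every required field is non-null.  Age is assessed first: a record
    failing both tests counts as an age exclusion.
    """
    lo, hi = spec.age_window_months
    eligible: list[PatientRecord] = []
    reasons: dict[str, str] = {}
    n_age = n_missing = 0
    for rec in records:
        if not (lo <= rec.age_months < hi):
            n_age += 1
            reasons[rec.patient_id] = "age"
            continue
        missing = sorted(f for f in spec.required_fields if getattr(rec, f) is None)
        if missing:
            n_missing += 1
            reasons[rec.patient_id] = "missing:" + ",".join(missing)
            continue
        eligible.append(rec)
    report = EligibilityReport(
        n_input=len(records),
        n_eligible=len(eligible),
        n_excluded_age=n_age,
        n_excluded_missing=n_missing,
        excluded_reasons=reasons,
    )
    return eligible, report


# ---------------------------------------------------------------------------
# CSV I/O


def load_dialect(path: str | Path) -> dict:
    """Load a YAML/JSON column-mapping config.

    Recognised keys: ``columns`` (user column name -> canonical name),
    ``true_tokens`` / ``false_tokens`` (extra boolean spellings).
    """
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    import yaml

    return yaml.safe_load(text)


def _parse_bool(token: str, true_tokens: set, false_tokens: set) -> bool | None:
    t = token.strip().lower()
    if t in true_tokens:
        return True
    if t in false_tokens:
        return False
    return None


def read_cohort(
    path: str | Path, dialect: Mapping | str | Path | None = None
) -> list[PatientRecord]:
    """Read a cohort CSV into :class:`PatientRecord`\\ s.

    Unparseable or out-of-range numeric cells become nulls; the number of
    such cells is logged as a warning.  Missing mandatory columns
    (patient_id, age_months, died) or an empty file are hard errors.
    """
    if dialect is not None and not isinstance(dialect, Mapping):
        dialect = load_dialect(dialect)
    dialect = dict(dialect or {})
    colmap = {v: k for k, v in dialect.get("columns", {}).items()}  # canonical -> user
    true_tokens = _TRUE_TOKENS | {t.lower() for t in dialect.get("true_tokens", [])}
    false_tokens = _FALSE_TOKENS | {t.lower() for t in dialect.get("false_tokens", [])}

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        header = set(reader.fieldnames)
        missing_cols = [
            c for c in MANDATORY_COLUMNS if colmap.get(c, c) not in header
        ]
        if missing_cols:
            raise ValueError(
                f"{path}: missing mandatory column(s): {', '.join(missing_cols)}"
            )
        rows = list(reader)
    if not rows:
        raise ValueError(f"{path}: no data rows")

    def cell(row: Mapping, canonical: str) -> str:
        return (row.get(colmap.get(canonical, canonical)) or "").strip()

    records: list[PatientRecord] = []
    n_warn = 0
    for i, row in enumerate(rows):
        pid = cell(row, "patient_id") or f"row{i + 1}"
        died = _parse_bool(cell(row, "died"), true_tokens, false_tokens)
        if died is None:
            raise ValueError(f"{path}: row {i + 1} ({pid}): unparseable 'died' value")
        try:
            age = float(cell(row, "age_months"))
            if age < 0:
                raise ValueError
        except ValueError:
            raise ValueError(
                f"{path}: row {i + 1} ({pid}): unparseable age_months"
            ) from None
        kwargs: dict = {"patient_id": pid, "age_months": age, "died": died}
        sex_tok = cell(row, "sex").lower()
        if sex_tok:
            kwargs["sex"] = _SEX_TOKENS.get(sex_tok)
            if kwargs["sex"] is None:
                n_warn += 1
        for name, (lo, hi) in _FLOAT_RANGES.items():
            tok = cell(row, name)
            if not tok:
                continue
            try:
                v = float(tok)
            except ValueError:
                n_warn += 1
                continue
            if not (lo <= v <= hi):
                n_warn += 1
                continue
            kwargs[name] = v
        for name in _BOOL_FIELDS:
            tok = cell(row, name)
            if not tok:
                continue
            b = _parse_bool(tok, true_tokens, false_tokens)
            if b is None:
                n_warn += 1
            else:
                kwargs[name] = b
        records.append(PatientRecord(**kwargs))
    if n_warn:
        logger.warning("%s: %d cell(s) unparseable or out of range, set to null", path, n_warn)
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    return str(value)


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records to the canonical cohort CSV (round-trips exactly)."""
    if not records:
        raise ValueError("refusing to write an empty cohort")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for rec in records:
            writer.writerow([_fmt(getattr(rec, c)) for c in CANONICAL_COLUMNS])


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort as a pandas DataFrame in canonical column order."""
    return pd.DataFrame(
        [{c: getattr(r, c) for c in CANONICAL_COLUMNS} for r in records],
        columns=CANONICAL_COLUMNS,
    )


def with_missing(record: PatientRecord, field: str) -> PatientRecord:
    """Copy of ``record`` with one nullable field set to null."""
    if field == "died":
        raise ValueError("the outcome 'died' may not be nulled")
    return replace(record, **{field: None})
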