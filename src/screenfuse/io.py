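"""Encounter-level data model and table I/O.

The canonical in-memory container for a cohort is a :class:`pandas.DataFrame`
with one row per patient visit and a fixed column set (:data:`COHORT_COLUMNS`).
Self-injurious-event tables are a second DataFrame (:data:`EVENT_COLUMNS`).
Files are delimited text (CSV) with ISO-8601 dates; ``.parquet`` is accepted
as a columnar alternative.  Typed per-row views (:class:`ScreeningResponse`,
:class:`Encounter`, :class:`EventRecord`) are provided for callers that prefer
objects over rows.

The six-question screener cascades: questions 3-5 (method / intent / plan)
are asked only when question 2 (suicidal thoughts) is answered yes.  The
unasked state is stored as the explicit sentinel ``"NA"``, distinct from
``"no"``; it is flattened to 0 only at feature-encoding time.  Question 6
(suicidal behavior) is stored as a recency category because the triage tiers
depend on how recent the behavior was, while the regression uses a binary
flattening.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, IntegrityError, ParseError, SchemaError

# ---------------------------------------------------------------------------
# Enumerations and column layout
# ---------------------------------------------------------------------------

YES = "yes"
NO = "no"
NOT_ASKED = "NA"

YES_NO = (YES, NO)
YES_NO_NA = (YES, NO, NOT_ASKED)

#: Recency of most recent suicidal behavior (question 6), least to most severe.
Q6_LEVELS = ("never", "more_than_1y", "3mo_to_1y", "within_3mo")

SETTINGS = ("ED", "inpatient", "psychiatric_ED", "ambulatory_surgery", "other")
SEXES = ("female", "male", "unknown")
RACES = ("black", "white", "other", "unknown")

OUTCOMES = ("SA", "SI")

QUESTION_COLUMNS = ("q1", "q2", "q3", "q4", "q5")

COHORT_COLUMNS = (
    "patient_id",
    "encounter_id",
    "discharge_date",
    "setting",
    "age",
    "sex",
    "race",
    "ehr_score",
    "q1",
    "q2",
    "q3",
    "q4",
    "q5",
    "q6_recency",
    "comment_present",
)

EVENT_COLUMNS = ("patient_id", "event_date", "code")

_FLOAT_FORMAT = "%.17g"  # round-trips IEEE doubles exactly


# ---------------------------------------------------------------------------
# Typed row views
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreeningResponse:
    """One administered screening instance: six questions plus a comment flag.

    ``q1``/``q2`` and ``comment_present`` are ``"yes"``/``"no"``; ``q3``-``q5``
    additionally admit ``"NA"`` (not asked); ``q6_recency`` is one of
    :data:`Q6_LEVELS`.
    """

    q1: str
    q2: str
    q3: str
    q4: str
    q5: str
    q6_recency: str
    comment_present: str

    def __post_init__(self):
        for name in ("q1", "q2", "comment_present"):
            if getattr(self, name) not in YES_NO:
                raise ParseError(f"{name} must be yes/no, got {getattr(self, name)!r}")
        for name in ("q3", "q4", "q5"):
            if getattr(self, name) not in YES_NO_NA:
                raise ParseError(f"{name} must be yes/no/NA, got {getattr(self, name)!r}")
        if self.q6_recency not in Q6_LEVELS:
            raise ParseError(f"q6_recency must be one of {Q6_LEVELS}, got {self.q6_recency!r}")
        if self.q2 == NO and not (self.q3 == self.q4 == self.q5 == NOT_ASKED):
            raise IntegrityError("q3-q5 must be NA when q2 is no")
        if self.q2 == YES and NOT_ASKED in (self.q3, self.q4, self.q5):
            raise IntegrityError("q3-q5 must be answered when q2 is yes")


@dataclass(frozen=True)
class Encounter:
    """One patient visit with its screening response and EHR risk score."""

    patient_id: str
    encounter_id: str
    discharge_date: pd.Timestamp
    setting: str
    age: int
    sex: str
    race: str
    ehr_score: float
    screening: ScreeningResponse

    def __post_init__(self):
        if not 0.0 <= self.ehr_score <= 1.0:
            raise ParseError(f"ehr_score must lie in [0,1], got {self.ehr_score}")


@dataclass(frozen=True)
class EventRecord:
    """A dated, coded self-injurious-thought-or-behavior event."""

    patient_id: str
    event_date: pd.Timestamp
    code: str


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _first_bad_row(mask: pd.Series) -> int:
    return int(mask.idxmax())


def validate_cohort(df: pd.DataFrame) -> None:
    """Validate a cohort DataFrame in place; raise on the first violation.

    Checks the column set, every enumeration, the ``ehr_score`` range,
    encounter-id uniqueness, and the question cascade.  Violations raise
    :class:`SchemaError`, :class:`ParseError` or :class:`IntegrityError`
    with the offending row index; nothing is silently repaired.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing column(s): {', '.join(missing)}")

    enums = {
        "setting": SETTINGS,
        "sex": SEXES,
        "race": RACES,
        "q1": YES_NO,
        "q2": YES_NO,
        "q3": YES_NO_NA,
        "q4": YES_NO_NA,
        "q5": YES_NO_NA,
        "q6_recency": Q6_LEVELS,
        "comment_present": YES_NO,
    }
    for col, allowed in enums.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = _first_bad_row(bad)
            raise ParseError(
                f"invalid value {df[col].loc[row]!r} in column {col!r}", row=row
            )

    score = pd.to_numeric(df["ehr_score"], errors="coerce")
    bad = score.isna() | (score < 0) | (score > 1)
    if bad.any():
        raise ParseError("ehr_score outside [0,1]", row=_first_bad_row(bad))

    if df["encounter_id"].duplicated().any():
        row = _first_bad_row(df["encounter_id"].duplicated())
        raise IntegrityError("duplicate encounter_id", row=row)

    q2_no = df["q2"] == NO
    for col in ("q3", "q4", "q5"):
        bad = q2_no & (df[col] != NOT_ASKED)
        if bad.any():
            raise IntegrityError(
                f"{col} populated while q2 = no (cascade violation)",
                row=_first_bad_row(bad),
            )
        bad = ~q2_no & (df[col] == NOT_ASKED)
        if bad.any():
            raise IntegrityError(
                f"{col} not asked while q2 = yes (cascade violation)",
                row=_first_bad_row(bad),
            )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _postprocess_cohort(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, list(COHORT_COLUMNS)].reset_index(drop=True)
    df["discharge_date"] = pd.to_datetime(df["discharge_date"])
    df["age"] = df["age"].astype(int)
    df["ehr_score"] = df["ehr_score"].astype(float)
    for col in ("patient_id", "encounter_id"):
        df[col] = df[col].astype(str)
    validate_cohort(df)
    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate an encounter table (CSV or parquet)."""
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing column(s): {', '.join(missing)}")
    return _postprocess_cohort(df)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a validated cohort; output is byte-stable for identical input."""
    if len(cohort) == 0:
        raise SchemaError("refusing to write an empty cohort")
    validate_cohort(cohort)
    out = cohort.loc[:, list(COHORT_COLUMNS)].copy()
    out["discharge_date"] = pd.to_datetime(out["discharge_date"]).dt.strftime("%Y-%m-%d")
    path = Path(path)
    if path.suffix == ".parquet":
        out.to_parquet(path, index=False)
    else:
        out.to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event table (patient_id, event_date, code)."""
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"event table missing column(s): {', '.join(missing)}")
    df = df.loc[:, list(EVENT_COLUMNS)].reset_index(drop=True)
    df["event_date"] = pd.to_datetime(df["event_date"])
    df["patient_id"] = df["patient_id"].astype(str)
    df["code"] = df["code"].astype(str)
    return df


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.loc[:, list(EVENT_COLUMNS)].copy()
    out["event_date"] = pd.to_datetime(out["event_date"]).dt.strftime("%Y-%m-%d")
    path = Path(path)
    if path.suffix == ".parquet":
        out.to_parquet(path, index=False)
    else:
        out.to_csv(path, index=False, lineterminator="\n")


def cohort_to_encounters(df: pd.DataFrame) -> list[Encounter]:
    """Materialize typed row objects from a cohort DataFrame."""
    out = []
    for row in df.itertuples(index=False):
        screening = ScreeningResponse(
            q1=row.q1, q2=row.q2, q3=row.q3, q4=row.q4, q5=row.q5,
            q6_recency=row.q6_recency, comment_present=row.comment_present,
        )
        out.append(
            Encounter(
                patient_id=row.patient_id,
                encounter_id=row.encounter_id,
                discharge_date=pd.Timestamp(row.discharge_date),
                setting=row.setting,
                age=int(row.age),
                sex=row.sex,
                race=row.race,
                ehr_score=float(row.ehr_score),
                screening=screening,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: Default synthetic code alphabet; real ICD lists are user-supplied config.
DEFAULT_CODE_LISTS = {
    "SA": ["SA-1", "SA-2"],
    "SI": ["SI-1", "SI-2"],
}


@dataclass
class AnalysisConfig:
    """Run-wide configuration for the screening/fusion analysis.

    ``horizons`` are the day counts after discharge at which outcomes are
    ascertained; ``percentile_cutoffs`` drive the threshold tables;
    ``code_lists`` map each outcome to its diagnostic-code set.
    """

    horizons: list[int] = field(default_factory=lambda: [7, 30, 60, 90, 180])
    outcomes: list[str] = field(default_factory=lambda: ["SA", "SI"])
    percentile_cutoffs: list[float] = field(default_factory=lambda: [50, 75, 90, 95, 99])
    n_folds: int = 5
    seed: int = 0
    code_lists: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CODE_LISTS.items()}
    )

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.horizons or any(h <= 0 for h in self.horizons):
            raise ConfigError("horizons must be positive")
        if any(b <= a for a, b in zip(self.horizons, self.horizons[1:])):
            raise ConfigError("horizons must be strictly increasing")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        bad = [o for o in self.outcomes if o not in OUTCOMES]
        if bad:
            raise ConfigError(f"unknown outcome(s): {bad}")
        for p in self.percentile_cutoffs:
            if not 0 < p < 100:
                raise ConfigError(f"percentile cutoff {p} outside (0, 100)")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a YAML or JSON document mirroring the field names."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)
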