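"""Core data model for event-level EHR extracts.

Everything downstream (the severity phenotyper, survey scoring, the
analysis stage) consumes the types defined here: a :class:`Person`, dated
coded :class:`ClinicalEvent` records, :class:`Encounter` visits with a
care-setting class, and a per-person :class:`EventTimeline`.

Conventions fixed once, here:

* Dates are calendar dates without times; every interval is measured in
  whole days (:func:`days_between`).
* Day windows phrased as "within N days after" are inclusive on both
  ends: offsets ``0..N`` qualify.
* Emergency-department visits are a distinct care setting and never
  count as inpatient admissions; an unknown visit setting is treated as
  outpatient (with a warning) so that uncertain data can never create
  the most severe class.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Vocabulary",
    "EventClass",
    "CareSetting",
    "Person",
    "ClinicalEvent",
    "Encounter",
    "EventTimeline",
    "SchemaConfig",
    "ReadResult",
    "days_between",
    "read_dataset",
    "write_dataset",
]


class Sex(str, Enum):
    female = "female"
    male = "male"
    other = "other"
    unknown = "unknown"


class Vocabulary(str, Enum):
    ICD9CM = "ICD9CM"
    ICD10CM = "ICD10CM"
    CPT = "CPT"
    LOCAL = "LOCAL"


class EventClass(str, Enum):
    diagnosis = "diagnosis"
    procedure = "procedure"
    imaging = "imaging"


class CareSetting(str, Enum):
    inpatient = "inpatient"
    outpatient = "outpatient"
    emergency = "emergency"


@dataclass
class Person:
    """One study participant.

    ``deprivation_index`` is a pre-computed area-level deprivation score
    in [0, 1] (higher = more deprived); ``charlson_index`` is the
    Charlson Comorbidity Index consumed as an input field.
    ``survey_dates`` maps survey/instrument names (e.g. ``"earliest"``,
    ``"healthcare_access"``, ``"sdoh"``) to completion dates.
    """

    person_id: str
    birth_date: dt.date | None = None
    sex_at_birth: Sex = Sex.unknown
    bmi: float | None = None
    charlson_index: int | None = None
    deprivation_index: float | None = None
    survey_dates: dict[str, dt.date] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.deprivation_index is not None and not (
            0.0 <= self.deprivation_index <= 1.0
        ):
            raise ValueError(
                f"deprivation_index must lie in [0, 1], got {self.deprivation_index}"
            )
        if self.charlson_index is not None and self.charlson_index < 0:
            raise ValueError("charlson_index must be non-negative")


@dataclass(frozen=True)
class ClinicalEvent:
    """A dated, coded diagnosis / procedure / imaging record."""

    person_id: str
    event_date: dt.date
    code: str
    vocabulary: Vocabulary
    event_class: EventClass
    encounter_id: str | None = None

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("ClinicalEvent.code must be non-empty")


@dataclass(frozen=True)
class Encounter:
    """A dated visit with a care-setting class."""

    encounter_id: str
    person_id: str
    start_date: dt.date
    end_date: dt.date
    setting: CareSetting

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError(
                f"Encounter {self.encounter_id}: end_date precedes start_date"
            )


def _event_sort_key(e: ClinicalEvent) -> tuple:
    return (e.event_date, e.event_class.value, e.code)


@dataclass
class EventTimeline:
    """All events and encounters of one person, date-ordered.

    Events are sorted ascending by date with ties broken by
    (event_class, code) lexicographically, so the ordering is total and
    deterministic for any permutation of the input rows.
    """

    person: Person
    events: list[ClinicalEvent] = field(default_factory=list)
    encounters: list[Encounter] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.events:
            if e.person_id != self.person.person_id:
                raise ValueError(
                    f"event person_id {e.person_id!r} does not match "
                    f"timeline person {self.person.person_id!r}"
                )
        self.events = sorted(self.events, key=_event_sort_key)
        self.encounters = sorted(
            self.encounters, key=lambda v: (v.start_date, v.end_date, v.encounter_id)
        )

    @property
    def encounter_by_id(self) -> dict[str, Encounter]:
        return {v.encounter_id: v for v in self.encounters}


def days_between(a: dt.date, b: dt.date) -> int:
    """Signed whole days from ``a`` to ``b`` (``b - a``); antisymmetric."""
    return (b - a).days


# ---------------------------------------------------------------------------
# CSV dataset I/O
# ---------------------------------------------------------------------------

#: default column names, remappable via SchemaConfig.columns
_DEFAULT_COLUMNS: dict[str, dict[str, str]] = {
    "persons": {
        "person_id": "person_id",
        "birth_date": "birth_date",
        "sex_at_birth": "sex_at_birth",
        "bmi": "bmi",
        "charlson_index": "charlson_index",
        "deprivation_index": "deprivation_index",
    },
    "condition_occurrence": {
        "person_id": "person_id",
        "event_date": "condition_date",
        "code": "code",
        "vocabulary": "vocabulary",
        "encounter_id": "visit_id",
    },
    "procedure_occurrence": {
        "person_id": "person_id",
        "event_date": "procedure_date",
        "code": "code",
        "vocabulary": "vocabulary",
        "event_class": "event_class",
        "encounter_id": "visit_id",
    },
    "visit_occurrence": {
        "encounter_id": "visit_id",
        "person_id": "person_id",
        "start_date": "start_date",
        "end_date": "end_date",
        "setting": "setting",
    },
    "survey_dates": {
        "person_id": "person_id",
        "instrument": "survey",
        "date": "survey_date",
    },
}

_REQUIRED: dict[str, tuple[str, ...]] = {
    "persons": ("person_id",),
    "condition_occurrence": ("person_id", "event_date", "code", "vocabulary"),
    "procedure_occurrence": ("person_id", "event_date", "code", "vocabulary"),
    "visit_occurrence": ("encounter_id", "person_id", "start_date", "end_date", "setting"),
    "survey_dates": ("person_id", "instrument", "date"),
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass
class SchemaConfig:
    """Column remapping and visit-setting collapse rules.

    ``columns`` maps table role -> {logical field -> actual CSV column}.
    ``setting_map`` maps raw visit-setting strings (case-insensitive) to
    ``inpatient`` / ``outpatient`` / ``emergency``; unmapped values fall
    back to outpatient with a warning, which can never promote a person
    into the inpatient-admission-driven severe class.
    """

    columns: dict[str, dict[str, str]] = field(default_factory=dict)
    setting_map: dict[str, str] = field(default_factory=dict)

    def column(self, table: str, logical: str) -> str:
        return self.columns.get(table, {}).get(
            logical, _DEFAULT_COLUMNS[table].get(logical, logical)
        )

    def resolve_setting(self, raw: object) -> CareSetting:
        text = str(raw).strip().lower()
        mapped = self.setting_map.get(text, text)
        try:
            return CareSetting(mapped)
        except ValueError:
            logger.warning("unknown visit setting %r treated as outpatient", raw)
            return CareSetting.outpatient


@dataclass
class ReadResult:
    """Timelines plus the rejects report (never silently dropped rows)."""

    timelines: dict[str, EventTimeline]
    rejects: pd.DataFrame  # columns: table, row, reason
    warnings: list[str] = field(default_factory=list)

    @property
    def n_dangling_links(self) -> int:
        return sum("dangling encounter" in w for w in self.warnings)


def _parse_date(value: object) -> dt.date:
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    ts = pd.Timestamp(str(value))
    if pd.isna(ts):
        raise ValueError("unparseable date")
    return ts.date()


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])


def _require(df: pd.DataFrame, table: str, schema: SchemaConfig, fields: Iterable[str]) -> None:
    for logical in fields:
        col = schema.column(table, logical)
        if col not in df.columns:
            raise SchemaError(f"table {table!r}: required column {col!r} missing")


def read_dataset(
    paths: Mapping[str, str | Path],
    schema_config: SchemaConfig | None = None,
) -> ReadResult:
    """Read persons / condition / procedure / visit CSVs into timelines.

    ``paths`` maps table roles (``persons``, ``condition_occurrence``,
    ``procedure_occurrence``, ``visit_occurrence``, optionally
    ``survey_dates``) to CSV paths; only ``persons`` is mandatory.
    Malformed rows land in the rejects report with the original row
    number and a reason; an event pointing at an unknown encounter is
    accepted with its link nulled and a warning recorded.
    """
    schema = schema_config or SchemaConfig()
    rejects: list[dict] = []
    warnings: list[str] = []

    persons_path = paths.get("persons")
    if persons_path is None:
        raise SchemaError("a 'persons' table is required")
    pdf = _read_csv(persons_path)
    _require(pdf, "persons", schema, _REQUIRED["persons"])
    col = lambda t, f: schema.column(t, f)  # noqa: E731

    persons: dict[str, Person] = {}
    for i, row in pdf.iterrows():
        try:
            pid = str(row[col("persons", "person_id")])
            birth_raw = row.get(col("persons", "birth_date"))
            sex_raw = row.get(col("persons", "sex_at_birth"))
            bmi_raw = row.get(col("persons", "bmi"))
            cci_raw = row.get(col("persons", "charlson_index"))
            adi_raw = row.get(col("persons", "deprivation_index"))
            persons[pid] = Person(
                person_id=pid,
                birth_date=None if pd.isna(birth_raw) or birth_raw is None else _parse_date(birth_raw),
                sex_at_birth=Sex(str(sex_raw)) if isinstance(sex_raw, str) and sex_raw else Sex.unknown,
                bmi=None if bmi_raw is None or pd.isna(bmi_raw) else float(bmi_raw),
                charlson_index=None if cci_raw is None or pd.isna(cci_raw) else int(float(cci_raw)),
                deprivation_index=None if adi_raw is None or pd.isna(adi_raw) else float(adi_raw),
            )
        except (ValueError, KeyError) as exc:
            rejects.append({"table": "persons", "row": i, "reason": str(exc)})

    encounters: dict[str, list[Encounter]] = {pid: [] for pid in persons}
    known_encounters: dict[str, str] = {}  # encounter_id -> person_id
    visits_path = paths.get("visit_occurrence")
    if visits_path is not None:
        vdf = _read_csv(visits_path)
        _require(vdf, "visit_occurrence", schema, _REQUIRED["visit_occurrence"])
        for i, row in vdf.iterrows():
            try:
                pid = str(row[col("visit_occurrence", "person_id")])
                if pid not in persons:
                    raise ValueError(f"unknown person_id {pid!r}")
                enc = Encounter(
                    encounter_id=str(row[col("visit_occurrence", "encounter_id")]),
                    person_id=pid,
                    start_date=_parse_date(row[col("visit_occurrence", "start_date")]),
                    end_date=_parse_date(row[col("visit_occurrence", "end_date")]),
                    setting=schema.resolve_setting(row[col("visit_occurrence", "setting")]),
                )
                encounters[pid].append(enc)
                known_encounters[enc.encounter_id] = pid
            except ValueError as exc:
                rejects.append({"table": "visit_occurrence", "row": i, "reason": str(exc)})

    events: dict[str, list[ClinicalEvent]] = {pid: [] for pid in persons}

    def _load_events(table: str, default_class: EventClass) -> None:
        path = paths.get(table)
        if path is None:
            return
        df = _read_csv(path)
        _require(df, table, schema, _REQUIRED[table])
        class_col = schema.column(table, "event_class")
        enc_col = schema.column(table, "encounter_id")
        for i, row in df.iterrows():
            try:
                pid = str(row[col(table, "person_id")])
                if pid not in persons:
                    raise ValueError(f"unknown person_id {pid!r}")
                eclass = default_class
                if class_col in df.columns and isinstance(row[class_col], str) and row[class_col]:
                    eclass = EventClass(row[class_col])
                enc_id: str | None = None
                if enc_col in df.columns:
                    raw = row[enc_col]
                    if isinstance(raw, str) and raw:
                        enc_id = raw
                if enc_id is not None and known_encounters.get(enc_id) != pid:
                    warnings.append(
                        f"{table} row {i}: dangling encounter link {enc_id!r} nulled"
                    )
                    logger.warning("%s row %d: dangling encounter link %r", table, i, enc_id)
                    enc_id = None
                events[pid].append(
                    ClinicalEvent(
                        person_id=pid,
                        event_date=_parse_date(row[col(table, "event_date")]),
                        code=str(row[col(table, "code")]),
                        vocabulary=Vocabulary(str(row[col(table, "vocabulary")])),
                        event_class=eclass,
                        encounter_id=enc_id,
                    )
                )
            except ValueError as exc:
                rejects.append({"table": table, "row": i, "reason": str(exc)})

    _load_events("condition_occurrence", EventClass.diagnosis)
    _load_events("procedure_occurrence", EventClass.procedure)

    surveys_path = paths.get("survey_dates")
    if surveys_path is not None:
        sdf = _read_csv(surveys_path)
        _require(sdf, "survey_dates", schema, _REQUIRED["survey_dates"])
        for i, row in sdf.iterrows():
            try:
                pid = str(row[col("survey_dates", "person_id")])
                if pid not in persons:
                    raise ValueError(f"unknown person_id {pid!r}")
                persons[pid].survey_dates[str(row[col("survey_dates", "instrument")])] = _parse_date(
                    row[col("survey_dates", "date")]
                )
            except ValueError as exc:
                rejects.append({"table": "survey_dates", "row": i, "reason": str(exc)})

    timelines = {
        pid: EventTimeline(person=persons[pid], events=events[pid], encounters=encounters[pid])
        for pid in persons
    }
    rejects_df = pd.DataFrame(rejects, columns=["table", "row", "reason"])
    return ReadResult(timelines=timelines, rejects=rejects_df, warnings=warnings)


def write_dataset(timelines: Mapping[str, EventTimeline], out_dir: str | Path) -> dict[str, Path]:
    """Write timelines back to the CSV table layout read_dataset accepts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    persons_rows, cond_rows, proc_rows, visit_rows, survey_rows = [], [], [], [], []
    for pid in sorted(timelines):
        tl = timelines[pid]
        p = tl.person
        persons_rows.append(
            {
                "person_id": p.person_id,
                "birth_date": p.birth_date.isoformat() if p.birth_date else "",
                "sex_at_birth": p.sex_at_birth.value,
                "bmi": "" if p.bmi is None else p.bmi,
                "charlson_index": "" if p.charlson_index is None else p.charlson_index,
                "deprivation_index": "" if p.deprivation_index is None else p.deprivation_index,
            }
        )
        for name, date in sorted(p.survey_dates.items()):
            survey_rows.append({"person_id": pid, "survey": name, "survey_date": date.isoformat()})
        for enc in tl.encounters:
            visit_rows.append(
                {
                    "visit_id": enc.encounter_id,
                    "person_id": pid,
                    "start_date": enc.start_date.isoformat(),
                    "end_date": enc.end_date.isoformat(),
                    "setting": enc.setting.value,
                }
            )
        for e in tl.events:
            row = {
                "person_id": pid,
                "code": e.code,
                "vocabulary": e.vocabulary.value,
                "visit_id": e.encounter_id or "",
            }
            if e.event_class is EventClass.diagnosis:
                cond_rows.append({**row, "condition_date": e.event_date.isoformat()})
            else:
                proc_rows.append(
                    {
                        **row,
                        "procedure_date": e.event_date.isoformat(),
                        "event_class": e.event_class.value,
                    }
                )
    paths = {}
    for name, rows, cols in [
        ("persons", persons_rows, list(_DEFAULT_COLUMNS["persons"].values())),
        ("condition_occurrence", cond_rows, ["person_id", "condition_date", "code", "vocabulary", "visit_id"]),
        ("procedure_occurrence", proc_rows, ["person_id", "procedure_date", "code", "vocabulary", "event_class", "visit_id"]),
        ("visit_occurrence", visit_rows, ["visit_id", "person_id", "start_date", "end_date", "setting"]),
        ("survey_dates", survey_rows, ["person_id", "survey", "survey_date"]),
    ]:
        path = out / f"{name}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        paths[name] = path
    return paths
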