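"""Rule-based severity phenotyping of diverticular disease.

A person becomes a *case* only with imaging or endoscopic confirmation:
a diverticular diagnosis code dated within 7 days **after** (inclusive,
offsets 0..7) an abdominal CT scan or lower-GI endoscopic procedure —
the *index pair*. Confirmed cases are then split into three mutually
exclusive severity classes:

* ``diverticulosis`` — only diverticulosis codes, never a diverticulitis
  code anywhere in the record;
* ``mild_diverticulitis`` — diverticulitis with only outpatient care or
  at most one inpatient admission;
* ``operative_or_recurrent`` — more than one inpatient admission for
  diverticulitis, or a procedure (colectomy, percutaneous drain,
  intestinal fistula repair) performed for diverticulitis.

Persons with no diverticular code at all are ``control``; persons with
codes but no confirming index pair are ``excluded`` rather than being
relabelled controls, so that code-only false positives cannot poison
downstream negative-predictive evaluations.

Inpatient admissions are counted as *distinct* inpatient encounters
carrying a linked diverticulitis code, after merging overlapping or
date-adjacent stays (a transfer between units must not fabricate a
recurrence). A procedure counts as "performed for diverticulitis" when a
diverticulitis code shares its encounter or falls within a configurable
±30-day window of the procedure date.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .codesets import CodeSetRegistry, match
from .ehr_core import CareSetting, ClinicalEvent, EventTimeline, Person, days_between

logger = logging.getLogger(__name__)

__all__ = [
    "Phenotype",
    "PhenotypeAssignment",
    "find_index_pair",
    "count_inpatient_diverticulitis_admissions",
    "find_qualifying_procedure",
    "assign_phenotype",
    "assign_cohort",
    "apply_inclusion_window",
    "assignments_to_frame",
    "CONFIRM_WINDOW_DAYS",
    "DEFAULT_LINK_WINDOW_DAYS",
]

#: diagnosis must fall 0..CONFIRM_WINDOW_DAYS days after the confirming study
CONFIRM_WINDOW_DAYS = 7
#: default ± window linking a procedure to its diverticulitis indication
DEFAULT_LINK_WINDOW_DAYS = 30


class Phenotype(str, Enum):
    control = "control"
    diverticulosis = "diverticulosis"
    mild_diverticulitis = "mild_diverticulitis"
    operative_or_recurrent = "operative_or_recurrent"
    excluded = "excluded"


@dataclass
class PhenotypeAssignment:
    person_id: str
    phenotype: Phenotype
    index_pair: tuple[ClinicalEvent, ClinicalEvent, int] | None = None
    inpatient_dx_admission_count: int = 0
    qualifying_procedure: tuple[ClinicalEvent, ClinicalEvent] | None = None
    assignment_date: dt.date | None = None
    unlinked_diverticulitis_codes: int = 0


def find_index_pair(
    timeline: EventTimeline, registry: CodeSetRegistry
) -> tuple[ClinicalEvent, ClinicalEvent, int] | None:
    """Earliest confirming (CT/endoscopy, diverticular dx) pair.

    The diagnosis must fall 0..7 days *after* the confirming event.
    Selection is by earliest diagnosis date, then earliest confirming
    event; remaining ties fall back to the timeline's total event order.
    """
    ct = registry["abdominal_ct"]
    endo = registry["lower_gi_endoscopy"]
    any_dx = registry["diverticular_any_dx"]
    confirms = [e for e in timeline.events if match(ct, e) or match(endo, e)]
    if not confirms:
        return None
    best: tuple[ClinicalEvent, ClinicalEvent, int] | None = None
    for dx in timeline.events:
        if not match(any_dx, dx):
            continue
        for confirm in confirms:
            offset = days_between(confirm.event_date, dx.event_date)
            if 0 <= offset <= CONFIRM_WINDOW_DAYS:
                if best is None or (dx.event_date, confirm.event_date) < (
                    best[1].event_date,
                    best[0].event_date,
                ):
                    best = (confirm, dx, offset)
        if best is not None and dx.event_date > best[1].event_date:
            break
    return best


def _merge_intervals(
    intervals: Iterable[tuple[dt.date, dt.date]]
) -> list[tuple[dt.date, dt.date]]:
    """Merge overlapping or date-adjacent (gap 0) [start, end] intervals."""
    merged: list[tuple[dt.date, dt.date]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def count_inpatient_diverticulitis_admissions(
    timeline: EventTimeline, registry: CodeSetRegistry
) -> tuple[int, int]:
    """Distinct inpatient admissions carrying a linked diverticulitis code.

    Returns ``(admission_count, unlinked_code_count)``. Encounters whose
    date ranges overlap or touch are merged into a single admission
    first. Diverticulitis codes with no encounter link count toward no
    admission but are tallied for the diagnostics report.
    """
    itis = registry["diverticulitis_dx"]
    enc_by_id = timeline.encounter_by_id
    coded: list[tuple[dt.date, dt.date]] = []
    unlinked = 0
    seen_enc: set[str] = set()
    for e in timeline.events:
        if not match(itis, e):
            continue
        if e.encounter_id is None:
            unlinked += 1
            continue
        enc = enc_by_id.get(e.encounter_id)
        if enc is None:
            unlinked += 1
            continue
        if enc.setting is CareSetting.inpatient and enc.encounter_id not in seen_enc:
            seen_enc.add(enc.encounter_id)
            coded.append((enc.start_date, enc.end_date))
    return len(_merge_intervals(coded)), unlinked


def find_qualifying_procedure(
    timeline: EventTimeline,
    registry: CodeSetRegistry,
    link_window_days: int = DEFAULT_LINK_WINDOW_DAYS,
) -> tuple[ClinicalEvent, ClinicalEvent] | None:
    """Earliest colectomy/drain/fistula-repair performed for diverticulitis.

    A procedure qualifies when a diverticulitis diagnosis shares its
    encounter or lies within ``±link_window_days`` of the procedure
    date; the nearest such diagnosis is reported as the indication.
    """
    proc_sets = [registry["colectomy"], registry["percutaneous_drain"], registry["fistula_repair"]]
    itis = registry["diverticulitis_dx"]
    dx_events = [e for e in timeline.events if match(itis, e)]
    if not dx_events:
        return None
    for proc in timeline.events:
        if not any(match(s, proc) for s in proc_sets):
            continue
        linked: ClinicalEvent | None = None
        best_dist: int | None = None
        for dx in dx_events:
            same_encounter = (
                proc.encounter_id is not None and proc.encounter_id == dx.encounter_id
            )
            dist = abs(days_between(proc.event_date, dx.event_date))
            if same_encounter or dist <= link_window_days:
                if best_dist is None or dist < best_dist:
                    linked, best_dist = dx, dist
        if linked is not None:
            return proc, linked
    return None


def assign_phenotype(
    timeline: EventTimeline,
    registry: CodeSetRegistry,
    link_window_days: int = DEFAULT_LINK_WINDOW_DAYS,
) -> PhenotypeAssignment:
    """Assign exactly one severity class to a person.

    Decision order: no diverticular code at all -> control; no index
    pair -> excluded; no diverticulitis code anywhere -> diverticulosis;
    qualifying procedure or >1 inpatient admission -> operative or
    recurrent; otherwise mild diverticulitis.
    """
    any_dx = registry["diverticular_any_dx"]
    dx_events = [e for e in timeline.events if match(any_dx, e)]
    pid = timeline.person.person_id
    if not dx_events:
        return PhenotypeAssignment(person_id=pid, phenotype=Phenotype.control)

    first_dx_date = dx_events[0].event_date
    pair = find_index_pair(timeline, registry)
    admissions, unlinked = count_inpatient_diverticulitis_admissions(timeline, registry)
    if pair is None:
        return PhenotypeAssignment(
            person_id=pid,
            phenotype=Phenotype.excluded,
            inpatient_dx_admission_count=admissions,
            assignment_date=first_dx_date,
            unlinked_diverticulitis_codes=unlinked,
        )

    itis = registry["diverticulitis_dx"]
    has_itis = any(match(itis, e) for e in timeline.events)
    common = dict(
        person_id=pid,
        index_pair=pair,
        inpatient_dx_admission_count=admissions,
        assignment_date=pair[1].event_date,
        unlinked_diverticulitis_codes=unlinked,
    )
    if not has_itis:
        return PhenotypeAssignment(phenotype=Phenotype.diverticulosis, **common)

    procedure = find_qualifying_procedure(timeline, registry, link_window_days)
    if procedure is not None or admissions > 1:
        return PhenotypeAssignment(
            phenotype=Phenotype.operative_or_recurrent,
            qualifying_procedure=procedure,
            **common,
        )
    return PhenotypeAssignment(phenotype=Phenotype.mild_diverticulitis, **common)


def assign_cohort(
    timelines: Mapping[str, EventTimeline],
    registry: CodeSetRegistry,
    link_window_days: int = DEFAULT_LINK_WINDOW_DAYS,
) -> dict[str, PhenotypeAssignment]:
    return {
        pid: assign_phenotype(tl, registry, link_window_days)
        for pid, tl in timelines.items()
    }


@dataclass
class InclusionResult:
    kept: dict[str, PhenotypeAssignment]
    n_dropped_outside_window: int = 0
    n_dropped_no_survey: int = 0
    dropped_person_ids: list[str] = field(default_factory=list)


def apply_inclusion_window(
    assignments: Mapping[str, PhenotypeAssignment],
    persons: Mapping[str, Person],
    window_years: float = 5.0,
    inclusion_survey: str = "earliest",
) -> InclusionResult:
    """Restrict cases to those diagnosed near survey completion.

    A case is kept when its assignment date lies within
    ``window_years`` (365.25 days/year) of the chosen survey's
    completion date, in either direction. ``inclusion_survey`` selects
    which completion date anchors the window: ``"earliest"`` takes the
    minimum over all recorded surveys, any other value names a specific
    instrument. Persons lacking that date are dropped and counted.
    Controls (no assignment date) are kept whenever the survey date
    exists.
    """
    window_days = 365.25 * window_years
    kept: dict[str, PhenotypeAssignment] = {}
    no_survey = 0
    outside = 0
    dropped: list[str] = []
    for pid, a in assignments.items():
        person = persons[pid]
        if inclusion_survey == "earliest":
            date = min(person.survey_dates.values()) if person.survey_dates else None
        else:
            date = person.survey_dates.get(inclusion_survey)
        if date is None:
            no_survey += 1
            dropped.append(pid)
            continue
        if a.assignment_date is None:
            kept[pid] = a
            continue
        if abs(days_between(date, a.assignment_date)) <= window_days:
            kept[pid] = a
        else:
            outside += 1
            dropped.append(pid)
    if no_survey:
        logger.info("inclusion window: %d persons lacked survey %r", no_survey, inclusion_survey)
    return InclusionResult(
        kept=kept,
        n_dropped_outside_window=outside,
        n_dropped_no_survey=no_survey,
        dropped_person_ids=dropped,
    )


def assignments_to_frame(assignments: Mapping[str, PhenotypeAssignment]) -> pd.DataFrame:
    """One row per person, suitable for phenotypes.csv."""
    rows = []
    for pid in sorted(assignments):
        a = assignments[pid]
        rows.append(
            {
                "person_id": pid,
                "phenotype": a.phenotype.value,
                "assignment_date": a.assignment_date.isoformat() if a.assignment_date else "",
                "index_confirm_code": a.index_pair[0].code if a.index_pair else "",
                "index_confirm_date": a.index_pair[0].event_date.isoformat() if a.index_pair else "",
                "index_dx_code": a.index_pair[1].code if a.index_pair else "",
                "index_dx_date": a.index_pair[1].event_date.isoformat() if a.index_pair else "",
                "index_day_offset": a.index_pair[2] if a.index_pair else "",
                "inpatient_dx_admission_count": a.inpatient_dx_admission_count,
                "qualifying_procedure_code": a.qualifying_procedure[0].code if a.qualifying_procedure else "",
                "qualifying_procedure_date": a.qualifying_procedure[0].event_date.isoformat() if a.qualifying_procedure else "",
                "unlinked_diverticulitis_codes": a.unlinked_diverticulitis_codes,
            }
        )
    return pd.DataFrame(rows)
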