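import datetime as dt

import pytest

from divertiphen.codesets import default_registry
from divertiphen.ehr_core import (
    CareSetting,
    ClinicalEvent,
    Encounter,
    EventClass,
    EventTimeline,
    Person,
    Vocabulary,
)

D0 = dt.date(2020, 1, 1)


def day(offset: int) -> dt.date:
    return D0 + dt.timedelta(days=offset)


def dx(pid, offset, code, vocab=Vocabulary.ICD10CM, enc=None):
    return ClinicalEvent(pid, day(offset), code, vocab, EventClass.diagnosis, enc)


def proc(pid, offset, code, enc=None, event_class=EventClass.procedure):
    return ClinicalEvent(pid, day(offset), code, Vocabulary.CPT, event_class, enc)


def ct(pid, offset, enc=None):
    return proc(pid, offset, "74176", enc, EventClass.imaging)


def endoscopy(pid, offset, enc=None):
    return proc(pid, offset, "45378", enc)


def inpatient(pid, enc_id, start, end):
    return Encounter(enc_id, pid, day(start), day(end), CareSetting.inpatient)


def outpatient(pid, enc_id, offset):
    return Encounter(enc_id, pid, day(offset), day(offset), CareSetting.outpatient)


def timeline(pid="p1", events=(), encounters=()):
    return EventTimeline(
        person=Person(person_id=pid), events=list(events), encounters=list(encounters)
    )


@pytest.fixture(scope="session")
def registry():
    return default_registry()
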