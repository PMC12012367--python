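import datetime as dt
import itertools

import numpy as np
import pytest

from divertiphen.ehr_core import Person
from divertiphen.phenotyper import (
    Phenotype,
    apply_inclusion_window,
    assign_phenotype,
    count_inpatient_diverticulitis_admissions,
    find_index_pair,
    find_qualifying_procedure,
)

from conftest import ct, day, dx, endoscopy, inpatient, outpatient, proc, timeline


class TestIndexPair:
    def test_ct_then_dx_within_window(self, registry):
        tl = timeline(events=[ct("p1", 0), dx("p1", 3, "K57.30")])
        confirm, dxe, offset = find_index_pair(tl, registry)
        assert offset == 3 and dxe.code == "K57.30"

    def test_dx_outside_window_is_no_pair(self, registry):
        tl = timeline(events=[ct("p1", 0), dx("p1", 8, "K57.30")])
        assert find_index_pair(tl, registry) is None

    def test_dx_before_confirmation_does_not_qualify(self, registry):
        tl = timeline(events=[dx("p1", 0, "K57.30"), ct("p1", 2)])
        assert find_index_pair(tl, registry) is None

    def test_same_day_offset_zero_qualifies(self, registry):
        tl = timeline(events=[ct("p1", 0), dx("p1", 0, "K57.32")])
        assert find_index_pair(tl, registry)[2] == 0

    def test_earliest_dx_selection_matches_brute_force(self, registry):
        # CT day 0 with dx day 7, endoscopy day 10 with dx day 10
        events = [ct("p1", 0), dx("p1", 7, "K57.30"), endoscopy("p1", 10), dx("p1", 10, "K57.32")]
        tl = timeline(events=events)
        confirm, dxe, offset = find_index_pair(tl, registry)
        # oracle: enumerate all confirm x dx pairs, keep valid ones,
        # minimize (dx date, confirm date)
        confirms = [e for e in tl.events if e.code in ("74176", "45378")]
        dxs = [e for e in tl.events if e.code.startswith("K57")]
        valid = [
            (c, d)
            for c, d in itertools.product(confirms, dxs)
            if 0 <= (d.event_date - c.event_date).days <= 7
        ]
        expected = min(valid, key=lambda p: (p[1].event_date, p[0].event_date))
        assert (confirm, dxe) == expected
        assert dxe.event_date == day(7) and confirm.code == "74176"


class TestAdmissionCounting:
    def test_two_disjoint_coded_stays_count_two(self, registry):
        encs = [inpatient("p1", "a", 0, 4), inpatient("p1", "b", 100, 103)]
        events = [dx("p1", 0, "K57.32", enc="a"), dx("p1", 100, "K57.32", enc="b")]
        n, unlinked = count_inpatient_diverticulitis_admissions(
            timeline(events=events, encounters=encs), registry
        )
        assert (n, unlinked) == (2, 0)

    def test_many_codes_one_stay_count_one(self, registry):
        encs = [inpatient("p1", "a", 0, 6)]
        events = [dx("p1", k, "K57.32", enc="a") for k in range(5)]
        n, _ = count_inpatient_diverticulitis_admissions(
            timeline(events=events, encounters=encs), registry
        )
        assert n == 1

    def test_overlapping_stays_merge_to_one(self, registry):
        # stay A days 1-5 and stay B days 5-9 share a day: one admission
        encs = [inpatient("p1", "a", 1, 5), inpatient("p1", "b", 5, 9)]
        events = [dx("p1", 1, "K57.32", enc="a"), dx("p1", 5, "K57.92", enc="b")]
        n, _ = count_inpatient_diverticulitis_admissions(
            timeline(events=events, encounters=encs), registry
        )
        assert n == 1

    def test_merge_agrees_with_interval_oracle(self, registry):
        # oracle: day-set union connected components over constructed stays
        rng = np.random.default_rng(5)
        for _ in range(50):
            k = int(rng.integers(1, 6))
            stays = []
            for i in range(k):
                start = int(rng.integers(0, 60))
                stays.append((start, start + int(rng.integers(0, 8))))
            encs = [inpatient("p1", f"e{i}", s, e) for i, (s, e) in enumerate(stays)]
            events = [dx("p1", s, "K57.32", enc=f"e{i}") for i, (s, _) in enumerate(stays)]
            n, _ = count_inpatient_diverticulitis_admissions(
                timeline(events=events, encounters=encs), registry
            )
            # half-day grid: stays sharing a calendar day connect; stays on
            # merely consecutive days do not
            covered = sorted(set(u for s, e in stays for u in range(2 * s, 2 * e + 1)))
            components = 1 + sum(
                1 for a, b in zip(covered, covered[1:]) if b - a > 1
            )
            assert n == components

    def test_unlinked_codes_count_toward_no_admission(self, registry):
        events = [dx("p1", 0, "K57.32"), dx("p1", 50, "K57.32")]
        n, unlinked = count_inpatient_diverticulitis_admissions(timeline(events=events), registry)
        assert (n, unlinked) == (0, 2)

    def test_emergency_visits_never_count(self, registry):
        from divertiphen.ehr_core import CareSetting, Encounter

        encs = [Encounter("e1", "p1", day(0), day(0), CareSetting.emergency)]
        events = [dx("p1", 0, "K57.32", enc="e1")]
        n, _ = count_inpatient_diverticulitis_admissions(
            timeline(events=events, encounters=encs), registry
        )
        assert n == 0


class TestQualifyingProcedure:
    def test_same_encounter_qualifies(self, registry):
        encs = [inpatient("p1", "a", 0, 5)]
        events = [dx("p1", 0, "K57.32", enc="a"), proc("p1", 2, "44140", enc="a")]
        got = find_qualifying_procedure(timeline(events=events, encounters=encs), registry)
        assert got is not None and got[0].code == "44140"

    def test_dx_45_days_away_does_not_qualify(self, registry):
        events = [proc("p1", 0, "44140"), dx("p1", 45, "K57.32")]
        assert find_qualifying_procedure(timeline(events=events), registry) is None

    def test_acceptance_region_is_plus_minus_window(self, registry):
        # exhaustive sweep: dx offset -40..40 around a drain at day 100
        for offset in range(-40, 41):
            events = [proc("p1", 100, "49406"), dx("p1", 100 + offset, "K57.32")]
            got = find_qualifying_procedure(timeline(events=events), registry, link_window_days=30)
            assert (got is not None) == (abs(offset) <= 30)

    def test_diverticulosis_indication_never_qualifies(self, registry):
        events = [proc("p1", 0, "44140"), dx("p1", 1, "K57.30")]
        assert find_qualifying_procedure(timeline(events=events), registry) is None


def _confirmed(pid, dx_code, dx_day=3):
    return [ct(pid, 0), dx(pid, dx_day, dx_code)]


class TestAssignPhenotype:
    def test_no_diverticular_codes_is_control(self, registry):
        tl = timeline(events=[dx("p1", 0, "I10"), ct("p1", 5)])
        assert assign_phenotype(tl, registry).phenotype is Phenotype.control

    def test_confirmed_diverticulosis_only(self, registry):
        tl = timeline(events=_confirmed("p1", "K57.30"))
        a = assign_phenotype(tl, registry)
        assert a.phenotype is Phenotype.diverticulosis
        assert a.index_pair[2] == 3

    def test_confirmed_diverticulitis_outpatient_only_is_mild(self, registry):
        encs = [outpatient("p1", "o1", 3)]
        tl = timeline(events=[ct("p1", 0), dx("p1", 3, "K57.32", enc="o1")], encounters=encs)
        assert assign_phenotype(tl, registry).phenotype is Phenotype.mild_diverticulitis

    def test_single_inpatient_admission_stays_mild(self, registry):
        encs = [inpatient("p1", "a", 3, 7)]
        tl = timeline(events=[ct("p1", 0), dx("p1", 3, "K57.32", enc="a")], encounters=encs)
        assert assign_phenotype(tl, registry).phenotype is Phenotype.mild_diverticulitis

    def test_two_merged_distinct_admissions_is_operative_or_recurrent(self, registry):
        encs = [inpatient("p1", "a", 3, 7), inpatient("p1", "b", 60, 64)]
        tl = timeline(
            events=[ct("p1", 0), dx("p1", 3, "K57.32", enc="a"), dx("p1", 60, "K57.32", enc="b")],
            encounters=encs,
        )
        a = assign_phenotype(tl, registry)
        assert a.phenotype is Phenotype.operative_or_recurrent
        assert a.inpatient_dx_admission_count == 2

    def test_linked_procedure_is_operative_or_recurrent(self, registry):
        tl = timeline(events=_confirmed("p1", "K57.32") + [proc("p1", 10, "44140")])
        a = assign_phenotype(tl, registry)
        assert a.phenotype is Phenotype.operative_or_recurrent
        assert a.qualifying_procedure[0].code == "44140"

    def test_unconfirmed_codes_are_excluded_not_control(self, registry):
        tl = timeline(events=[dx("p1", 0, "K57.32"), ct("p1", 30)])
        assert assign_phenotype(tl, registry).phenotype is Phenotype.excluded

    def test_any_diverticulitis_code_removes_diverticulosis_class(self, registry):
        # index dx is a diverticulosis code, but a lone later diverticulitis
        # code anywhere makes the person at least mild
        tl = timeline(events=_confirmed("p1", "K57.30") + [dx("p1", 400, "K57.32")])
        assert assign_phenotype(tl, registry).phenotype is Phenotype.mild_diverticulitis

    def test_each_branch_hit_exactly_once_on_fixture_suite(self, registry):
        fixtures = {
            Phenotype.control: timeline(events=[dx("p1", 0, "I10")]),
            Phenotype.excluded: timeline(events=[dx("p1", 0, "K57.92")]),
            Phenotype.diverticulosis: timeline(events=_confirmed("p1", "K57.30")),
            Phenotype.mild_diverticulitis: timeline(events=_confirmed("p1", "K57.32")),
            Phenotype.operative_or_recurrent: timeline(
                events=_confirmed("p1", "K57.32") + [proc("p1", 5, "49406")]
            ),
        }
        for expected, tl in fixtures.items():
            assert assign_phenotype(tl, registry).phenotype is expected

    def test_assignment_invariant_under_event_permutation(self, registry):
        events = _confirmed("p1", "K57.32") + [proc("p1", 5, "49406"), dx("p1", -30, "K57.30")]
        baseline = assign_phenotype(timeline(events=events), registry)
        rng = np.random.default_rng(3)
        for _ in range(10):
            shuffled = list(events)
            rng.shuffle(shuffled)
            again = assign_phenotype(timeline(events=shuffled), registry)
            assert again.phenotype is baseline.phenotype
            assert again.index_pair == baseline.index_pair

    def test_adding_disjoint_admission_never_decreases_severity(self, registry):
        severity = {
            Phenotype.control: 0,
            Phenotype.excluded: 0,
            Phenotype.diverticulosis: 1,
            Phenotype.mild_diverticulitis: 2,
            Phenotype.operative_or_recurrent: 3,
        }
        bases = [
            timeline(events=[dx("p1", 0, "I10")]),
            timeline(events=[dx("p1", 0, "K57.92")]),
            timeline(events=_confirmed("p1", "K57.30")),
            timeline(events=_confirmed("p1", "K57.32")),
            timeline(
                events=_confirmed("p1", "K57.32") + [dx("p1", 60, "K57.32", enc="a")],
                encounters=[inpatient("p1", "a", 60, 63)],
            ),
        ]
        for base in bases:
            before = assign_phenotype(base, registry)
            extra_enc = inpatient("p1", "zz", 300, 304)
            extra_dx = dx("p1", 300, "K57.33", enc="zz")
            after = assign_phenotype(
                timeline(events=base.events + [extra_dx], encounters=base.encounters + [extra_enc]),
                registry,
            )
            assert severity[after.phenotype] >= severity[before.phenotype]

    def test_deleting_confirmation_demotes_to_control_or_excluded(self, registry):
        cases = [
            timeline(events=_confirmed("p1", "K57.30")),
            timeline(events=_confirmed("p1", "K57.32") + [proc("p1", 5, "49406")]),
        ]
        for tl in cases:
            stripped = timeline(
                events=[e for e in tl.events if e.code not in ("74176", "45378")],
                encounters=tl.encounters,
            )
            got = assign_phenotype(stripped, registry).phenotype
            assert got in (Phenotype.control, Phenotype.excluded)


class TestInclusionWindow:
    def _setup(self, lag_days, registry):
        persons = {}
        assignments = {}
        for i, lag in enumerate(lag_days):
            pid = f"p{i}"
            persons[pid] = Person(person_id=pid, survey_dates={"earliest": day(0)})
            assignments[pid] = assign_phenotype(
                timeline(pid=pid, events=[ct(pid, lag), dx(pid, lag, "K57.30")]), registry
            )
        return assignments, persons

    def test_boundaries_in_days(self, registry):
        lag_49 = int(4.9 * 365.25)
        lag_26 = int(2.6 * 365.25) + 1
        assignments, persons = self._setup([lag_49, lag_26], registry)
        kept5 = apply_inclusion_window(assignments, persons, window_years=5.0).kept
        assert "p0" in kept5 and "p1" in kept5
        kept25 = apply_inclusion_window(assignments, persons, window_years=2.5).kept
        assert "p1" not in kept25

    def test_missing_survey_dropped_and_counted(self, registry):
        assignments, persons = self._setup([0, 10], registry)
        persons["p1"].survey_dates.clear()
        res = apply_inclusion_window(assignments, persons)
        assert res.n_dropped_no_survey == 1 and "p1" not in res.kept

    def test_switching_survey_equals_naive_recompute(self, registry):
        rng = np.random.default_rng(11)
        persons, assignments = {}, {}
        for i in range(60):
            pid = f"p{i}"
            lag = int(rng.integers(-2500, 2500))
            persons[pid] = Person(
                person_id=pid,
                survey_dates={
                    "earliest": day(0),
                    "sdoh": day(int(rng.integers(0, 400))),
                },
            )
            assignments[pid] = assign_phenotype(
                timeline(pid=pid, events=[ct(pid, lag), dx(pid, lag, "K57.30")]), registry
            )
        for survey in ("earliest", "sdoh"):
            kept = set(apply_inclusion_window(assignments, persons, 5.0, survey).kept)
            naive = {
                pid
                for pid, a in assignments.items()
                if survey in persons[pid].survey_dates
                and abs((a.assignment_date - persons[pid].survey_dates[survey]).days)
                <= 365.25 * 5.0
            }
            assert kept == naive
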