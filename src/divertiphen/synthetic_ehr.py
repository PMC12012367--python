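"""Seeded synthetic EHR + survey cohort generator with known truth.

Every downstream module is testable without any restricted data
because this generator emits the full table set the readers accept —
persons, condition/procedure occurrences, visits with care settings,
item-level survey responses, a precomputed deprivation index — together
with the ground truth used to create it (severity class, barrier flags,
deprivation quintile, outcome-model linear predictor).

Construction is the inverse of the severity rules: a timeline built for
a target class is guaranteed to be assigned that class by the
phenotyper under the default code registry (e.g. a mild case gets a CT
plus a diverticulitis code 0-7 days later and at most one inpatient
admission; an operative/recurrent case gets either two disjoint coded
inpatient admissions or a linked colectomy/drain/fistula repair; an
excluded person carries diverticular codes but no confirming study in
the window; controls carry only decoy codes).

Default calibration emulates the study population the package targets:
severity mix with the most severe class near 5% of the
diverticulosis+severe contrast pool, composite unmet-need prevalence
near 40%, deprivation-graded barrier probabilities, and differential
(MAR) missingness that is heavier at lower income and education.

Randomness: one master seed; per-person substreams are derived by
counter (seed, person index), so enlarging a cohort never perturbs the
draws of earlier persons.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .ehr_core import (
    CareSetting,
    ClinicalEvent,
    Encounter,
    EventClass,
    EventTimeline,
    Person,
    Sex,
    Vocabulary,
)
from .phenotyper import Phenotype
from .sdoh_scoring import EDUCATION_LEVELS, EMPLOYMENT_LEVELS, INCOME_LEVELS

__all__ = [
    "OutcomeModel",
    "MissingnessModel",
    "SimConfig",
    "SimulatedCohort",
    "generate_events_for_class",
    "generate_cohort",
    "generate_analysis_frame",
    "plant_missingness",
    "tune_intercept",
]

_REFERENCE_DATE = dt.date(2020, 1, 1)

# codes used when *constructing* timelines (all present in the default registry)
_OSIS_CODES = ["K57.30", "K57.90", "562.10"]
_ITIS_CODES = ["K57.32", "K57.92", "562.11"]
_CT_CODES = ["74176", "74177", "74160"]
_ENDO_CODES = ["45378", "45380"]
_PROC_CODES = ["44140", "49406", "44660"]  # colectomy, drain, fistula repair
_DECOY_DX = [("I10", Vocabulary.ICD10CM), ("E11.9", Vocabulary.ICD10CM), ("K21.9", Vocabulary.ICD10CM)]

_CODE_VOCAB = {
    **{c: Vocabulary.ICD10CM for c in ["K57.30", "K57.90", "K57.32", "K57.92"]},
    **{c: Vocabulary.ICD9CM for c in ["562.10", "562.11"]},
}


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class OutcomeModel:
    """Logistic model for the severe-vs-diverticulosis contrast.

    Coefficients are on the log-odds scale and keyed by the design
    column names of the analysis stage. When ``intercept`` is None it is
    tuned (by bisection on a probe sample) so the marginal outcome
    prevalence within the contrast pool hits ``target_prevalence``.
    """

    coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "unmet_social_need": math.log(1.61),
            "age": 0.010,
            "sex_male": 0.05,
            "sex_other": 0.0,
            "bmi": 0.010,
            "charlson_index": 0.10,
            "insurance_barrier": 0.05,
            "education_less_than_hs": 0.30,
            "education_hs": 0.10,
            "income_lt_50k": 0.15,
            "income_50_100k": 0.05,
            "unmet_x_income_lt_50k": 0.0,
            "unmet_x_income_50_100k": 0.0,
            "unmet_x_education_less_than_hs": 0.0,
            "unmet_x_education_hs": 0.0,
        }
    )
    intercept: float | None = None
    target_prevalence: float = 0.05

    def linear_predictor(self, design: pd.DataFrame, intercept: float) -> np.ndarray:
        lp = np.full(len(design), intercept, dtype=float)
        for name, beta in self.coefficients.items():
            if beta != 0.0 and name in design.columns:
                lp += beta * design[name].to_numpy(dtype=float)
        return lp


@dataclass
class MissingnessModel:
    """Per-variable masking rates, optionally differential (MAR).

    ``rates`` maps a maskable variable (an instrument name, or ``bmi``)
    to a base probability. Variables listed in ``mar_variables`` get an
    extra log-odds shift ``mar_coefficient`` for persons with low income
    or low education, reproducing heavier social-needs missingness at
    lower socioeconomic status.
    """

    rates: dict[str, float] = field(default_factory=dict)
    mar_variables: tuple[str, ...] = ()
    mar_coefficient: float = 0.0

    def validate(self) -> None:
        for var, rate in self.rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {var!r} outside [0, 1]: {rate}")


def default_missingness() -> MissingnessModel:
    return MissingnessModel(
        rates={
            "hunger_vital_sign": 0.25,
            "housing_instability": 0.25,
            "delayed_or_cant_afford_care": 0.25,
            "bmi": 0.05,
            "income": 0.10,
            "education": 0.04,
        },
        mar_variables=(
            "hunger_vital_sign",
            "housing_instability",
            "delayed_or_cant_afford_care",
        ),
        mar_coefficient=0.7,
    )


#: deprivation-quintile-graded probabilities of each generated barrier
DEFAULT_BARRIER_PROBABILITIES: dict[str, tuple[float, ...]] = {
    "hunger_vital_sign": (0.07, 0.08, 0.10, 0.13, 0.18),
    "housing_instability": (0.13, 0.15, 0.17, 0.20, 0.24),
    "delayed_or_cant_afford_care": (0.17, 0.19, 0.21, 0.24, 0.28),
    "housing_quality": (0.13, 0.15, 0.17, 0.20, 0.25),
    "insurance": (0.06, 0.07, 0.08, 0.10, 0.12),
    "english_proficiency": (0.006, 0.008, 0.010, 0.014, 0.022),
    "neighborhood_disorder": (0.25, 0.35, 0.45, 0.55, 0.68),
    "mos_social_support": (0.55, 0.58, 0.61, 0.65, 0.70),
    "brief_health_literacy_screen": (0.30, 0.33, 0.36, 0.40, 0.46),
}

DEFAULT_CLASS_MIX: dict[str, float] = {
    "control": 0.66,
    "diverticulosis": 0.2375,
    "mild_diverticulitis": 0.05,
    "operative_or_recurrent": 0.0125,
    "excluded": 0.04,
}

#: income and education marginals by deprivation quintile (rows sum to 1)
_INCOME_BY_QUINTILE = np.array(
    [
        [0.28, 0.27, 0.45],
        [0.33, 0.27, 0.40],
        [0.39, 0.27, 0.34],
        [0.45, 0.26, 0.29],
        [0.52, 0.25, 0.23],
    ]
)
_EDUCATION_BY_QUINTILE = np.array(
    [
        [0.033, 0.10, 0.867],
        [0.045, 0.11, 0.845],
        [0.055, 0.125, 0.820],
        [0.070, 0.14, 0.790],
        [0.095, 0.16, 0.745],
    ]
)


@dataclass
class SimConfig:
    n_persons: int = 1000
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    survey_lag_sd_days: float = 450.0  # sd of survey-to-diagnosis lag
    barrier_probabilities: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BARRIER_PROBABILITIES)
    )
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    missingness_model: MissingnessModel = field(default_factory=default_missingness)
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class_mix must sum to 1, got {total}")
        for name, p in self.class_mix.items():
            Phenotype(name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"class_mix[{name!r}] outside [0, 1]")
        for name, probs in self.barrier_probabilities.items():
            if len(probs) != 5 or any(not 0 <= q <= 1 for q in probs):
                raise ValueError(f"barrier_probabilities[{name!r}] must be 5 values in [0, 1]")
        self.missingness_model.validate()
        pool = self.class_mix["diverticulosis"] + self.class_mix["operative_or_recurrent"]
        if pool <= 0 and self.outcome_model.target_prevalence > 0:
            raise ValueError("outcome model implies a contrast pool of size zero")


# ---------------------------------------------------------------------------
# Event-timeline construction (inverse of the severity rules)
# ---------------------------------------------------------------------------


def _day(anchor: dt.date, offset: int) -> dt.date:
    return anchor + dt.timedelta(days=int(offset))


def _dx_event(pid: str, date: dt.date, code: str, encounter_id: str | None = None) -> ClinicalEvent:
    return ClinicalEvent(
        person_id=pid,
        event_date=date,
        code=code,
        vocabulary=_CODE_VOCAB[code],
        event_class=EventClass.diagnosis,
        encounter_id=encounter_id,
    )


def _proc_event(pid: str, date: dt.date, code: str, event_class: EventClass,
                encounter_id: str | None = None) -> ClinicalEvent:
    return ClinicalEvent(
        person_id=pid,
        event_date=date,
        code=code,
        vocabulary=Vocabulary.CPT,
        event_class=event_class,
        encounter_id=encounter_id,
    )


def generate_events_for_class(
    target_class: Phenotype | str,
    person: Person,
    rng: np.random.Generator,
    anchor_date: dt.date | None = None,
) -> EventTimeline:
    """Build a timeline guaranteed to be assigned ``target_class``.

    ``anchor_date`` positions the index diagnosis (default: a random
    date within three years of the reference date). Decoy
    non-diverticular events and outpatient/ED encounters are sprinkled
    in so that classification is never trivially inferable from table
    sizes.
    """
    target = Phenotype(target_class)
    pid = person.person_id
    if anchor_date is None:
        anchor_date = _day(_REFERENCE_DATE, int(rng.integers(-1095, 366)))
    events: list[ClinicalEvent] = []
    encounters: list[Encounter] = []
    enc_seq = 0

    def new_encounter(start: dt.date, end: dt.date, setting: CareSetting) -> Encounter:
        nonlocal enc_seq
        enc_seq += 1
        enc = Encounter(
            encounter_id=f"{pid}-v{enc_seq}",
            person_id=pid,
            start_date=start,
            end_date=end,
            setting=setting,
        )
        encounters.append(enc)
        return enc

    # decoys for everyone
    for _ in range(int(rng.integers(0, 3))):
        code, vocab = _DECOY_DX[int(rng.integers(0, len(_DECOY_DX)))]
        d = _day(anchor_date, int(rng.integers(-700, 700)))
        enc = new_encounter(d, d, CareSetting.outpatient)
        events.append(
            ClinicalEvent(pid, d, code, vocab, EventClass.diagnosis, enc.encounter_id)
        )

    def confirm_event(date: dt.date) -> ClinicalEvent:
        if rng.random() < 0.7:
            return _proc_event(pid, date, _CT_CODES[int(rng.integers(0, len(_CT_CODES)))],
                               EventClass.imaging)
        return _proc_event(pid, date, _ENDO_CODES[int(rng.integers(0, len(_ENDO_CODES)))],
                           EventClass.procedure)

    def pick(codes: list[str]) -> str:
        return codes[int(rng.integers(0, len(codes)))]

    def inpatient_admission(start_offset: int, code: str, los: int | None = None) -> None:
        los = int(rng.integers(2, 7)) if los is None else los
        start = _day(anchor_date, start_offset)
        enc = new_encounter(start, _day(anchor_date, start_offset + los), CareSetting.inpatient)
        events.append(_dx_event(pid, start, code, enc.encounter_id))

    if target is Phenotype.control:
        # optionally a CT with a non-diverticular indication
        if rng.random() < 0.4:
            d = _day(anchor_date, int(rng.integers(-400, 400)))
            events.append(confirm_event(d))

    elif target is Phenotype.diverticulosis:
        offset = int(rng.integers(0, 8))
        events.append(confirm_event(_day(anchor_date, -offset)))
        enc = new_encounter(anchor_date, anchor_date, CareSetting.outpatient)
        events.append(_dx_event(pid, anchor_date, pick(_OSIS_CODES), enc.encounter_id))
        if rng.random() < 0.4:  # later repeat diverticulosis coding
            d = _day(anchor_date, int(rng.integers(30, 400)))
            events.append(_dx_event(pid, d, pick(_OSIS_CODES)))

    elif target is Phenotype.mild_diverticulitis:
        offset = int(rng.integers(0, 8))
        events.append(confirm_event(_day(anchor_date, -offset)))
        itis = pick(_ITIS_CODES)
        u = rng.random()
        if u < 0.45:  # at most one coded inpatient admission
            inpatient_admission(0, itis)
        elif u < 0.65:  # ED visit: never counts as an admission
            enc = new_encounter(anchor_date, anchor_date, CareSetting.emergency)
            events.append(_dx_event(pid, anchor_date, itis, enc.encounter_id))
        else:
            enc = new_encounter(anchor_date, anchor_date, CareSetting.outpatient)
            events.append(_dx_event(pid, anchor_date, itis, enc.encounter_id))
        if rng.random() < 0.3:
            events.append(_dx_event(pid, _day(anchor_date, -int(rng.integers(100, 600))),
                                    pick(_OSIS_CODES)))

    elif target is Phenotype.operative_or_recurrent:
        offset = int(rng.integers(0, 8))
        events.append(confirm_event(_day(anchor_date, -offset)))
        itis = pick(_ITIS_CODES)
        if rng.random() < 0.5:  # recurrent arm: >=2 disjoint coded admissions
            inpatient_admission(0, itis, los=int(rng.integers(2, 6)))
            gap = int(rng.integers(30, 500))
            inpatient_admission(gap, pick(_ITIS_CODES), los=int(rng.integers(2, 6)))
        else:  # operative arm: linked qualifying procedure
            inpatient_admission(0, itis, los=5)
            proc_date = _day(anchor_date, int(rng.integers(0, 21)))
            events.append(
                _proc_event(pid, proc_date, pick(_PROC_CODES), EventClass.procedure,
                            encounters[-1].encounter_id)
            )

    elif target is Phenotype.excluded:
        # a diverticular code with no confirming study 0..7 days before it
        code = pick(_OSIS_CODES) if rng.random() < 0.5 else pick(_ITIS_CODES)
        events.append(_dx_event(pid, anchor_date, code))
        if rng.random() < 0.5:  # a study *after* the code never confirms
            events.append(confirm_event(_day(anchor_date, int(rng.integers(10, 200)))))

    return EventTimeline(person=person, events=events, encounters=encounters)


# ---------------------------------------------------------------------------
# Vectorized covariate / outcome generation
# ---------------------------------------------------------------------------


def _draw_covariates(n: int, rng: np.random.Generator,
                     barrier_probabilities: Mapping[str, tuple[float, ...]]) -> pd.DataFrame:
    """Demographics, deprivation, socioeconomic categories, barrier flags."""
    age = np.clip(rng.normal(66, 9, n), 25, 95)
    sex_u = rng.random(n)
    sex = np.where(sex_u < 0.565, "female", np.where(sex_u < 0.997, "male", "other"))
    bmi = np.clip(rng.normal(30, 5.5, n), 16, 60)
    cci = np.minimum(rng.poisson(3.0, n), 15)
    dep = rng.random(n)
    quintile = np.minimum((dep * 5).astype(int) + 1, 5)

    def categorical_by_quintile(table: np.ndarray, levels: tuple[str, ...]) -> np.ndarray:
        out = np.empty(n, dtype=object)
        u = rng.random(n)
        for q in range(1, 6):
            mask = quintile == q
            cum = np.cumsum(table[q - 1])
            out[mask] = np.array(levels, dtype=object)[np.searchsorted(cum, u[mask])]
        return out

    income = categorical_by_quintile(_INCOME_BY_QUINTILE, INCOME_LEVELS)
    education = categorical_by_quintile(_EDUCATION_BY_QUINTILE, EDUCATION_LEVELS)

    frame = pd.DataFrame(
        {
            "age": age,
            "sex_at_birth": sex,
            "bmi": bmi,
            "charlson_index": cci,
            "deprivation_index": dep,
            "deprivation_quintile": quintile,
            "income": income,
            "education": education,
        }
    )
    for name, probs in barrier_probabilities.items():
        p = np.asarray(probs, dtype=float)[quintile - 1]
        frame[f"flag_{name}"] = (rng.random(n) < p).astype(int)
    frame["insurance"] = np.where(
        frame.get("flag_insurance", pd.Series(np.zeros(n))).to_numpy() == 1,
        "none or not accepted",
        "insured",
    )
    frame["unmet_social_need"] = (
        (frame["flag_hunger_vital_sign"] == 1)
        | (frame["flag_housing_instability"] == 1)
        | (frame["flag_delayed_or_cant_afford_care"] == 1)
    ).astype(int)
    frame["employment"] = np.array(EMPLOYMENT_LEVELS, dtype=object)[
        np.searchsorted(np.cumsum([0.055, 0.42, 0.525]), rng.random(n))
    ]
    return frame


def _design_from_covariates(frame: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=frame.index)
    X["age"] = frame["age"]
    X["sex_male"] = (frame["sex_at_birth"] == "male").astype(float)
    X["sex_other"] = (frame["sex_at_birth"] == "other").astype(float)
    X["bmi"] = frame["bmi"]
    X["charlson_index"] = frame["charlson_index"].astype(float)
    X["unmet_social_need"] = frame["unmet_social_need"].astype(float)
    X["insurance_barrier"] = (frame["insurance"] == "none or not accepted").astype(float)
    X["education_less_than_hs"] = (frame["education"] == EDUCATION_LEVELS[0]).astype(float)
    X["education_hs"] = (frame["education"] == EDUCATION_LEVELS[1]).astype(float)
    X["income_lt_50k"] = (frame["income"] == INCOME_LEVELS[0]).astype(float)
    X["income_50_100k"] = (frame["income"] == INCOME_LEVELS[1]).astype(float)
    X["unmet_x_income_lt_50k"] = X["unmet_social_need"] * X["income_lt_50k"]
    X["unmet_x_income_50_100k"] = X["unmet_social_need"] * X["income_50_100k"]
    X["unmet_x_education_less_than_hs"] = X["unmet_social_need"] * X["education_less_than_hs"]
    X["unmet_x_education_hs"] = X["unmet_social_need"] * X["education_hs"]
    return X


def tune_intercept(
    model: OutcomeModel,
    design: pd.DataFrame,
    target_prevalence: float | None = None,
) -> float:
    """Bisection for the intercept hitting the target marginal prevalence."""
    target = model.target_prevalence if target_prevalence is None else target_prevalence
    if not 0 < target < 1:
        raise ValueError("target prevalence must lie strictly inside (0, 1)")
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = (lo + hi) / 2
        prev = float(np.mean(_sigmoid(model.linear_predictor(design, mid))))
        if prev < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_analysis_frame(
    n: int,
    outcome_model: OutcomeModel | None = None,
    seed: int = 0,
    barrier_probabilities: Mapping[str, tuple[float, ...]] | None = None,
) -> pd.DataFrame:
    """Fast covariate-level draw of a severe-vs-diverticulosis contrast pool.

    Bypasses event-timeline construction (the deterministic phenotyper
    round-trip is exercised separately): covariates and barrier flags
    are drawn as in :func:`generate_cohort`, the outcome class is drawn
    from the configured logistic model, and the frame is returned ready
    for :func:`divertiphen.analysis.fit_severity_model`. Used for
    parameter-recovery and coverage studies where hundreds of replicates
    are needed.
    """
    model = outcome_model or OutcomeModel()
    rng = np.random.default_rng([seed, 77])
    frame = _draw_covariates(n, rng, barrier_probabilities or DEFAULT_BARRIER_PROBABILITIES)
    X = _design_from_covariates(frame)
    intercept = model.intercept
    if intercept is None:
        intercept = tune_intercept(model, X)
    p = _sigmoid(model.linear_predictor(X, intercept))
    y = rng.random(n) < p
    frame["phenotype"] = np.where(y, Phenotype.operative_or_recurrent.value,
                                  Phenotype.diverticulosis.value)
    frame["true_probability"] = p
    frame["person_id"] = [f"p{i:07d}" for i in range(n)]
    return frame


# ---------------------------------------------------------------------------
# Full cohort generation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    tables: dict[str, pd.DataFrame]
    ground_truth: pd.DataFrame
    config: SimConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in self.tables.items():
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = path
        gt_path = out / "ground_truth.csv"
        self.ground_truth.to_csv(gt_path, index=False)
        paths["ground_truth"] = gt_path
        return paths


def _survey_rows_for_person(
    pid: str,
    cov: Mapping[str, object],
    rng: np.random.Generator,
) -> list[tuple[str, str, str]]:
    """Item-level responses consistent with the drawn flags and scores."""
    rows: list[tuple[str, str, str]] = []

    def add(item: str, resp: str) -> None:
        rows.append((pid, item, resp))

    if cov["flag_hunger_vital_sign"]:
        endorsed = int(rng.integers(0, 2))
        levels = ["never true", "sometimes true"]
        add("hvs_1", levels[1 - endorsed])
        add("hvs_2", levels[endorsed])
    else:
        add("hvs_1", "never true")
        add("hvs_2", "never true")
    add("housing_instability_1", "yes" if cov["flag_housing_instability"] else "no")
    add("housing_quality_1", "yes" if cov["flag_housing_quality"] else "no")
    if cov["flag_delayed_or_cant_afford_care"]:
        which = rng.random()
        add("delayed_care", "yes" if which < 0.7 else "no")
        add("cant_afford_care", "yes" if which >= 0.3 else "no")
    else:
        add("delayed_care", "no")
        add("cant_afford_care", "no")
    # BHLS: barrier -> at least one item below the top level
    if cov["flag_brief_health_literacy_screen"]:
        vals = rng.integers(3, 5, size=3)  # 3..4
    else:
        vals = np.full(3, 5)
    for k, v in enumerate(vals, 1):
        add(f"bhls_{k}", str(int(v)))
    # neighborhood disorder: favorable = all 1s
    if cov["flag_neighborhood_disorder"]:
        vals = 1 + rng.binomial(2, 0.35, size=6)
        if vals.max() == 1:
            vals[int(rng.integers(0, 6))] = 2
    else:
        vals = np.ones(6, dtype=int)
    for k, v in enumerate(vals, 1):
        add(f"nds_{k}", str(int(v)))
    # MOS-SS: favorable = all 5s
    if cov["flag_mos_social_support"]:
        vals = 5 - rng.binomial(3, 0.3, size=8)
        if vals.min() == 5:
            vals[int(rng.integers(0, 8))] = 4
    else:
        vals = np.full(8, 5)
    for k, v in enumerate(vals, 1):
        add(f"mos_{k}", str(int(v)))
    add("insurance_1", str(cov["insurance"]))
    add("income_1", str(cov["income"]))
    add("education_1", str(cov["education"]))
    add("english_1", "barrier" if cov["flag_english_proficiency"] else "proficient")
    add("employment_1", str(cov["employment"]))
    return rows


def generate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate the full CSV-ready table set plus ground truth.

    Severity classes are drawn from ``class_mix`` except inside the
    diverticulosis / operative-or-recurrent contrast pool, where the
    outcome class follows the configured logistic outcome model given
    the person's covariates. Event timelines are then constructed to
    realize the class; survey responses realize the drawn barrier
    flags; missingness is planted last. Fully reproducible per seed.
    """
    config.validate()
    n = config.n_persons
    rng = np.random.default_rng([config.seed, 1])
    cov = _draw_covariates(n, rng, config.barrier_probabilities)

    mix = config.class_mix
    pool_p = mix["diverticulosis"] + mix["operative_or_recurrent"]
    other = ["control", "mild_diverticulitis", "excluded"]
    cuts = np.cumsum([mix[c] for c in other] + [pool_p])
    u = rng.random(n)
    bucket = np.searchsorted(cuts, u)  # 0..2 other classes, 3 contrast pool

    X = _design_from_covariates(cov)
    model = config.outcome_model
    intercept = model.intercept
    if intercept is None:
        intercept = tune_intercept(model, X)
    p_severe = _sigmoid(model.linear_predictor(X, intercept))
    severe = rng.random(n) < p_severe
    classes = np.empty(n, dtype=object)
    for k, name in enumerate(other):
        classes[bucket == k] = name
    in_pool = bucket == len(other)
    classes[in_pool & severe] = Phenotype.operative_or_recurrent.value
    classes[in_pool & ~severe] = Phenotype.diverticulosis.value

    persons_rows, cond_rows, proc_rows, visit_rows, survey_date_rows = [], [], [], [], []
    response_rows: list[tuple[str, str, str]] = []
    gt_rows = []
    lag_days = rng.normal(0, config.survey_lag_sd_days, n)

    for i in range(n):
        pid = f"p{i:07d}"
        prng = np.random.default_rng([config.seed, 2, i])  # per-person substream
        birth = _REFERENCE_DATE - dt.timedelta(days=int(cov.at[i, "age"] * 365.25))
        person = Person(
            person_id=pid,
            birth_date=birth,
            sex_at_birth=Sex(cov.at[i, "sex_at_birth"]),
            bmi=round(float(cov.at[i, "bmi"]), 1),
            charlson_index=int(cov.at[i, "charlson_index"]),
            deprivation_index=round(float(cov.at[i, "deprivation_index"]), 4),
        )
        anchor = _day(_REFERENCE_DATE, int(prng.integers(-1095, 366)))
        timeline = generate_events_for_class(classes[i], person, prng, anchor_date=anchor)
        survey_date = _day(anchor, int(lag_days[i]))
        persons_rows.append(
            {
                "person_id": pid,
                "birth_date": birth.isoformat(),
                "sex_at_birth": person.sex_at_birth.value,
                "bmi": person.bmi,
                "charlson_index": person.charlson_index,
                "deprivation_index": person.deprivation_index,
            }
        )
        for name, date in [
            ("earliest", survey_date),
            ("healthcare_access", _day(survey_date, int(prng.integers(0, 90)))),
            ("sdoh", _day(survey_date, int(prng.integers(0, 365)))),
        ]:
            survey_date_rows.append({"person_id": pid, "survey": name, "survey_date": date.isoformat()})
        for enc in timeline.encounters:
            visit_rows.append(
                {
                    "visit_id": enc.encounter_id,
                    "person_id": pid,
                    "start_date": enc.start_date.isoformat(),
                    "end_date": enc.end_date.isoformat(),
                    "setting": enc.setting.value,
                }
            )
        for e in timeline.events:
            base = {
                "person_id": pid,
                "code": e.code,
                "vocabulary": e.vocabulary.value,
                "visit_id": e.encounter_id or "",
            }
            if e.event_class is EventClass.diagnosis:
                cond_rows.append({**base, "condition_date": e.event_date.isoformat()})
            else:
                proc_rows.append(
                    {**base, "procedure_date": e.event_date.isoformat(), "event_class": e.event_class.value}
                )
        response_rows.extend(_survey_rows_for_person(pid, cov.loc[i], prng))
        gt_rows.append(
            {
                "person_id": pid,
                "true_class": classes[i],
                "deprivation_quintile": int(cov.at[i, "deprivation_quintile"]),
                "unmet_social_need": int(cov.at[i, "unmet_social_need"]),
                "flag_hunger_vital_sign": int(cov.at[i, "flag_hunger_vital_sign"]),
                "flag_housing_instability": int(cov.at[i, "flag_housing_instability"]),
                "flag_delayed_or_cant_afford_care": int(cov.at[i, "flag_delayed_or_cant_afford_care"]),
                "in_contrast_pool": bool(in_pool[i]),
                "true_probability_severe": float(p_severe[i]),
            }
        )

    tables = {
        "persons": pd.DataFrame(persons_rows),
        "condition_occurrence": pd.DataFrame(
            cond_rows, columns=["person_id", "code", "vocabulary", "visit_id", "condition_date"]
        ),
        "procedure_occurrence": pd.DataFrame(
            proc_rows,
            columns=["person_id", "code", "vocabulary", "visit_id", "procedure_date", "event_class"],
        ),
        "visit_occurrence": pd.DataFrame(
            visit_rows, columns=["visit_id", "person_id", "start_date", "end_date", "setting"]
        ),
        "survey_dates": pd.DataFrame(survey_date_rows),
        "survey_responses": pd.DataFrame(response_rows, columns=["person_id", "item_id", "response"]),
    }
    mask_rng = np.random.default_rng([config.seed, 3])
    tables = plant_missingness(tables, config.missingness_model, mask_rng, covariates=cov)
    return SimulatedCohort(tables=tables, ground_truth=pd.DataFrame(gt_rows), config=config)


_INSTRUMENT_ITEMS: dict[str, list[str]] = {
    "hunger_vital_sign": ["hvs_1", "hvs_2"],
    "housing_instability": ["housing_instability_1"],
    "housing_quality": ["housing_quality_1"],
    "delayed_or_cant_afford_care": ["delayed_care", "cant_afford_care"],
    "brief_health_literacy_screen": ["bhls_1", "bhls_2", "bhls_3"],
    "neighborhood_disorder": [f"nds_{k}" for k in range(1, 7)],
    "mos_social_support": [f"mos_{k}" for k in range(1, 9)],
    "insurance": ["insurance_1"],
    "income": ["income_1"],
    "education": ["education_1"],
    "english_proficiency": ["english_1"],
    "employment": ["employment_1"],
}


def plant_missingness(
    tables: dict[str, pd.DataFrame],
    model: MissingnessModel,
    rng: np.random.Generator,
    covariates: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Mask survey instruments / person fields according to the model.

    Instrument masking removes all of that instrument's item rows for
    the selected persons. Under the differential (MAR) setting the
    masking log-odds shift ``mar_coefficient`` applies to persons with
    income below 50k or education below high school, so the missing
    group ends up with a higher low-income share than the available
    group, in expectation.
    """
    model.validate()
    tables = {k: v.copy() for k, v in tables.items()}
    persons = tables["persons"]
    n = len(persons)
    pid_index = pd.Index(persons["person_id"])

    low_ses = np.zeros(n, dtype=bool)
    if covariates is not None:
        low_ses = (
            (covariates["income"] == INCOME_LEVELS[0])
            | (covariates["education"] == EDUCATION_LEVELS[0])
        ).to_numpy()

    responses = tables.get("survey_responses")
    for var, rate in model.rates.items():
        if rate == 0:
            continue
        logit = math.log(rate / (1 - rate)) if 0 < rate < 1 else None
        if var in model.mar_variables and logit is not None and model.mar_coefficient:
            p = np.asarray(_sigmoid(logit + model.mar_coefficient * low_ses.astype(float)))
        else:
            p = np.full(n, rate)
        masked = rng.random(n) < p
        masked_ids = set(pid_index[masked])
        if var in _INSTRUMENT_ITEMS and responses is not None:
            items = set(_INSTRUMENT_ITEMS[var])
            drop = responses["item_id"].isin(items) & responses["person_id"].isin(masked_ids)
            responses = responses[~drop]
        elif var in persons.columns:
            persons.loc[persons["person_id"].isin(masked_ids), var] = np.nan
    if responses is not None:
        tables["survey_responses"] = responses.reset_index(drop=True)
    tables["persons"] = persons
    return tables
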