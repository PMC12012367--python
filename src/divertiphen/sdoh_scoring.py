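"""Survey instrument scoring and social-barrier derivation.

This module scores item-level survey responses into instrument scores,
binarizes barriers through *top-box conversion* (a top-box score is
achieved only when every answered item takes its most favorable level;
any other response pattern is non-top-box), builds the composite
unmet-social-need flag (any of food insecurity, housing instability, or
delayed / can't afford care), assigns area-deprivation quintiles from
the analysis cohort's empirical index distribution, and computes the
quintile fold enrichment of each barrier (share of the barrier's counts
falling in the most deprived quintile divided by the share in the least
deprived quintile, which reduces to a ratio of raw counts).

Missing-data conventions: an instrument score is missing when any item
is missing (strictest default); a barrier flag is missing only when all
of its items are missing; the composite flag is 1 on any endorsed
barrier, 0 only when all three are observed 0, and missing otherwise
(absence of need cannot be certified from incomplete data).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ehr_core import Person

logger = logging.getLogger(__name__)

__all__ = [
    "Scoring",
    "ItemSpec",
    "InstrumentSpec",
    "InstrumentRegistry",
    "SurveyProfile",
    "MISSING",
    "score_instrument",
    "top_box",
    "barrier_flag",
    "composite_unmet_need",
    "assign_quintiles",
    "fold_enrichment",
    "build_profiles",
    "barrier_matrix",
    "enrichment_table",
    "default_instruments",
]

#: sentinel for a missing score / flag (kept distinct from numeric 0)
MISSING = None

UNMET_NEED_COMPONENTS = ("hunger_vital_sign", "housing_instability", "delayed_or_cant_afford_care")


class Scoring(str, Enum):
    sum = "sum"
    mean = "mean"
    categorical = "categorical"
    screen = "screen"


@dataclass(frozen=True)
class ItemSpec:
    item_id: str
    levels: tuple[str, ...]  # ordered; numeric value of level k is k+1
    favorable: str  # the single most favorable level

    def __post_init__(self) -> None:
        if self.favorable not in self.levels:
            raise ValueError(f"item {self.item_id}: favorable level not among levels")

    def value(self, response: str) -> int | None:
        try:
            return self.levels.index(response) + 1
        except ValueError:
            return None  # unknown level -> treated missing


@dataclass(frozen=True)
class InstrumentSpec:
    name: str
    items: tuple[ItemSpec, ...]
    scoring: Scoring
    at_risk_levels: frozenset[str] = frozenset()  # for screen-type scoring
    barrier_levels: frozenset[str] = frozenset()  # for categorical barriers

    def item(self, item_id: str) -> ItemSpec:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)


def score_instrument(
    spec: InstrumentSpec, responses: Mapping[str, str]
) -> float | str | None:
    """Score one instrument from its item responses.

    sum / mean use the 1-based level index as the item value; screen
    scoring (Hunger Vital Sign) is positive iff any answered item takes
    an at-risk level; categorical instruments return the (single) item's
    level. Unknown levels are treated as missing items, and any missing
    item makes the whole score missing (strictest default), except for
    the screen, which is positive on any endorsed item regardless of the
    other item's availability.
    """
    if spec.scoring is Scoring.screen:
        answered = []
        for it in spec.items:
            resp = responses.get(it.item_id)
            if resp is not None and resp in it.levels:
                answered.append(resp)
        if not answered:
            return MISSING
        if any(r in spec.at_risk_levels for r in answered):
            return "positive"
        if len(answered) < len(spec.items):
            return MISSING  # cannot certify a negative screen
        return "negative"

    if spec.scoring is Scoring.categorical:
        it = spec.items[0]
        resp = responses.get(it.item_id)
        if resp is None or resp not in it.levels:
            return MISSING
        return resp

    values = []
    for it in spec.items:
        resp = responses.get(it.item_id)
        v = None if resp is None else it.value(resp)
        if v is None:
            return MISSING
        values.append(v)
    total = float(sum(values))
    return total if spec.scoring is Scoring.sum else total / len(values)


def top_box(spec: InstrumentSpec, responses: Mapping[str, str]) -> int | None:
    """1 iff every item is answered at its most favorable level.

    Any answered item below its favorable level, or any missing item
    alongside answered ones, yields 0; missing only when all items are
    missing.
    """
    n_missing = 0
    all_favorable = True
    for it in spec.items:
        resp = responses.get(it.item_id)
        if resp is None or resp not in it.levels:
            n_missing += 1
            continue
        if resp != it.favorable:
            all_favorable = False
    if n_missing == len(spec.items):
        return MISSING
    if n_missing > 0:
        return 0
    return 1 if all_favorable else 0


def barrier_flag(spec: InstrumentSpec, responses: Mapping[str, str]) -> int | None:
    """1 = barrier present, 0 = absent, None = unobservable.

    Screens use the screen result; categorical instruments with declared
    barrier levels flag those levels; scored scales invert the top-box
    (non-top-box responses indicate the barrier).
    """
    if spec.scoring is Scoring.screen:
        s = score_instrument(spec, responses)
        if s is MISSING:
            return MISSING
        return 1 if s == "positive" else 0
    if spec.scoring is Scoring.categorical and spec.barrier_levels:
        s = score_instrument(spec, responses)
        if s is MISSING:
            return MISSING
        return 1 if s in spec.barrier_levels else 0
    tb = top_box(spec, responses)
    if tb is MISSING:
        return MISSING
    return 1 - tb


def composite_unmet_need(
    food_insecurity: int | None,
    housing_instability: int | None,
    delayed_or_cant_afford_care: int | None,
) -> int | None:
    """Any-of composite over the three selected barriers (symmetric)."""
    flags = (food_insecurity, housing_instability, delayed_or_cant_afford_care)
    if any(f == 1 for f in flags):
        return 1
    if all(f == 0 for f in flags):
        return 0
    return MISSING


def assign_quintiles(
    index_values: Sequence[float | None] | np.ndarray,
    boundaries: Sequence[float] | None = None,
) -> list[int | None]:
    """Quintile (1..5, 5 = most deprived) per deprivation-index value.

    Boundaries default to the 20/40/60/80th percentiles of the supplied
    non-missing values (the analysis cohort's empirical distribution);
    pass ``boundaries`` to use fixed external cut points instead. Values
    exactly on a boundary fall into the lower quintile. A degenerate
    all-identical input yields quintile 1 everywhere with a warning.
    """
    arr = np.array(
        [np.nan if v is None else float(v) for v in index_values], dtype=float
    )
    finite = arr[~np.isnan(arr)]
    if boundaries is None:
        if finite.size < 5:
            raise ValueError("need at least 5 non-missing index values")
        if np.all(finite == finite[0]):
            logger.warning("all deprivation-index values identical; everyone in quintile 1")
            return [None if math.isnan(v) else 1 for v in arr]
        boundaries = np.percentile(finite, [20, 40, 60, 80])
    bounds = np.asarray(boundaries, dtype=float)
    out: list[int | None] = []
    for v in arr:
        if math.isnan(v):
            out.append(None)
        else:
            out.append(int(1 + np.sum(v > bounds)))
    return out


@dataclass
class FoldEnrichment:
    value: float | None
    undefined_reason: str | None = None
    proportions: tuple[float, ...] = ()


def fold_enrichment(barrier_counts_by_quintile: Sequence[int]) -> FoldEnrichment:
    """c5/c1 on within-variable quintile proportions (the totals cancel).

    The five within-variable proportions are retained for heatmap-style
    output. A zero reference quintile (c1 = 0) flags the ratio as
    undefined rather than returning infinity.
    """
    counts = list(barrier_counts_by_quintile)
    if len(counts) != 5:
        raise ValueError("expected 5 quintile counts")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("total barrier count is zero")
    props = tuple(c / total for c in counts)
    if counts[0] == 0:
        return FoldEnrichment(value=None, undefined_reason="undefined (zero reference)", proportions=props)
    return FoldEnrichment(value=counts[4] / counts[0], proportions=props)


# ---------------------------------------------------------------------------
# Default instrument registry
# ---------------------------------------------------------------------------

InstrumentRegistry = dict[str, InstrumentSpec]

_YES_NO = ("no", "yes")
_AGREEMENT_5 = ("1", "2", "3", "4", "5")

INCOME_LEVELS = ("Less than 50k", "50-100k", "More than 100k")
EDUCATION_LEVELS = (
    "Less than high school degree or equivalent",
    "High school degree or equivalent",
    "Some college, college degree, or advanced degree",
)
EMPLOYMENT_LEVELS = ("Out of work", "Employed", "Other")


def default_instruments() -> InstrumentRegistry:
    """Bundled instrument definitions.

    Scored scales: the Hunger Vital Sign 2-item food-insecurity screen
    (positive on either item endorsed "often true"/"sometimes true"),
    the 3-item Brief Health Literacy Screen (sum, 3..15, 15 = best), a
    6-item perceived neighborhood physical disorder scale (mean, low =
    favorable), and an 8-item modified MOS social-support survey (mean,
    high = favorable). Housing instability/quality, delayed or can't
    afford care, insurance and English proficiency are single- or
    two-item instruments with one designated favorable level; income,
    education and employment are categorical with barrier groupings
    matching the descriptive-table cut points (income below 50k,
    education below high school, out of work).
    """

    def simple(name: str, items: list[str], levels: tuple[str, ...], favorable: str,
               scoring: Scoring, **kw) -> InstrumentSpec:
        return InstrumentSpec(
            name=name,
            items=tuple(ItemSpec(i, levels, favorable) for i in items),
            scoring=scoring,
            **kw,
        )

    hvs_levels = ("never true", "sometimes true", "often true")
    reg: InstrumentRegistry = {}
    reg["hunger_vital_sign"] = simple(
        "hunger_vital_sign", ["hvs_1", "hvs_2"], hvs_levels, "never true",
        Scoring.screen, at_risk_levels=frozenset({"sometimes true", "often true"}),
    )
    reg["brief_health_literacy_screen"] = simple(
        "brief_health_literacy_screen", ["bhls_1", "bhls_2", "bhls_3"],
        _AGREEMENT_5, "5", Scoring.sum,
    )
    reg["neighborhood_disorder"] = simple(
        "neighborhood_disorder", [f"nds_{k}" for k in range(1, 7)],
        _AGREEMENT_5, "1", Scoring.mean,
    )
    reg["mos_social_support"] = simple(
        "mos_social_support", [f"mos_{k}" for k in range(1, 9)],
        _AGREEMENT_5, "5", Scoring.mean,
    )
    reg["housing_instability"] = simple(
        "housing_instability", ["housing_instability_1"], _YES_NO, "no",
        Scoring.categorical, barrier_levels=frozenset({"yes"}),
    )
    reg["housing_quality"] = simple(
        "housing_quality", ["housing_quality_1"], _YES_NO, "no",
        Scoring.categorical, barrier_levels=frozenset({"yes"}),
    )
    # two items treated as one construct: endorsing either counts as the barrier
    reg["delayed_or_cant_afford_care"] = InstrumentSpec(
        name="delayed_or_cant_afford_care",
        items=(
            ItemSpec("delayed_care", _YES_NO, "no"),
            ItemSpec("cant_afford_care", _YES_NO, "no"),
        ),
        scoring=Scoring.screen,
        at_risk_levels=frozenset({"yes"}),
    )
    reg["insurance"] = simple(
        "insurance", ["insurance_1"], ("insured", "none or not accepted"), "insured",
        Scoring.categorical, barrier_levels=frozenset({"none or not accepted"}),
    )
    reg["income"] = simple(
        "income", ["income_1"], INCOME_LEVELS, "More than 100k",
        Scoring.categorical, barrier_levels=frozenset({"Less than 50k"}),
    )
    reg["education"] = simple(
        "education", ["education_1"], EDUCATION_LEVELS, EDUCATION_LEVELS[2],
        Scoring.categorical, barrier_levels=frozenset({EDUCATION_LEVELS[0]}),
    )
    reg["english_proficiency"] = simple(
        "english_proficiency", ["english_1"], ("proficient", "barrier"), "proficient",
        Scoring.categorical, barrier_levels=frozenset({"barrier"}),
    )
    reg["employment"] = simple(
        "employment", ["employment_1"], EMPLOYMENT_LEVELS, "Employed",
        Scoring.categorical, barrier_levels=frozenset({"Out of work"}),
    )
    return reg


def load_instruments(path: str | Path) -> InstrumentRegistry:
    """Load instrument definitions from a YAML file (same dialect as codesets).

    Layout per instrument: ``items`` (id -> {levels, favorable} or a
    shared block), ``scoring``, optional ``at_risk_levels`` /
    ``barrier_levels``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    reg: InstrumentRegistry = {}
    for name, block in raw.items():
        items = tuple(
            ItemSpec(
                item_id=item_id,
                levels=tuple(idef["levels"]),
                favorable=idef["favorable"],
            )
            for item_id, idef in block["items"].items()
        )
        reg[name] = InstrumentSpec(
            name=name,
            items=items,
            scoring=Scoring(block["scoring"]),
            at_risk_levels=frozenset(block.get("at_risk_levels", [])),
            barrier_levels=frozenset(block.get("barrier_levels", [])),
        )
    return reg


# ---------------------------------------------------------------------------
# Profile assembly
# ---------------------------------------------------------------------------


@dataclass
class SurveyProfile:
    person_id: str
    instrument_scores: dict[str, float | str | None] = field(default_factory=dict)
    barrier_flags: dict[str, int | None] = field(default_factory=dict)
    unmet_social_need: int | None = None
    deprivation_quintile: int | None = None


def build_profiles(
    responses: pd.DataFrame,
    persons: Mapping[str, Person],
    registry: InstrumentRegistry | None = None,
    quintile_boundaries: Sequence[float] | None = None,
) -> dict[str, SurveyProfile]:
    """Score every instrument for every person and derive the composites.

    ``responses`` holds item-level rows (person_id, item_id, response).
    Deprivation quintiles are computed over the supplied persons'
    non-missing index values unless fixed boundaries are given.
    """
    registry = registry or default_instruments()
    by_person: dict[str, dict[str, str]] = {pid: {} for pid in persons}
    for row in responses.itertuples(index=False):
        pid = str(row.person_id)
        if pid in by_person and isinstance(row.response, str) and row.response:
            by_person[pid][str(row.item_id)] = row.response

    ids = sorted(persons)
    quintiles = assign_quintiles(
        [persons[pid].deprivation_index for pid in ids], boundaries=quintile_boundaries
    )
    profiles: dict[str, SurveyProfile] = {}
    for pid, quint in zip(ids, quintiles):
        resp = by_person.get(pid, {})
        prof = SurveyProfile(person_id=pid, deprivation_quintile=quint)
        for name, spec in registry.items():
            prof.instrument_scores[name] = score_instrument(spec, resp)
            prof.barrier_flags[name] = barrier_flag(spec, resp)
        prof.unmet_social_need = composite_unmet_need(
            prof.barrier_flags.get("hunger_vital_sign"),
            prof.barrier_flags.get("housing_instability"),
            prof.barrier_flags.get("delayed_or_cant_afford_care"),
        )
        profiles[pid] = prof
    return profiles


def profiles_to_frame(profiles: Mapping[str, SurveyProfile]) -> pd.DataFrame:
    rows = []
    for pid in sorted(profiles):
        p = profiles[pid]
        row: dict[str, object] = {"person_id": pid, "deprivation_quintile": p.deprivation_quintile,
                                  "unmet_social_need": p.unmet_social_need}
        for name, score in p.instrument_scores.items():
            row[f"score_{name}"] = score
        for name, flag in p.barrier_flags.items():
            row[f"barrier_{name}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)


def barrier_matrix(profiles: Mapping[str, SurveyProfile]) -> pd.DataFrame:
    """Variables x quintiles matrix of within-variable barrier proportions.

    Cell (v, q) = count of persons in quintile q endorsing barrier v,
    divided by the total endorsed count of v across quintiles — the
    heatmap layout behind the enrichment ratios.
    """
    names = sorted({n for p in profiles.values() for n in p.barrier_flags})
    counts = pd.DataFrame(0, index=names, columns=[1, 2, 3, 4, 5], dtype=float)
    for p in profiles.values():
        if p.deprivation_quintile is None:
            continue
        for name, flag in p.barrier_flags.items():
            if flag == 1:
                counts.loc[name, p.deprivation_quintile] += 1
    totals = counts.sum(axis=1)
    props = counts.div(totals.replace(0, np.nan), axis=0)
    return props


def enrichment_table(profiles: Mapping[str, SurveyProfile]) -> pd.DataFrame:
    """Fold enrichment (quintile-5 share / quintile-1 share) per barrier."""
    names = sorted({n for p in profiles.values() for n in p.barrier_flags})
    counts = {name: [0, 0, 0, 0, 0] for name in names}
    for p in profiles.values():
        if p.deprivation_quintile is None:
            continue
        for name, flag in p.barrier_flags.items():
            if flag == 1:
                counts[name][p.deprivation_quintile - 1] += 1
    rows = []
    for name in names:
        c = counts[name]
        if sum(c) == 0:
            rows.append({"barrier": name, "fold_enrichment": np.nan, "note": "no endorsements"})
            continue
        fe = fold_enrichment(c)
        rows.append(
            {
                "barrier": name,
                "fold_enrichment": np.nan if fe.value is None else fe.value,
                "note": fe.undefined_reason or "",
            }
        )
    return pd.DataFrame(rows)
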