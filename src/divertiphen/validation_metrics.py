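"""Chart-review concordance statistics for phenotype validation.

The validation design: sample a fixed number of charts per assigned
class, have blinded experts label each chart with a severity class, then
score the algorithm one-vs-rest per class with positive and negative
predictive values, quantify inter-rater reliability with Cohen's kappa,
and report the per-class percentage of differential classification
(records where reviewers disagreed with each other).
"""

from __future__ import annotations

import math
import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "ReviewRecord",
    "ReviewSet",
    "ClassMetrics",
    "per_class_ppv_npv",
    "cohens_kappa",
    "differential_classification_pct",
    "sample_for_review",
    "consensus_label",
]


@dataclass(frozen=True)
class ReviewRecord:
    person_id: str
    algorithm_label: str
    reviewer_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.reviewer_labels) < 1:
            raise ValueError("at least one reviewer label required")


@dataclass
class ReviewSet:
    records: list[ReviewRecord] = field(default_factory=list)

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.algorithm_label)
            for lab in r.reviewer_labels:
                seen.setdefault(lab)
        return sorted(seen)


def consensus_label(record: ReviewRecord) -> tuple[str, bool]:
    """Majority vote over reviewer labels.

    Ties are resolved by first-reviewer precedence; the second return
    value flags that a tie occurred (the original design resolved
    disagreements by discussion, which cannot be mechanized).
    """
    counts = Counter(record.reviewer_labels)
    top = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == top]
    if len(winners) == 1:
        return winners[0], False
    for lab in record.reviewer_labels:
        if lab in winners:
            return lab, True
    raise AssertionError("unreachable")


@dataclass
class ClassMetrics:
    ppv: float | None
    npv: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    ppv_undefined_reason: str | None = None
    npv_undefined_reason: str | None = None


def per_class_ppv_npv(
    review: ReviewSet, reference: str | int = "consensus"
) -> dict[str, ClassMetrics]:
    """One-vs-rest PPV and NPV per class against a review reference.

    ``reference`` is either ``"consensus"`` (majority vote with
    first-reviewer tie-break) or an integer index selecting a single
    reviewer. PPV is computed over records the algorithm assigned to the
    class, NPV over records it withheld; a zero denominator yields
    ``None`` with a reason rather than 0.
    """
    refs: list[str] = []
    for r in review.records:
        if reference == "consensus":
            refs.append(consensus_label(r)[0])
        else:
            refs.append(r.reviewer_labels[int(reference)])
    out: dict[str, ClassMetrics] = {}
    for cls in review.classes:
        tp = fp = tn = fn = 0
        for rec, ref in zip(review.records, refs):
            assigned = rec.algorithm_label == cls
            truly = ref == cls
            if assigned and truly:
                tp += 1
            elif assigned:
                fp += 1
            elif truly:
                fn += 1
            else:
                tn += 1
        ppv = tp / (tp + fp) if (tp + fp) else None
        npv = tn / (tn + fn) if (tn + fn) else None
        out[cls] = ClassMetrics(
            ppv=ppv,
            npv=npv,
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
            ppv_undefined_reason=None if ppv is not None else "class never assigned by algorithm",
            npv_undefined_reason=None if npv is not None else "class always assigned by algorithm",
        )
    return out


def cohens_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from
    the product of the raters' marginal distributions. Perfect observed
    agreement returns 1 even when p_e = 1 (degenerate single-category
    case); p_e = 1 with imperfect agreement is undefined and raises.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    n = len(labels_a)
    if n < 2:
        raise ValueError("need at least 2 paired labels")
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    if p_o == 1.0:
        return 1.0
    ca, cb = Counter(labels_a), Counter(labels_b)
    cats = set(ca) | set(cb)
    p_e = sum((ca[c] / n) * (cb[c] / n) for c in cats)
    if math.isclose(p_e, 1.0):
        raise ValueError("expected agreement is 1 with imperfect observed agreement")
    return (p_o - p_e) / (1.0 - p_e)


def differential_classification_pct(
    review: ReviewSet,
) -> tuple[dict[str, float], int]:
    """Per algorithm-class percent of records with reviewer disagreement.

    Records with fewer than two reviewers are excluded; their count is
    returned alongside the percentages.
    """
    excluded = 0
    totals: Counter[str] = Counter()
    disagreements: Counter[str] = Counter()
    for r in review.records:
        if len(r.reviewer_labels) < 2:
            excluded += 1
            continue
        totals[r.algorithm_label] += 1
        if len(set(r.reviewer_labels)) > 1:
            disagreements[r.algorithm_label] += 1
    pct = {cls: 100.0 * disagreements[cls] / totals[cls] for cls in totals}
    return pct, excluded


def sample_for_review(
    assignments: Mapping[str, str], per_class_n: int, seed: int
) -> ReviewSet:
    """Seeded per-class uniform sample (without replacement) of charts.

    ``assignments`` maps person_id -> algorithm class. Classes smaller
    than ``per_class_n`` are sampled whole (with a warning via the
    return size). Row order is shuffled so reviewers are blinded to the
    sampling class blocks; reviewer label tuples start empty.
    """
    rng = random.Random(seed)
    by_class: dict[str, list[str]] = {}
    for pid in sorted(assignments):
        by_class.setdefault(assignments[pid], []).append(pid)
    rows: list[tuple[str, str]] = []
    for cls in sorted(by_class):
        pool = by_class[cls]
        k = min(per_class_n, len(pool))
        for pid in rng.sample(pool, k):
            rows.append((pid, cls))
    rng.shuffle(rows)
    return ReviewSet(
        records=[
            ReviewRecord(person_id=pid, algorithm_label=cls, reviewer_labels=("__unreviewed__",))
            for pid, cls in rows
        ]
    )
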