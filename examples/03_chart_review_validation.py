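"""Validate algorithm assignments against simulated chart review.

A stratified sample of persons is drawn per assigned class, two
simulated reviewers read each chart (here: the ground-truth label with
a small independent error rate), and the agreement statistics used to
validate phenotyping algorithms are computed: per-class PPV/NPV against
the reviewer consensus, Cohen's kappa between reviewers, and the
differential classification rate.
"""

import random

from divertiphen import (
    ReviewRecord,
    ReviewSet,
    SimConfig,
    cohens_kappa,
    differential_classification_pct,
    generate_cohort,
    per_class_ppv_npv,
    sample_for_review,
)

REVIEWER_ERROR = 0.05
CLASSES = ["control", "diverticulosis", "mild_diverticulitis",
           "operative_or_recurrent", "excluded"]

cohort = generate_cohort(SimConfig(n_persons=4000, seed=3))
truth = cohort.ground_truth.set_index("person_id")["true_class"].to_dict()

# The generator's labels double as algorithm output here (the
# phenotyper reproduces them exactly; see example 01).
sampled = sample_for_review(truth, per_class_n=100, seed=1)
print(f"sampled {len(sampled.records)} charts for review")


def reviewer_label(pid: str, rng: random.Random) -> str:
    """Ground truth corrupted with an independent 5% error."""
    if rng.random() < REVIEWER_ERROR:
        return rng.choice([c for c in CLASSES if c != truth[pid]])
    return truth[pid]


rng1, rng2 = random.Random(21), random.Random(22)
review = ReviewSet(
    records=[
        ReviewRecord(
            person_id=r.person_id,
            algorithm_label=r.algorithm_label,
            reviewer_labels=(reviewer_label(r.person_id, rng1),
                             reviewer_label(r.person_id, rng2)),
        )
        for r in sampled.records
    ]
)

print("\nper-class PPV / NPV against reviewer consensus:")
for cls, m in per_class_ppv_npv(review, reference="consensus").items():
    ppv = "undefined" if m.ppv is None else f"{m.ppv:.2f}"
    npv = "undefined" if m.npv is None else f"{m.npv:.2f}"
    print(f"  {cls:24s} PPV {ppv}  NPV {npv}  (tp={m.tp} fp={m.fp} tn={m.tn} fn={m.fn})")

kappa = cohens_kappa(
    [r.reviewer_labels[0] for r in review.records],
    [r.reviewer_labels[1] for r in review.records],
)
print(f"\nCohen's kappa between reviewers: {kappa:.3f}")

pct, excluded = differential_classification_pct(review)
print("\ndifferential classification (reviewers disagree), % per class:")
for cls, v in pct.items():
    print(f"  {cls:24s} {v:.1f}%")
print(f"  ({excluded} single-reviewer records excluded)")
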