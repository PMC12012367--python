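"""Descriptive tables, imputation, predictor filtering, and the
adjusted severity model.

The modelling contrast throughout is the most severe class (operative
or recurrent inpatient diverticulitis) against the least severe
confirmed class (diverticulosis, the reference); the mild class and
controls are excluded from the model. The adjusted logistic regression
covariates are age, sex at birth, BMI, Charlson Comorbidity Index, the
binary unmet-social-need flag, insurance, highest education, annual
income, and unmet-need x income / unmet-need x education interaction
terms. Multicollinearity is screened with variance inflation factors
computed on the pre-interaction design; covariates with under 20%
missingness are imputed with bagged decision trees; indicator levels
with near-zero variance or pairwise |r| > 0.90 are filtered during
design construction.

Descriptive tables report median (IQR) for continuous variables and
n (%) for categorical ones, compared with Kruskal-Wallis / Pearson
chi-squared across >2 groups (Wilcoxon rank-sum for 2 groups), and mask
any displayed cell with a count between 1 and 20 (small-cell
suppression; true counts are retained internally and exact zeros are
shown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import BaggingClassifier, BaggingRegressor
from sklearn.preprocessing import OrdinalEncoder
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .ehr_core import Person
from .phenotyper import Phenotype, PhenotypeAssignment, apply_inclusion_window
from .sdoh_scoring import EDUCATION_LEVELS, INCOME_LEVELS, SurveyProfile

logger = logging.getLogger(__name__)

__all__ = [
    "SUPPRESSION_THRESHOLD",
    "CohortTable",
    "ModelResult",
    "build_analysis_frame",
    "build_cohort_table",
    "impute_covariates",
    "filter_predictors",
    "fit_severity_model",
    "run_sensitivity",
]

#: displayed cells with 1 <= count <= SUPPRESSION_THRESHOLD are masked
SUPPRESSION_THRESHOLD = 20


# ---------------------------------------------------------------------------
# Analysis frame assembly
# ---------------------------------------------------------------------------


def build_analysis_frame(
    assignments: Mapping[str, PhenotypeAssignment],
    persons: Mapping[str, Person],
    profiles: Mapping[str, SurveyProfile],
) -> pd.DataFrame:
    """Join phenotype, demographics and survey-derived variables.

    Age is computed at the assignment date for cases, else at the
    earliest recorded survey date. One row per person present in
    ``assignments``.
    """
    rows = []
    for pid in sorted(assignments):
        a = assignments[pid]
        person = persons[pid]
        prof = profiles.get(pid)
        ref_date = a.assignment_date
        if ref_date is None and person.survey_dates:
            ref_date = min(person.survey_dates.values())
        age = None
        if ref_date is not None and person.birth_date is not None:
            age = (ref_date - person.birth_date).days / 365.25
        row: dict[str, object] = {
            "person_id": pid,
            "phenotype": a.phenotype.value,
            "age": age,
            "sex_at_birth": person.sex_at_birth.value,
            "bmi": person.bmi,
            "charlson_index": person.charlson_index,
            "deprivation_index": person.deprivation_index,
        }
        if prof is not None:
            row["unmet_social_need"] = prof.unmet_social_need
            row["deprivation_quintile"] = prof.deprivation_quintile
            row["income"] = prof.instrument_scores.get("income")
            row["education"] = prof.instrument_scores.get("education")
            row["insurance"] = prof.instrument_scores.get("insurance")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Descriptive tables with small-cell suppression
# ---------------------------------------------------------------------------


@dataclass
class TableCell:
    variable: str
    level: str  # "" for continuous rows
    group: str
    count: int | None = None
    percent: float | None = None
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    suppressed: bool = False


@dataclass
class CohortTable:
    cells: list[TableCell] = field(default_factory=list)
    comparisons: dict[str, tuple[str, float, float]] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def suppress(self, threshold: int = SUPPRESSION_THRESHOLD) -> "CohortTable":
        """Mark small cells; idempotent (true counts are kept internally)."""
        for c in self.cells:
            if c.count is not None and 1 <= c.count <= threshold:
                c.suppressed = True
        return self

    def to_frame(self, masked: bool = True) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            if c.median is not None or (c.count is None and not c.suppressed):
                display = (
                    f"{c.median:g} ({c.q1:g}, {c.q3:g})" if c.median is not None else ""
                )
            elif c.suppressed and masked:
                display = f"<={SUPPRESSION_THRESHOLD}"
            elif c.count is not None:
                display = f"{c.count} ({c.percent:.1f}%)" if c.percent is not None else str(c.count)
            else:
                display = ""
            test = self.comparisons.get(c.variable)
            rows.append(
                {
                    "variable": c.variable,
                    "level": c.level,
                    "group": c.group,
                    "display": display,
                    "count": None if (c.suppressed and masked) else c.count,
                    "percent": None if (c.suppressed and masked) else c.percent,
                    "suppressed": c.suppressed,
                    "test": test[0] if test else "",
                    "p_value": test[2] if test else np.nan,
                }
            )
        return pd.DataFrame(rows)


def build_cohort_table(
    frame: pd.DataFrame,
    group_col: str,
    variables: Sequence[str] | None = None,
    threshold: int = SUPPRESSION_THRESHOLD,
) -> CohortTable:
    """Per-variable summaries by group with comparison statistics.

    Numeric columns get median (IQR) and a Kruskal-Wallis rank-sum test
    (Wilcoxon rank-sum when exactly 2 groups); everything else gets
    level counts with within-group percentages and a Pearson chi-squared
    test. Suppression is applied last and affects display only.
    """
    groups = [g for g in frame[group_col].dropna().unique()]
    groups = sorted(groups, key=str)
    if variables is None:
        variables = [c for c in frame.columns if c not in (group_col, "person_id")]
    table = CohortTable(group_sizes={str(g): int((frame[group_col] == g).sum()) for g in groups})
    for var in variables:
        col = frame[var]
        if col.notna().sum() == 0:
            table.notes.append(f"{var}: all values missing")
            for g in groups:
                table.cells.append(TableCell(variable=var, level="(missing)", group=str(g)))
            continue
        if pd.api.types.is_numeric_dtype(col):
            samples = []
            for g in groups:
                vals = frame.loc[frame[group_col] == g, var].dropna().astype(float)
                samples.append(vals)
                if len(vals):
                    q1, med, q3 = np.percentile(vals, [25, 50, 75])
                    table.cells.append(
                        TableCell(variable=var, level="", group=str(g), median=med, q1=q1, q3=q3)
                    )
                else:
                    table.cells.append(TableCell(variable=var, level="", group=str(g)))
            nonempty = [s for s in samples if len(s) > 0]
            if len(nonempty) >= 2:
                try:
                    if len(groups) == 2:
                        stat, p = stats.ranksums(*nonempty[:2])
                        table.comparisons[var] = ("wilcoxon_rank_sum", float(stat), float(p))
                    else:
                        stat, p = stats.kruskal(*nonempty)
                        table.comparisons[var] = ("kruskal_wallis", float(stat), float(p))
                except ValueError as exc:
                    table.notes.append(f"{var}: test not computed ({exc})")
        else:
            levels = sorted(col.dropna().astype(str).unique())
            contingency = np.zeros((len(levels), len(groups)), dtype=int)
            for j, g in enumerate(groups):
                sub = frame.loc[frame[group_col] == g, var].dropna().astype(str)
                denom = len(sub)
                for i, lev in enumerate(levels):
                    n = int((sub == lev).sum())
                    contingency[i, j] = n
                    table.cells.append(
                        TableCell(
                            variable=var,
                            level=lev,
                            group=str(g),
                            count=n,
                            percent=(100.0 * n / denom) if denom else None,
                        )
                    )
            if contingency.sum() and contingency.shape[0] > 1 and contingency.shape[1] > 1:
                keep = contingency.sum(axis=1) > 0
                try:
                    chi2, p, _, _ = stats.chi2_contingency(contingency[keep])
                    table.comparisons[var] = ("pearson_chi2", float(chi2), float(p))
                except ValueError as exc:
                    table.notes.append(f"{var}: chi-squared not computed ({exc})")
    return table.suppress(threshold)


# ---------------------------------------------------------------------------
# Imputation and predictor filtering
# ---------------------------------------------------------------------------


def impute_covariates(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    max_missing_frac: float = 0.20,
    seed: int | None = 0,
    n_estimators: int = 25,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Bagged-tree single imputation of covariates under 20% missing.

    Each eligible covariate is predicted from the fully observed
    covariates by an ensemble of bootstrap-aggregated decision trees
    (regressor for numeric, classifier for categorical). Covariates at
    or above the threshold are left untouched and flagged; columns not
    listed in ``covariates`` (outcome, exposure, identifiers) are never
    imputed. With no complete predictor available the fallback is
    median / mode imputation, with a warning in the report.
    """
    out = frame.copy()
    report: dict[str, dict] = {}
    n = len(out)
    if n == 0:
        return out, report
    complete = [c for c in covariates if out[c].notna().all()]
    for col in covariates:
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        frac = n_missing / n
        if frac >= max_missing_frac:
            report[col] = {"n_missing": n_missing, "frac": frac, "method": "left_unimputed"}
            continue
        predictors = [c for c in complete if c != col]
        numeric = pd.api.types.is_numeric_dtype(out[col])
        if not predictors:
            if numeric:
                fill = out[col].median()
            else:
                fill = out[col].mode().iloc[0]
            out[col] = out[col].fillna(fill)
            report[col] = {"n_missing": n_missing, "frac": frac, "method": "fallback_median_mode"}
            logger.warning("no complete predictors; %s imputed by median/mode", col)
            continue
        X = pd.DataFrame(index=out.index)
        for p in predictors:
            if pd.api.types.is_numeric_dtype(out[p]):
                X[p] = out[p].astype(float)
            else:
                enc = OrdinalEncoder()
                X[p] = enc.fit_transform(out[[p]].astype(str)).ravel()
        mask = out[col].isna()
        if numeric:
            model = BaggingRegressor(n_estimators=n_estimators, random_state=seed)
            model.fit(X[~mask], out.loc[~mask, col].astype(float))
            out.loc[mask, col] = model.predict(X[mask])
        else:
            model = BaggingClassifier(n_estimators=n_estimators, random_state=seed)
            model.fit(X[~mask], out.loc[~mask, col].astype(str))
            out.loc[mask, col] = model.predict(X[mask])
        report[col] = {"n_missing": n_missing, "frac": frac, "method": "bagged_trees"}
    return out, report


def filter_predictors(
    design: pd.DataFrame,
    min_prevalence: float = 0.01,
    freq_ratio: float = 19.0,
    corr_threshold: float = 0.90,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Drop near-zero-variance and highly correlated design columns.

    Near-zero variance: constant columns, indicator levels below
    ``min_prevalence``, or a most-common / second-most-common frequency
    ratio above ``freq_ratio`` in a column with few distinct values
    (unique fraction under 10%, so a continuous covariate with a
    clipped tail is never discarded). Correlation: for each pair with
    |r| > ``corr_threshold`` the later column is dropped; both members
    are reported.
    """
    dropped: list[tuple[str, str]] = []
    keep = []
    n = len(design)
    for col in design.columns:
        vals = design[col]
        counts = vals.value_counts()
        if len(counts) <= 1:
            dropped.append((col, "constant"))
            continue
        is_indicator = set(np.unique(vals)) <= {0, 1, 0.0, 1.0}
        if is_indicator and min(vals.mean(), 1 - vals.mean()) < min_prevalence:
            dropped.append((col, "near_zero_variance (prevalence)"))
            continue
        few_distinct = len(counts) / max(n, 1) < 0.10
        if few_distinct and counts.iloc[0] / counts.iloc[1] > freq_ratio:
            dropped.append((col, "near_zero_variance (frequency ratio)"))
            continue
        keep.append(col)
    design = design[keep]
    if len(design.columns) > 1 and n > 1:
        corr = design.corr().abs()
        to_drop = set()
        cols = list(design.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if cols[j] in to_drop or cols[i] in to_drop:
                    continue
                r = corr.iloc[i, j]
                if np.isfinite(r) and r > corr_threshold:
                    to_drop.add(cols[j])
                    dropped.append((cols[j], f"correlated with {cols[i]} (|r|={r:.3f})"))
        design = design[[c for c in cols if c not in to_drop]]
    return design, dropped


# ---------------------------------------------------------------------------
# Severity model
# ---------------------------------------------------------------------------


@dataclass
class ModelTerm:
    name: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class ModelResult:
    terms: list[ModelTerm] = field(default_factory=list)
    interaction_p: dict[str, float] = field(default_factory=dict)
    vif: dict[str, float] = field(default_factory=dict)
    n_used: int = 0
    n_outcome: int = 0
    imputation_report: dict = field(default_factory=dict)
    dropped_predictors: list[tuple[str, str]] = field(default_factory=list)
    converged: bool = True
    separation_flag: bool = False
    note: str = ""

    def term(self, name: str) -> ModelTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "terms": [vars(t) for t in self.terms],
            "interaction_p": self.interaction_p,
            "vif": self.vif,
            "n_used": self.n_used,
            "n_outcome": self.n_outcome,
            "imputation_report": self.imputation_report,
            "dropped_predictors": [list(d) for d in self.dropped_predictors],
            "converged": self.converged,
            "separation_flag": self.separation_flag,
            "note": self.note,
        }


OUTCOME_CLASS = Phenotype.operative_or_recurrent.value
REFERENCE_CLASS = Phenotype.diverticulosis.value

_CONTINUOUS = ["age", "bmi", "charlson_index"]


def _design_main_effects(frame: pd.DataFrame) -> pd.DataFrame:
    """Main-effect design with explicit reference levels.

    References: female sex, insured, education at least some college,
    income above 100k, no unmet social need.
    """
    X = pd.DataFrame(index=frame.index)
    for c in _CONTINUOUS:
        X[c] = frame[c].astype(float)
    X["sex_male"] = (frame["sex_at_birth"] == "male").astype(float)
    X["sex_other"] = (~frame["sex_at_birth"].isin(["male", "female"])).astype(float)
    X["unmet_social_need"] = frame["unmet_social_need"].astype(float)
    X["insurance_barrier"] = (frame["insurance"] == "none or not accepted").astype(float)
    X["education_less_than_hs"] = (frame["education"] == EDUCATION_LEVELS[0]).astype(float)
    X["education_hs"] = (frame["education"] == EDUCATION_LEVELS[1]).astype(float)
    X["income_lt_50k"] = (frame["income"] == INCOME_LEVELS[0]).astype(float)
    X["income_50_100k"] = (frame["income"] == INCOME_LEVELS[1]).astype(float)
    return X

INTERACTION_PARENTS = ("income_lt_50k", "income_50_100k", "education_less_than_hs", "education_hs")


def fit_severity_model(
    frame: pd.DataFrame,
    seed: int | None = 0,
    impute: bool = True,
    profile_ci: bool = False,
) -> ModelResult:
    """Adjusted logistic model for the severe-vs-diverticulosis contrast.

    Restricts to the two contrast classes, imputes eligible covariates,
    computes VIFs on the pre-interaction design, applies the
    near-zero-variance and correlation filters, adds unmet-need x
    income and unmet-need x education interaction terms, and fits a
    maximum-likelihood logit. Odds ratios come with 95% Wald intervals
    by default (``profile_ci`` switches to profile likelihood);
    interaction p-values are Wald tests on the interaction
    coefficients. Detected separation or non-convergence is flagged,
    never silently clipped.
    """
    result = ModelResult()
    sub = frame[frame["phenotype"].isin([OUTCOME_CLASS, REFERENCE_CLASS])].copy()
    sub = sub[sub["unmet_social_need"].notna()]
    if impute:
        sub, result.imputation_report = impute_covariates(
            sub, covariates=_CONTINUOUS + ["sex_at_birth", "insurance", "education", "income"],
            seed=seed,
        )
    needed = _CONTINUOUS + ["sex_at_birth", "insurance", "education", "income", "unmet_social_need"]
    sub = sub.dropna(subset=[c for c in needed if c in sub.columns])
    y = (sub["phenotype"] == OUTCOME_CLASS).astype(float)
    result.n_used = len(sub)
    result.n_outcome = int(y.sum())
    if len(sub) < 10 or y.nunique() < 2:
        result.converged = False
        result.note = "not estimable: cohort too small or outcome degenerate"
        return result

    X = _design_main_effects(sub)
    # VIFs on the pre-interaction design (with intercept)
    Xc = sm.add_constant(X, has_constant="add")
    arr = np.asarray(Xc, dtype=float)
    for k, name in enumerate(Xc.columns):
        if name == "const":
            continue
        try:
            result.vif[name] = float(variance_inflation_factor(arr, k))
        except (ZeroDivisionError, np.linalg.LinAlgError):
            result.vif[name] = float("inf")

    X, result.dropped_predictors = filter_predictors(X)
    for parent in INTERACTION_PARENTS:
        if parent in X.columns and "unmet_social_need" in X.columns:
            X[f"unmet_x_{parent}"] = X["unmet_social_need"] * X[parent]
    Xc = sm.add_constant(X, has_constant="add")

    model = sm.Logit(y, Xc)
    try:
        fit = model.fit(disp=0, maxiter=200)
    except Exception:
        # a singular Hessian under quasi-separation stops Newton; a
        # gradient-only optimizer can still reach the MLE, with the
        # inflated standard errors flagged below
        try:
            fit = model.fit(disp=0, maxiter=500, method="bfgs")
            result.note = "newton failed (singular hessian); bfgs fit reported"
        except Exception as exc:  # PerfectSeparationError and friends
            result.converged = False
            result.separation_flag = True
            result.note = f"fit failed: {exc}"
            return result
    result.converged = bool(fit.mle_retvals.get("converged", True))
    # enormous standard errors indicate quasi-separation
    if np.any(np.asarray(fit.bse) > 50):
        result.separation_flag = True
        result.note = (result.note + "; " if result.note else "") + (
            "quasi-separation suspected (inflated standard errors)"
        )

    ci = fit.conf_int(alpha=0.05)
    if profile_ci:
        try:
            ci = fit.conf_int(alpha=0.05, method="profile")
        except Exception:
            result.note += " profile CI unavailable; Wald reported"
    for name in Xc.columns:
        if name == "const":
            continue
        result.terms.append(
            ModelTerm(
                name=name,
                odds_ratio=float(np.exp(fit.params[name])),
                ci_low=float(np.exp(ci.loc[name, 0])),
                ci_high=float(np.exp(ci.loc[name, 1])),
                p=float(fit.pvalues[name]),
            )
        )
        if name.startswith("unmet_x_"):
            result.interaction_p[name] = float(fit.pvalues[name])
    return result


def run_sensitivity(
    assignments: Mapping[str, PhenotypeAssignment],
    persons: Mapping[str, Person],
    profiles: Mapping[str, SurveyProfile],
    variants: Sequence[dict] = (
        {"window_years": 2.5, "inclusion_survey": "earliest"},
        {"window_years": 5.0, "inclusion_survey": "healthcare_access"},
        {"window_years": 5.0, "inclusion_survey": "sdoh"},
    ),
    seed: int | None = 0,
) -> list[dict]:
    """Refit the severity model under alternative inclusion rules.

    Each variant re-applies the survey inclusion window to the raw
    (unfiltered) assignments, rebuilds the analysis frame, and refits;
    cohort-size deltas are reported alongside each ModelResult. A
    variant too small to fit is reported as not estimable rather than
    raising.
    """
    out = []
    for variant in variants:
        inc = apply_inclusion_window(
            assignments,
            persons,
            window_years=variant.get("window_years", 5.0),
            inclusion_survey=variant.get("inclusion_survey", "earliest"),
        )
        frame = build_analysis_frame(inc.kept, persons, profiles)
        res = fit_severity_model(frame, seed=seed)
        out.append(
            {
                "variant": dict(variant),
                "n_cohort": len(inc.kept),
                "n_dropped_outside_window": inc.n_dropped_outside_window,
                "n_dropped_no_survey": inc.n_dropped_no_survey,
                "model": res,
            }
        )
    return out
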