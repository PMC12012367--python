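import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import hadamard

from divertiphen.analysis import (
    build_cohort_table,
    filter_predictors,
    fit_severity_model,
    impute_covariates,
    run_sensitivity,
)
from divertiphen.sdoh_scoring import EDUCATION_LEVELS, INCOME_LEVELS
from divertiphen.synthetic_ehr import OutcomeModel, generate_analysis_frame


class TestCohortTable:
    def _toy_frame(self):
        rng = np.random.default_rng(0)
        n = 120
        return pd.DataFrame(
            {
                "group": np.repeat(["a", "b"], n // 2),
                "flag": rng.choice(["yes", "no"], n),
                "value": rng.normal(10, 2, n),
            }
        )

    def test_binary_variable_gets_percent_cells_and_chi2(self):
        table = build_cohort_table(self._toy_frame(), "group")
        cells = [c for c in table.cells if c.variable == "flag"]
        assert {c.group for c in cells} == {"a", "b"}
        assert table.comparisons["flag"][0] == "pearson_chi2"
        assert table.comparisons["value"][0] == "wilcoxon_rank_sum"

    def test_small_cells_suppressed_values_withheld(self):
        frame = pd.DataFrame(
            {
                "group": ["a"] * 100 + ["b"] * 100,
                "flag": ["yes"] * 18 + ["no"] * 82 + ["yes"] * 60 + ["no"] * 40,
            }
        )
        table = build_cohort_table(frame, "group")
        cell = next(c for c in table.cells if c.group == "a" and c.level == "yes")
        assert cell.suppressed and cell.count == 18  # true count kept internally
        out = table.to_frame()
        row = out[(out.group == "a") & (out.level == "yes")].iloc[0]
        assert pd.isna(row["count"]) and row["display"] == "<=20"

    def test_zero_cells_are_displayed_not_suppressed(self):
        frame = pd.DataFrame(
            {"group": ["a"] * 60 + ["b"] * 60, "flag": ["no"] * 60 + ["yes"] * 30 + ["no"] * 30}
        )
        cell = next(
            c
            for c in build_cohort_table(frame, "group").cells
            if c.group == "a" and c.level == "yes"
        )
        assert cell.count == 0 and not cell.suppressed

    def test_suppression_idempotent(self):
        table = build_cohort_table(self._toy_frame(), "group")
        before = [(c.count, c.suppressed) for c in table.cells]
        table.suppress()
        assert [(c.count, c.suppressed) for c in table.cells] == before

    def test_percentages_sum_to_100_within_variable(self):
        table = build_cohort_table(self._toy_frame(), "group")
        for group in ("a", "b"):
            pct = [c.percent for c in table.cells if c.variable == "flag" and c.group == group]
            assert sum(pct) == pytest.approx(100.0)

    def test_kruskal_p_uniform_under_null(self):
        # 3 groups drawn from one distribution: p-values should be uniform
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(1000):
            frame = pd.DataFrame(
                {"group": np.repeat(["a", "b", "c"], 30), "value": rng.normal(size=90)}
            )
            pvals.append(build_cohort_table(frame, "group").comparisons["value"][2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_all_missing_variable_noted(self):
        frame = self._toy_frame()
        frame["ghost"] = np.nan
        table = build_cohort_table(frame, "group")
        assert any("ghost" in note for note in table.notes)


class TestImputation:
    def test_no_missingness_is_identity(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [0.5, 0.1, 0.9]})
        out, report = impute_covariates(frame, ["x", "y"])
        pd.testing.assert_frame_equal(out, frame)
        assert report == {}

    def test_heavy_missingness_left_untouched_and_flagged(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"x": rng.normal(size=100), "y": rng.normal(size=100)})
        frame.loc[:24, "y"] = np.nan  # 25% missing
        out, report = impute_covariates(frame, ["x", "y"])
        assert out["y"].isna().sum() == 25
        assert report["y"]["method"] == "left_unimputed"

    def test_bagged_trees_beat_median_imputation_on_correlated_data(self):
        rng = np.random.default_rng(1)
        n = 600
        x = rng.normal(size=n)
        z = 2 * x + rng.normal(scale=0.3, size=n)
        frame = pd.DataFrame({"x": x, "z": z})
        holes = rng.choice(n, size=n // 10, replace=False)  # 10% MCAR
        truth = frame.loc[holes, "z"].copy()
        frame.loc[holes, "z"] = np.nan
        out, report = impute_covariates(frame, ["x", "z"], seed=1)
        assert report["z"]["method"] == "bagged_trees"
        rmse = np.sqrt(np.mean((out.loc[holes, "z"] - truth) ** 2))
        median_rmse = np.sqrt(np.mean((truth - frame["z"].median()) ** 2))
        assert rmse < median_rmse

    def test_categorical_imputation_fills_all_holes(self):
        rng = np.random.default_rng(2)
        n = 300
        x = rng.normal(size=n)
        cat = np.where(x > 0, "high", "low").astype(object)
        frame = pd.DataFrame({"x": x, "cat": cat})
        frame.loc[:20, "cat"] = np.nan
        out, _ = impute_covariates(frame, ["x", "cat"], seed=0)
        assert out["cat"].notna().all()

    def test_protected_columns_never_imputed(self):
        frame = pd.DataFrame({"x": [1.0, np.nan, 3.0] * 10, "y": [np.nan, 1.0, 2.0] * 10})
        out, report = impute_covariates(frame, ["y"])
        assert out["x"].isna().sum() == 10 and "x" not in report


class TestFilterPredictors:
    def test_constant_column_dropped(self):
        design = pd.DataFrame({"a": [1.0] * 50, "b": np.arange(50, dtype=float)})
        kept, dropped = filter_predictors(design)
        assert "a" not in kept.columns and ("a", "constant") in dropped

    def test_duplicated_column_dropped_exactly_once(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        design = pd.DataFrame({"x1": x, "x2": x.copy(), "y": rng.normal(size=200)})
        kept, dropped = filter_predictors(design)
        assert list(kept.columns) == ["x1", "y"]
        assert any("x2" == name and "correlated" in reason for name, reason in dropped)

    def test_rare_indicator_dropped_as_near_zero_variance(self):
        n = 2000
        rare = np.zeros(n)
        rare[:2] = 1  # 0.1% prevalence, like a tiny "Other" sex cell
        design = pd.DataFrame({"rare": rare, "keep": np.tile([0.0, 1.0], n // 2)})
        kept, dropped = filter_predictors(design)
        assert "rare" not in kept.columns and "keep" in kept.columns

    def test_continuous_with_clipped_tail_not_dropped(self):
        rng = np.random.default_rng(3)
        bmi = np.clip(rng.normal(30, 5.5, 5000), 16, 60)
        design = pd.DataFrame({"bmi": bmi, "other": rng.normal(size=5000)})
        kept, _ = filter_predictors(design)
        assert "bmi" in kept.columns


class TestSeverityModel:
    def test_vif_is_one_for_orthogonal_design(self):
        # Hadamard-derived covariate patterns are exactly orthogonal
        H = hadamard(16).astype(float)
        frame = pd.DataFrame(
            {
                "phenotype": np.where(H[:, 1] > 0, "operative_or_recurrent", "diverticulosis"),
                "age": 60 + 5 * H[:, 2],
                "bmi": 30 + 2 * H[:, 3],
                "charlson_index": 3 + H[:, 4],
                "sex_at_birth": np.where(H[:, 5] > 0, "male", "female"),
                "unmet_social_need": (H[:, 6] > 0).astype(float),
                "insurance": np.where(H[:, 7] > 0, "none or not accepted", "insured"),
                "education": np.where(H[:, 8] > 0, EDUCATION_LEVELS[0], EDUCATION_LEVELS[2]),
                "income": np.where(H[:, 9] > 0, INCOME_LEVELS[0], INCOME_LEVELS[2]),
            }
        )
        res = fit_severity_model(frame, impute=False)
        for name in ("age", "bmi", "charlson_index", "sex_male", "unmet_social_need",
                     "insurance_barrier", "education_less_than_hs", "income_lt_50k"):
            assert res.vif[name] == pytest.approx(1.0, abs=1e-8)

    def test_invariant_to_row_order(self):
        frame = generate_analysis_frame(4000, seed=5)
        res1 = fit_severity_model(frame, seed=0)
        shuffled = frame.sample(frac=1.0, random_state=9).reset_index(drop=True)
        res2 = fit_severity_model(shuffled, seed=0)
        for t1 in res1.terms:
            assert res2.term(t1.name).odds_ratio == pytest.approx(t1.odds_ratio, rel=1e-6)

    def test_null_effect_is_unbiased_with_nominal_coverage(self):
        # generator unmet-need coefficient 0: estimates center on OR 1 and
        # Wald CIs cover 1 at close to the nominal 95% rate
        model = OutcomeModel()
        model.coefficients = dict(model.coefficients, unmet_social_need=0.0)
        ors, covered = [], 0
        n_reps = 500
        for s in range(n_reps):
            frame = generate_analysis_frame(4000, outcome_model=model, seed=10_000 + s)
            res = fit_severity_model(frame, seed=s, impute=False)
            t = res.term("unmet_social_need")
            ors.append(t.odds_ratio)
            covered += t.ci_low <= 1.0 <= t.ci_high
        assert np.mean(np.log(ors)) == pytest.approx(0.0, abs=0.03)
        assert covered / n_reps >= 0.93

    def test_recovers_doubled_odds_at_scale(self):
        # generator OR 2.0, n=20 000, ~5% outcome prevalence, 200 replicates
        model = OutcomeModel()
        model.coefficients = dict(model.coefficients, unmet_social_need=math.log(2.0))
        ors = []
        for s in range(200):
            frame = generate_analysis_frame(20_000, outcome_model=model, seed=20_000 + s)
            res = fit_severity_model(frame, seed=s, impute=False)
            ors.append(res.term("unmet_social_need").odds_ratio)
        assert abs(np.mean(ors) - 2.0) / 2.0 < 0.05

    def test_interaction_pvalues_reported(self):
        frame = generate_analysis_frame(8000, seed=3)
        res = fit_severity_model(frame, seed=0)
        assert set(res.interaction_p) == {
            name for name in res.interaction_p if name.startswith("unmet_x_")
        }
        assert len(res.interaction_p) >= 2

    def test_degenerate_cohort_reported_not_raised(self):
        frame = generate_analysis_frame(200, seed=1)
        frame["phenotype"] = "diverticulosis"
        res = fit_severity_model(frame)
        assert not res.converged and "not estimable" in res.note


@pytest.fixture(scope="module")
def pipeline(tmp_path_factory):
    from divertiphen.codesets import default_registry
    from divertiphen.ehr_core import read_dataset
    from divertiphen.phenotyper import assign_cohort
    from divertiphen.sdoh_scoring import build_profiles
    from divertiphen.synthetic_ehr import SimConfig, generate_cohort

    model = OutcomeModel()
    model.coefficients = dict(model.coefficients, unmet_social_need=math.log(2.0))
    cohort = generate_cohort(SimConfig(n_persons=12_000, seed=99, outcome_model=model))
    paths = cohort.write(tmp_path_factory.mktemp("cohort"))
    res = read_dataset(
        {k: v for k, v in paths.items() if k not in ("ground_truth", "survey_responses")}
    )
    persons = {pid: tl.person for pid, tl in res.timelines.items()}
    assignments = assign_cohort(res.timelines, default_registry())
    responses = pd.read_csv(paths["survey_responses"], dtype=str, keep_default_na=False)
    profiles = build_profiles(responses, persons)
    return assignments, persons, profiles


class TestSensitivity:
    def test_narrower_window_gives_strictly_smaller_cohort(self, pipeline):
        assignments, persons, profiles = pipeline
        out = run_sensitivity(
            assignments, persons, profiles,
            variants=[
                {"window_years": 5.0, "inclusion_survey": "earliest"},
                {"window_years": 2.5, "inclusion_survey": "earliest"},
            ],
        )
        assert out[1]["n_cohort"] < out[0]["n_cohort"]

    def test_empty_variant_list_gives_empty_result(self, pipeline):
        assignments, persons, profiles = pipeline
        assert run_sensitivity(assignments, persons, profiles, variants=[]) == []

    def test_effect_direction_stable_across_variants(self, pipeline):
        assignments, persons, profiles = pipeline
        out = run_sensitivity(assignments, persons, profiles)
        for entry in out:
            model = entry["model"]
            if model.converged and model.n_outcome >= 20:
                assert model.term("unmet_social_need").odds_ratio > 1.0
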