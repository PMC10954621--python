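"""Score engine: ranking, categorisation, point fitting, application."""

import numpy as np
import pandas as pd
import pytest

from edscore import (
    apply_score,
    categorize,
    clinical_cutoff_scheme,
    fit_points,
    paper_score_tables,
    parsimony_curve,
    rank_variables,
)
from edscore.scoring import (
    CutoffScheme,
    ParsimonyCurve,
    RankedVariables,
    ScoreError,
    interval_labels,
    points_from_coefficients,
)

from conftest import make_cohort


class TestCategorize:
    @pytest.mark.parametrize(
        "age,label", [(59.9, "<60"), (60.0, "60-80"), (79.9, "60-80"), (80.0, ">=80")]
    )
    def test_age_boundaries_left_closed(self, age, label):
        cohort = make_cohort(pd.DataFrame(dict(age=[age], death_2day=[False])))
        design, _ = categorize(cohort, ["age"], clinical_cutoff_scheme(["age"]))
        assert design["age"].iloc[0] == label

    def test_spo2_midband(self):
        cohort = make_cohort(pd.DataFrame(dict(spo2=[93.0], death_2day=[False])))
        design, _ = categorize(cohort, ["spo2"], clinical_cutoff_scheme(["spo2"]))
        assert design["spo2"].iloc[0] == "90-95"

    def test_constant_variable_flagged_unusable(self):
        cohort = make_cohort(
            pd.DataFrame(dict(sbp=[120.0] * 50, death_2day=[False] * 49 + [True]))
        )
        design, scheme = categorize(cohort, ["sbp"], "auto-quantile")
        assert "sbp" in scheme.unusable
        assert "sbp" not in design.columns

    def test_auto_quantile_merges_sparse_bins(self, cohort_b_small):
        design, scheme = categorize(cohort_b_small, ["sbp", "age"], "auto-quantile")
        for var in ("sbp", "age"):
            frac = design[var].value_counts(normalize=True)
            assert (frac >= 0.01).all(), var

    def test_missing_variable_rejected(self, cohort_b_small):
        with pytest.raises(ScoreError):
            categorize(cohort_b_small, ["not_a_column"], "auto-quantile")

    def test_interval_labels_require_increasing_cuts(self):
        assert interval_labels([90.0, 95.0]) == ["<90", "90-95", ">=95"]
        with pytest.raises(ScoreError):
            interval_labels([95.0, 90.0])


class TestRankVariables:
    def test_signal_variable_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 3000
        df = pd.DataFrame({f"noise": rng.normal(size=n)})
        df = pd.DataFrame(
            dict(
                spo2=rng.uniform(70, 100, n),
                age=rng.uniform(20, 90, n),
                pulse=rng.normal(90, 15, n),
                sbp=rng.normal(120, 20, n),
                dbp=rng.normal(75, 12, n),
                temperature=rng.normal(36.8, 0.5, n),
                resp_rate=rng.normal(18, 3, n),
            )
        )
        df["death_2day"] = df["spo2"] < 85  # deterministic threshold outcome
        ranked = rank_variables(make_cohort(df), seed=1, n_estimators=100)
        assert ranked.names[0] == "spo2"

    def test_single_class_rejected(self, tiny_cohort):
        data = tiny_cohort.data.assign(death_2day=False)
        from edscore import Cohort

        with pytest.raises(ScoreError):
            rank_variables(Cohort(site_id="T", data=data), seed=0, n_estimators=10)

    def test_importances_nonincreasing_and_tiebreak_stable(self):
        with pytest.raises(ScoreError):
            RankedVariables(items=[("a", 0.1), ("b", 0.5)])
        ranked = RankedVariables(items=[("b", 0.5), ("a", 0.5), ("c", 0.1)])
        assert ranked.top(2) == ["b", "a"]


class TestFitPoints:
    @staticmethod
    def binary_design(beta1=1.0, beta2=2.0, intercept=-1.0, n_cell=1000):
        """Grouped data whose logistic MLE is (essentially) the target betas."""
        rows = []
        for x1 in (0, 1):
            for x2 in (0, 1):
                p = 1.0 / (1.0 + np.exp(-(intercept + beta1 * x1 + beta2 * x2)))
                k = int(round(n_cell * p))
                rows += [(x1, x2, 1)] * k + [(x1, x2, 0)] * (n_cell - k)
        df = pd.DataFrame(rows, columns=["x1", "x2", "y"])
        design = pd.DataFrame(
            {"x1": np.where(df["x1"] == 1, "yes", "no"),
             "x2": np.where(df["x2"] == 1, "yes", "no")}
        )
        scheme = CutoffScheme(
            categorical={
                "x1": {"levels": ["no", "yes"], "reference": "no"},
                "x2": {"levels": ["no", "yes"], "reference": "no"},
            }
        )
        return design, df["y"], scheme

    def test_known_coefficient_ratio_gives_33_67(self):
        design, y, scheme = self.binary_design(beta1=1.0, beta2=2.0)
        table = fit_points(design, y, scheme)
        assert table.variables["x1"]["points"]["yes"] == 33
        assert table.variables["x2"]["points"]["yes"] == 67

    def test_single_positive_predictor_scores_100(self):
        design, y, scheme = self.binary_design()
        one = pd.DataFrame({"x1": design["x1"]})
        scheme_one = CutoffScheme(categorical={"x1": dict(scheme.categorical["x1"])})
        table = fit_points(one, y, scheme_one)
        assert table.variables["x1"]["points"] == {"no": 0, "yes": 100}

    def test_negative_coefficients_clamped_to_zero(self):
        design, y, scheme = self.binary_design(beta1=-1.5, beta2=2.0)
        table = fit_points(design, y, scheme)
        assert table.variables["x1"]["points"]["yes"] == 0
        assert table.variables["x2"]["points"]["yes"] == 100

    def test_single_class_rejected(self):
        design, y, scheme = self.binary_design()
        from edscore.scoring import ScoreFitError

        with pytest.raises(ScoreFitError):
            fit_points(design, pd.Series(np.zeros(len(design))), scheme)


class TestPointsMapping:
    def test_scale_equivariance(self):
        coef = {("a", "x"): 0.7, ("a", "y"): 1.4, ("b", "x"): -0.3, ("c", "z"): 2.2}
        base = points_from_coefficients(coef)
        for factor in (0.1, 3.0, 17.5):
            scaled = points_from_coefficients({k: factor * v for k, v in coef.items()})
            assert scaled == base

    def test_all_nonpositive_coefficients_give_zero_points(self):
        pts = points_from_coefficients({("a", "x"): -1.0, ("b", "y"): 0.0})
        assert set(pts.values()) == {0}

    def test_max_total_normalisation(self):
        pts = points_from_coefficients({("a", "x"): 1.0, ("b", "y"): 2.0, ("b", "z"): 1.0})
        per_var_max = {}
        for (var, _), p in pts.items():
            per_var_max[var] = max(per_var_max.get(var, 0), p)
        assert sum(per_var_max.values()) in (99, 100, 101)  # rounding slack


class TestApplyScore:
    def test_all_reference_patient_scores_zero(self):
        table = paper_score_tables()["overall"]
        record = dict(
            age=30, pulse=80, resp_rate=16, temperature=37.0, sbp=120, dbp=80,
            spo2=99, consciousness="alert",
        )
        assert apply_score(record, table) == 0

    def test_unconscious_low_spo2_sums_published_cells(self):
        table = paper_score_tables()["overall"]
        record = dict(
            age=30, pulse=80, resp_rate=16, temperature=37.0, sbp=120, dbp=80,
            spo2=85, consciousness="unconscious",
        )
        assert apply_score(record, table) == 24 + 15 == 39

    def test_additivity_against_per_variable_loop(self, cohort_b_small):
        table = paper_score_tables()["overall"]
        totals = apply_score(cohort_b_small.data, table)
        df = cohort_b_small.data
        for i in [0, 17, 255, 999]:
            manual = sum(
                table.points(var, table.category_of(var, df[var].iloc[i]))
                for var in table.variables
            )
            assert totals[i] == manual

    def test_scoring_is_idempotent(self, cohort_b_small):
        table = paper_score_tables()["A"]
        t1 = apply_score(cohort_b_small.data, table)
        t2 = apply_score(cohort_b_small.data, table)
        assert (t1 == t2).all()

    def test_missing_variable_scores_reference(self, caplog):
        table = paper_score_tables()["overall"]
        record = dict(
            age=85, pulse=80, resp_rate=16, temperature=37.0, sbp=120, dbp=80, spo2=99
        )  # consciousness absent
        import logging

        with caplog.at_level(logging.WARNING, logger="edscore.scoring"):
            total = apply_score(record, table)
        assert total == 11  # age >=80 only
        assert "consciousness" in caplog.text

    def test_unmapped_category_names_variable(self):
        table = paper_score_tables()["overall"]
        record = dict(
            age=30, pulse=80, resp_rate=16, temperature=37.0, sbp=120, dbp=80,
            spo2=99, consciousness="stuporous",
        )
        with pytest.raises(ScoreError, match="consciousness"):
            apply_score(record, table)


class TestPaperScoreTables:
    def test_published_cells(self):
        tables = paper_score_tables()
        assert tables["overall"].points("consciousness", "painful") == 17
        assert tables["A"].points("spo2", "<90") == 17
        assert tables["B"].points("consciousness", "unconscious") == 33
        assert tables["C"].points("sbp", "<90") == 14

    def test_reference_rows_all_zero(self):
        for table in paper_score_tables().values():
            for var, spec in table.variables.items():
                assert spec["points"][spec["reference"]] == 0, (table.site_id, var)

    def test_max_totals(self):
        totals = {s: t.max_total for s, t in paper_score_tables().items()}
        assert totals == {"A": 86, "B": 101, "C": 99, "overall": 93}

    def test_json_round_trip(self, tmp_path):
        from edscore.scoring import ScoreTable

        table = paper_score_tables()["B"]
        path = tmp_path / "scorecard.json"
        table.to_json(path)
        assert ScoreTable.from_json(path).to_dict() == table.to_dict()


class TestParsimony:
    def test_curve_defined_for_every_k(self, cohort_b_medium):
        from edscore import split_cohort

        dev, val = split_cohort(cohort_b_medium, 0.7, seed=0)
        ranked = rank_variables(dev, seed=0, n_estimators=50)
        curve = parsimony_curve(ranked, dev, val, k_max=4)
        assert [k for k, _ in curve.points] == [1, 2, 3, 4]
        assert all(np.isfinite(a) for _, a in curve.points)

    def test_select_respects_forced_k_and_tolerance(self):
        curve = ParsimonyCurve(points=[(1, 0.80), (2, 0.898), (3, 0.90), (4, 0.901)])
        assert curve.select(forced_k=8) == 8
        assert curve.select(tol=0.005) == 2  # 0.898 >= 0.995 * 0.901
        assert curve.select(tol=0.0) == 4

    def test_k_max_beyond_ranking_rejected(self, cohort_b_small):
        ranked = RankedVariables(items=[("age", 0.5), ("spo2", 0.4)])
        with pytest.raises(ScoreError):
            parsimony_curve(ranked, cohort_b_small, cohort_b_small, k_max=3)
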