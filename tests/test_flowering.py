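"""Stage-2 flowering regressions: designs, stepwise AIC, intervals, CV."""

import numpy as np
import pandas as pd
import pytest

from phenocast import flowering, synthetic
from phenocast.config import FULL_DATA_COEFFICIENTS, SINGLE_ORCHARD_COEFFICIENTS
from phenocast.errors import ConfigError, SchemaError
from phenocast.linmodel import evaluate_coefficients, interval_critical_value

EQ1_TERMS = (("CV",), ("BB",), ("DD",), ("CV", "BB"), ("BB", "DD"))


class TestPublishedModels:
    def test_full_data_model_intercept(self):
        value = evaluate_coefficients(FULL_DATA_COEFFICIENTS, {"CV": 0, "BB": 0, "DD": 0})
        assert value == pytest.approx(312.7, abs=1e-12)

    def test_single_orchard_model_intercept(self):
        value = evaluate_coefficients(SINGLE_ORCHARD_COEFFICIENTS, {"CV": 0, "BB": 0, "DD": 0})
        assert value == pytest.approx(471.2, abs=1e-12)

    def test_hayward_offset(self):
        z = evaluate_coefficients(FULL_DATA_COEFFICIENTS, {"CV": 0, "BB": 2.0, "DD": 2.0})
        h = evaluate_coefficients(FULL_DATA_COEFFICIENTS, {"CV": 1, "BB": 2.0, "DD": 2.0})
        assert h - z == pytest.approx(15.1 - 3.5 * 2.0)

    def test_99pct_normal_critical_value(self):
        assert round(interval_critical_value(0.99), 3) == 2.576


class TestDesign:
    def test_two_variable_full_factorial(self, eq1_records):
        terms = flowering.full_interaction_terms(("CV", "BB"))
        X, _ = flowering.build_design(eq1_records, terms)
        assert list(X.columns) == ["Intercept", "CV", "BB", "CV:BB"]

    def test_three_variable_expansion_has_eight_terms(self, eq1_records):
        terms = flowering.full_interaction_terms(("CV", "BB", "DD"))
        X, _ = flowering.build_design(eq1_records, terms)
        assert X.shape[1] == 8
        assert "CV:BB:DD" in X.columns

    def test_final_model_term_structure_representable(self, eq1_records):
        X, _ = flowering.build_design(eq1_records, EQ1_TERMS)
        assert list(X.columns) == ["Intercept", "CV", "BB", "DD", "CV:BB", "BB:DD"]

    def test_missing_predictor_is_schema_error(self, eq1_records):
        with pytest.raises(SchemaError, match="DL2"):
            flowering.build_design(eq1_records, (("DL2",),))

    def test_interaction_column_is_product(self, eq1_records):
        X, _ = flowering.build_design(eq1_records, (("CV",), ("BB",), ("CV", "BB")))
        np.testing.assert_allclose(X["CV:BB"], X["CV"] * X["BB"])


class TestOLS:
    def test_exact_linear_data_r2_one(self):
        rng = np.random.default_rng(0)
        df = synthetic.simulate_flowering_records(100, FULL_DATA_COEFFICIENTS, rng,
                                                  residual_sd=0.0)
        fit = flowering.fit_ols(df, EQ1_TERMS)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.rmse == pytest.approx(0.0, abs=1e-6)

    def test_matches_normal_equations_on_hand_dataset(self):
        df = pd.DataFrame({"CV": [0, 0, 1, 1, 1.0], "BB": [1.0, 2, 1, 3, 2],
                           "flower_doy": [310.0, 316, 330, 342, 335]})
        fit = flowering.fit_ols(df, (("CV",), ("BB",)))
        X = np.column_stack([np.ones(5), df["CV"], df["BB"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["flower_doy"].to_numpy())
        np.testing.assert_allclose(list(fit.coefficients.values()), beta, atol=1e-9)

    def test_coefficient_recovery_from_noisy_data(self):
        """Fitted Eq-structure coefficients land within 3 SEs of the truth."""
        hits = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = synthetic.simulate_flowering_records(500, FULL_DATA_COEFFICIENTS, rng)
            fit = flowering.fit_ols(df, EQ1_TERMS)
            se = np.asarray(fit.results.bse)
            truth = np.array([FULL_DATA_COEFFICIENTS[c] for c in fit.info.columns])
            est = np.asarray(fit.results.params)
            hits += int(np.sum(np.abs(est - truth) <= 3 * se))
            total += len(truth)
        assert hits / total >= 0.95

    def test_collinear_terms_named(self):
        rng = np.random.default_rng(1)
        df = synthetic.simulate_flowering_records(50, FULL_DATA_COEFFICIENTS, rng)
        df["DD"] = 2.0 * df["BB"]
        with pytest.raises(SchemaError, match="DD"):
            flowering.fit_ols(df, (("CV",), ("BB",), ("DD",)))

    def test_prediction_at_mean_design_is_mean_response(self, eq1_records):
        """OLS with intercept passes through the design-column centroid."""
        fit = flowering.fit_ols(eq1_records, EQ1_TERMS)
        X, _ = flowering.build_design(eq1_records, fit.terms, info=fit.info)
        centroid = X.mean().to_numpy()[None, :]
        pred = float(fit.results.predict(centroid)[0])
        assert pred == pytest.approx(eq1_records["flower_doy"].mean(), abs=1e-6)


class TestStepwise:
    def test_spurious_three_way_dropped(self):
        """A zero three-way interaction is pruned in most replicates.

        AIC-based stepwise retains a single null term with probability
        P(chi2_1 > 2) ~= 0.157, so the drop rate is ~84%; we assert a
        bound that rate clearly exceeds.
        """
        dropped = 0
        full = flowering.full_interaction_terms(("CV", "BB", "DD"))
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            df = synthetic.simulate_flowering_records(300, FULL_DATA_COEFFICIENTS, rng)
            start = flowering.fit_ols(df, full)
            refined = flowering.stepwise_refine(df, start)
            assert refined.aic <= start.aic + 1e-9
            if ("CV", "BB", "DD") not in refined.terms:
                dropped += 1
        assert dropped >= 37  # binomial(50, 0.843) lower tail, p < 1e-3

    def test_true_minimal_model_is_a_fixed_point(self):
        rng = np.random.default_rng(2)
        df = synthetic.simulate_flowering_records(2000, FULL_DATA_COEFFICIENTS, rng,
                                                  residual_sd=0.5)
        start = flowering.fit_ols(df, EQ1_TERMS)
        refined = flowering.stepwise_refine(df, start)
        assert set(refined.terms) == set(EQ1_TERMS)

    def test_marginality_never_violated(self):
        rng = np.random.default_rng(3)
        df = synthetic.simulate_flowering_records(300, FULL_DATA_COEFFICIENTS, rng)
        full = flowering.full_interaction_terms(("CV", "BB", "DD"))
        refined = flowering.stepwise_refine(df, flowering.fit_ols(df, full))
        kept = set(refined.terms)
        for term in kept:
            if len(term) > 1:
                for var in term:
                    assert (var,) in kept


class TestIntervals:
    def test_zero_variance_zero_width(self):
        rng = np.random.default_rng(4)
        df = synthetic.simulate_flowering_records(200, FULL_DATA_COEFFICIENTS, rng,
                                                  residual_sd=0.0)
        fit = flowering.fit_ols(df, EQ1_TERMS)
        pt = flowering.predict_with_interval(fit, df.head(10))
        assert pt["interval_width"].max() == pytest.approx(0.0, abs=1e-5)

    def test_width_tracks_residual_sd(self, eq1_records):
        """With SE_mean << sigma the width is about 2 x 2.576 x RMSE."""
        fit = flowering.fit_ols(eq1_records, EQ1_TERMS)
        pt = flowering.predict_with_interval(fit, eq1_records)
        nominal = 2 * 2.576 * fit.rmse
        assert pt["interval_width"].min() == pytest.approx(nominal, rel=0.02)

    def test_nominal_coverage_on_correctly_specified_data(self):
        rng = np.random.default_rng(5)
        train = synthetic.simulate_flowering_records(1000, FULL_DATA_COEFFICIENTS, rng)
        test = synthetic.simulate_flowering_records(2000, FULL_DATA_COEFFICIENTS, rng)
        fit = flowering.fit_ols(train, EQ1_TERMS)
        pt = flowering.predict_with_interval(fit, test, level=0.99)
        assert flowering.coverage_percent(pt) == pytest.approx(99.0, abs=2.0)

    def test_extrapolation_flagged(self, eq1_records):
        fit = flowering.fit_ols(eq1_records, EQ1_TERMS)
        far = pd.DataFrame({"CV": [0.0], "BB": [50.0], "DD": [3.0]})
        pt = flowering.predict_with_interval(fit, far)
        assert bool(pt["extrapolated"].iloc[0])


class TestYearSplit:
    def test_generating_candidate_selected(self, eq1_records):
        res = flowering.evaluate_year_split(eq1_records, range(2016, 2020),
                                            range(2020, 2022))
        assert res.best_label == "CV.BB.DD"
        refined_row = res.table[res.table["model"] == "CV.BB.DD_1"].iloc[0]
        full_row = res.table[res.table["model"] == "CV.BB.DD"].iloc[0]
        assert refined_row["aic"] <= full_row["aic"] + 1e-9

    def test_unseen_test_cultivar_excluded(self, eq1_records):
        records = eq1_records.copy()
        # make the test years single-cultivar in training
        train_mask = records["year"] < 2020
        records = records[~(train_mask & (records["CV"] == 1))]
        res = flowering.evaluate_year_split(
            records, range(2016, 2020), range(2020, 2022), candidates=("BB.DD",))
        pred = res.predictions["BB.DD"]
        assert len(pred) == (records["year"] >= 2020).sum() - (
            (records["year"] >= 2020) & (records["cultivar"] == "Hayward")).sum()

    def test_empty_split_rejected(self, eq1_records):
        with pytest.raises(ConfigError):
            flowering.evaluate_year_split(eq1_records, (1990,), (2020, 2021))


class TestKFold:
    def test_training_folds_hold_80_percent(self, eq1_records):
        cv = flowering.kfold_cv(eq1_records, EQ1_TERMS, k=5, seed=1)
        n = len(eq1_records)
        for size in cv["train_sizes"]:
            assert abs(size - 0.8 * n) <= 1

    def test_noiseless_data_zero_cv_rmse(self):
        rng = np.random.default_rng(6)
        df = synthetic.simulate_flowering_records(200, FULL_DATA_COEFFICIENTS, rng,
                                                  residual_sd=0.0)
        cv = flowering.kfold_cv(df, EQ1_TERMS, k=5, seed=1)
        assert cv["rmse_max"] == pytest.approx(0.0, abs=1e-6)

    def test_cv_rmse_estimates_residual_sd(self):
        rng = np.random.default_rng(7)
        df = synthetic.simulate_flowering_records(1000, FULL_DATA_COEFFICIENTS, rng,
                                                  residual_sd=4.0)
        cv = flowering.kfold_cv(df, EQ1_TERMS, k=5, seed=1)
        assert cv["rmse_mean"] == pytest.approx(4.0, rel=0.10)

    def test_k_larger_than_n_rejected(self, eq1_records):
        with pytest.raises(ConfigError):
            flowering.kfold_cv(eq1_records.head(3), EQ1_TERMS, k=5)


def _orchard_records(rng, n_years=4, vines_per_year=24, row_effect=0.0):
    frames = []
    for year in range(2017, 2017 + n_years):
        df = synthetic.simulate_flowering_records(vines_per_year,
                                                  FULL_DATA_COEFFICIENTS, rng)
        df["year"] = year
        df["orchard"] = "KK-O1"
        idx = np.arange(vines_per_year)
        df["row"] = [f"R{(i // 2) % 4 + 1}" for i in idx]
        df["bay"] = [f"B{(i + i // 2) % 2 + 1}" for i in idx]
        df["flower_doy"] += row_effect * (df["row"] == "R1")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestPositional:
    def test_null_row_effects_widen_intervals(self):
        """With zero row effects the extra position parameters only add SE."""
        rng = np.random.default_rng(8)
        records = _orchard_records(rng)
        table = flowering.positional_analysis(records, (2017, 2018, 2019), (2020,),
                                              candidates=("CV.BB.DD",))
        inc = table[(table["model"] == "CV.BB.DD") & (table["row_bay"] == "included")]
        exc = table[(table["model"] == "CV.BB.DD") & (table["row_bay"] == "excluded")]
        assert inc["interval_max"].iloc[0] >= exc["interval_max"].iloc[0]

    def test_single_level_positions_change_nothing(self):
        rng = np.random.default_rng(9)
        records = _orchard_records(rng)
        records["row"] = "R1"
        records["bay"] = "B1"
        table = flowering.positional_analysis(records, (2017, 2018, 2019), (2020,),
                                              candidates=("CV.BB",))
        inc = table[table["row_bay"] == "included"].set_index("model")
        exc = table[table["row_bay"] == "excluded"].set_index("model")
        np.testing.assert_allclose(inc["aic"], exc["aic"], atol=1e-9)

    def test_multiple_orchards_rejected(self, eq1_records):
        records = eq1_records.assign(orchard=np.where(eq1_records.index % 2 == 0,
                                                      "A", "B"),
                                     row="R1", bay="B1")
        with pytest.raises(SchemaError):
            flowering.positional_analysis(records, (2016,), (2020,))
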