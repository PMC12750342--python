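"""Predictor screening, VIF, collinearity resolution, OLS fit, validation."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor

from paddythresh import core, reference, simulate
from paddythresh.regression import (
    Term,
    TransferModel,
    compute_vif,
    fit_transfer_model,
    linear_predictor,
    predict_rice,
    relative_importance,
    resolve_collinearity,
    screen_predictors,
    transformed_design,
    validate_model,
)

from conftest import make_regression_frame


class TestScreenPredictors:
    def test_strong_signal_retained(self):
        rng = np.random.default_rng(0)
        frame = make_regression_frame(100, rng, noise_sd=0.25)
        kept = screen_predictors(frame, "Cd")
        assert "S_T_Cd" in kept

    def test_type_one_error_calibrated_to_alpha(self):
        # a pure-noise predictor should survive screening at rate ~ alpha
        rng = np.random.default_rng(42)
        n, reps, hits = 100, 1000, 0
        for _ in range(reps):
            frame = pd.DataFrame(
                {
                    "site_id": [str(i) for i in range(n)],
                    "C_Fe": rng.lognormal(6, 0.5, n),
                    "Rice_Cd": rng.lognormal(-2, 0.5, n),
                }
            )
            kept = screen_predictors(frame, "Cd", candidates=["C_Fe"])
            hits += "C_Fe" in kept
        assert 0.03 <= hits / reps <= 0.07

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        frame = make_regression_frame(50, rng, noise_sd=0.2)
        frame["C_Fe"] = 390.0
        with pytest.warns(UserWarning, match="constant"):
            kept = screen_predictors(frame, "Cd")
        assert "C_Fe" not in kept

    def test_too_few_samples(self):
        rng = np.random.default_rng(2)
        frame = make_regression_frame(8, rng)
        with pytest.raises(ValueError, match="10"):
            screen_predictors(frame, "Cd")


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        vifs = compute_vif(pd.DataFrame({"a": x1, "b": x2}))
        assert vifs["a"] == pytest.approx(1.0, abs=1e-12)
        assert vifs["b"] == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_predictor_flags_infinity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        vifs = compute_vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])

    def test_matches_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(4)
        n = 200
        z = rng.normal(size=n)
        design = pd.DataFrame(
            {
                "a": 0.8 * z + 0.6 * rng.normal(size=n),
                "b": z,
                "c": rng.normal(size=n),
            }
        )
        vifs = compute_vif(design)
        X = design.to_numpy()
        for j, col in enumerate(design.columns):
            # brute-force oracle: R² of column j on the others
            others = np.column_stack(
                [np.ones(n), np.delete(X, j, axis=1)]
            )
            beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ beta
            r2 = 1 - resid @ resid / np.sum((X[:, j] - X[:, j].mean()) ** 2)
            assert vifs[col] == pytest.approx(1 / (1 - r2), abs=1e-9)
            sm_vif = variance_inflation_factor(
                np.column_stack([np.ones(n), X]), j + 1
            )
            assert vifs[col] == pytest.approx(sm_vif, rel=1e-8)


class TestResolveCollinearity:
    def test_available_form_dropped_from_correlated_pair(self):
        rng = np.random.default_rng(5)
        frame = make_regression_frame(116, rng, noise_sd=0.2)
        design = transformed_design(frame, ["S_T_Cd", "A_Cd", "pH"])
        assert design[["S_T_Cd", "A_Cd"]].corr().iloc[0, 1] > 0.7
        kept = resolve_collinearity(design)
        assert "S_T_Cd" in kept and "A_Cd" not in kept

    def test_low_vif_input_unchanged(self):
        rng = np.random.default_rng(6)
        design = pd.DataFrame(rng.normal(size=(80, 3)), columns=["x", "y", "z"])
        assert resolve_collinearity(design) == ["x", "y", "z"]

    def test_matches_exhaustive_search_on_collinear_triple(self):
        rng = np.random.default_rng(7)
        n = 150
        z = rng.normal(size=n)
        design = pd.DataFrame(
            {
                "x1": z + 0.05 * rng.normal(size=n),
                "x2": z + 0.05 * rng.normal(size=n),
                "x3": rng.normal(size=n),
            }
        )
        kept = resolve_collinearity(design)
        # brute-force oracle: maximal subsets whose VIFs all pass
        valid = []
        cols = list(design.columns)
        for mask in range(1, 2 ** len(cols)):
            subset = [c for k, c in enumerate(cols) if mask >> k & 1]
            if len(subset) < 2:
                valid.append(subset)
                continue
            if max(compute_vif(design[subset]).values()) <= 5.0:
                valid.append(subset)
        max_size = max(len(s) for s in valid)
        assert len(kept) == max_size
        assert sorted(kept) in [sorted(s) for s in valid if len(s) == max_size]
        assert max(compute_vif(design[kept]).values()) <= 5.0

    def test_output_always_passes_threshold(self):
        rng = np.random.default_rng(8)
        n = 100
        base = rng.normal(size=(n, 2))
        design = pd.DataFrame(
            {
                "p1": base[:, 0],
                "p2": base[:, 0] * 0.9 + 0.1 * rng.normal(size=n),
                "p3": base[:, 1],
                "p4": base[:, 1] * 0.95 + 0.05 * rng.normal(size=n),
            }
        )
        kept = resolve_collinearity(design)
        assert len(kept) == 1 or max(compute_vif(design[kept]).values()) <= 5.0


class TestFitTransferModel:
    def test_response_equal_to_predictor_gives_perfect_fit(self):
        rng = np.random.default_rng(9)
        frame = make_regression_frame(40, rng)
        frame["Rice_Cd"] = frame["S_T_Cd"]
        model = fit_transfer_model(frame, "Cd", ["S_T_Cd", "pH"])
        assert model.r2 == pytest.approx(1.0, abs=1e-12)
        assert model.coefficient("S_T_Cd") == pytest.approx(1.0, abs=1e-9)
        assert model.coefficient("pH") == pytest.approx(0.0, abs=1e-9)
        assert model.intercept == pytest.approx(0.0, abs=1e-8)

    def test_adjusted_r2_closed_form_identity(self):
        rng = np.random.default_rng(10)
        frame = make_regression_frame(60, rng, noise_sd=0.3)
        preds = ["pH", "SOM", "S_T_Cd", "C_Fe"]
        model = fit_transfer_model(frame, "Cd", preds)
        n, p = model.n_fit, len(preds)
        expected = 1 - (1 - model.r2) * (n - 1) / (n - p - 1)
        assert model.adj_r2 == pytest.approx(expected, abs=1e-12)

    def test_residuals_orthogonal_to_predictors(self):
        rng = np.random.default_rng(11)
        frame = make_regression_frame(80, rng, noise_sd=0.3)
        preds = ["pH", "S_T_Cd", "F_Fe"]
        model = fit_transfer_model(frame, "Cd", preds)
        design = transformed_design(frame, preds)
        resid = np.log10(frame["Rice_Cd"]) - linear_predictor(model, frame)
        for col in preds:
            x = design[col] - design[col].mean()
            x = x / np.std(x)
            assert abs(np.dot(resid, x)) < 1e-8

    def test_singular_design_names_dependent_columns(self):
        rng = np.random.default_rng(12)
        frame = make_regression_frame(40, rng, noise_sd=0.1)
        frame["F_Mn"] = frame["C_Fe"]  # exact duplicate after log10
        with pytest.raises(ValueError, match="C_Fe|F_Mn"):
            fit_transfer_model(frame, "Cd", ["pH", "C_Fe", "F_Mn"])

    def test_too_few_observations(self):
        rng = np.random.default_rng(13)
        frame = make_regression_frame(4, rng)
        with pytest.raises(ValueError, match="n > p"):
            fit_transfer_model(frame, "Cd", ["pH", "SOM", "S_T_Cd"])


class TestPredictRice:
    def test_identity_model(self):
        identity = TransferModel("Cd", 0.0, (Term("S_T_Cd", 1.0, "log10"),))
        assert predict_rice(identity, {"S_T_Cd": 0.2}) == pytest.approx(0.2)

    def test_doubling_soil_as_scales_by_power_law(self):
        model = reference.AS_TRANSFER_MODEL
        cov = {
            "pH": 7.5,
            "SOM": 34.55,
            "A_As": 40.0,
            **reference.COVARIATE_MEANS.oxides,
        }
        p1 = predict_rice(model, {**cov, "S_T_As": 60.0})
        p2 = predict_rice(model, {**cov, "S_T_As": 120.0})
        # with the available fraction held fixed the ratio is exactly 2^0.975
        assert p2 / p1 == pytest.approx(2 ** 0.975, rel=1e-12)
        # recomputing the available fraction from the tie perturbs it slightly
        aux = reference.AAS_RELATION
        q1 = predict_rice(model, {**cov, "S_T_As": 60.0, "A_As": aux(60.0)})
        q2 = predict_rice(model, {**cov, "S_T_As": 120.0, "A_As": aux(120.0)})
        assert q2 / q1 == pytest.approx(2 ** 0.975, rel=0.01)

    def test_missing_predictor_raises(self):
        with pytest.raises(core.SchemaError, match="S_T_Cd"):
            predict_rice(
                TransferModel("Cd", 0.0, (Term("S_T_Cd", 1.0, "log10"),)), {"pH": 7}
            )


class TestRelativeImportance:
    def test_single_predictor_is_100(self):
        rng = np.random.default_rng(14)
        frame = make_regression_frame(50, rng, noise_sd=0.2)
        model = fit_transfer_model(frame, "Cd", ["S_T_Cd"])
        assert relative_importance(model, frame) == {"S_T_Cd": 100.0}

    def test_equal_standardized_effects_both_100(self):
        rng = np.random.default_rng(15)
        n = 400
        frame = pd.DataFrame(
            {
                "site_id": [str(i) for i in range(n)],
                "pH": 7.0 + rng.normal(0, 1, n),
                "SOM": 30.0 + rng.normal(0, 1, n),
            }
        )
        frame["Rice_Cd"] = 10 ** (0.5 * frame["pH"] + 0.5 * frame["SOM"])
        model = fit_transfer_model(frame, "Cd", ["pH", "SOM"])
        imp = relative_importance(model, frame)
        assert imp["pH"] == pytest.approx(100.0, rel=0.15)
        assert imp["SOM"] == pytest.approx(100.0, rel=0.15)
        assert max(imp.values()) == 100.0

    def test_dominant_predictor_ranked_first(self, study_dataset):
        model = fit_transfer_model(
            study_dataset, "As", list(reference.AS_TRANSFER_MODEL.predictors)
        )
        imp = relative_importance(model, study_dataset)
        assert max(imp, key=imp.get) == "S_T_As"


class TestValidateModel:
    def test_perfect_predictions(self, reference_models):
        soils = simulate.generate_soils(simulate.GeneratorConfig(n=30, seed=16))
        ds = simulate.generate_rice(soils, noise_sd=0.0)
        ds = core.split_dataset(ds, n_validation=10, seed=1)
        report = validate_model(reference_models["Cd"], ds)
        assert report.r2 == pytest.approx(1.0, abs=1e-9)
        assert report.rmse == pytest.approx(0.0, abs=1e-9)
        assert report.n_validation == 10

    def test_constant_predictions_give_nonpositive_r2(self):
        rng = np.random.default_rng(17)
        frame = make_regression_frame(30, rng, noise_sd=0.3)
        ds = core.split_dataset(core.Dataset(frame), n_validation=10, seed=2)
        constant = TransferModel("Cd", -1.0, (Term("SOM", 0.0, "raw"),))
        report = validate_model(constant, ds)
        assert report.r2 <= 0.0

    def test_rmse_tracks_generating_noise(self, study_dataset):
        ds = core.split_dataset(study_dataset, n_validation=25, seed=3)
        model = fit_transfer_model(
            ds, "Cd", list(reference.CD_TRANSFER_MODEL.predictors)
        )
        report = validate_model(model, ds)
        assert 0.125 <= report.rmse <= 0.5  # within a factor 2 of sd 0.25

    def test_empty_validation_split(self, study_dataset):
        with pytest.raises(ValueError):
            validate_model(reference.CD_TRANSFER_MODEL, study_dataset)
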