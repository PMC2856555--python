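"""Probe ranking, forward-selection PLSR and its cross-validation honesty."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from strindex import (
    ExpressionMatrix,
    SignatureRegressor,
    evaluate_rmsep,
    fit_final_model,
    loo_rmsep_curve,
    predict_index,
    rank_probes,
)


def make_expr(values, phenotype, tissues=None, probes=None):
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        phenotype=pd.Series(phenotype, index=samples),
        tissue_of=pd.Series(tissues if tissues is not None else samples, index=samples),
    )


class TestRankProbes:
    def test_phenotype_copies_rank_first_regardless_of_sign(self, rng):
        y = np.array([0.0, 1.0, 2.0, 3.5, 5.0])
        values = rng.normal(size=(10, 5))
        values[3] = y
        values[7] = -y
        ranked = rank_probes(make_expr(values, y))
        assert set(ranked.index[:2]) == {"p3", "p7"}
        assert ranked.loc["p3", "r"] == pytest.approx(1.0)
        assert ranked.loc["p7", "r"] == pytest.approx(-1.0)

    def test_constant_probe_is_flagged_and_ranked_last(self, rng):
        y = np.arange(6.0)
        values = rng.normal(size=(5, 6))
        values[2] = 4.2
        ranked = rank_probes(make_expr(values, y))
        assert ranked.index[-1] == "p2"
        assert bool(ranked.loc["p2", "zero_variance"])
        assert np.isnan(ranked.loc["p2", "r"])

    def test_ranking_invariant_under_positive_affine_transform(self, rng):
        y = rng.normal(size=8)
        values = rng.normal(size=(20, 8))
        base = rank_probes(make_expr(values, y))
        scaled = values.copy()
        scaled[5] = 3.7 * scaled[5] + 11.0
        again = rank_probes(make_expr(scaled, y))
        assert list(base.index) == list(again.index)
        assert base["r"].drop("p5").equals(again["r"].drop("p5"))
        assert base.loc["p5", "r"] == pytest.approx(again.loc["p5", "r"])

    def test_p_values_follow_the_t_transform(self, rng):
        from scipy import stats

        y = rng.normal(size=10)
        values = rng.normal(size=(3, 10))
        ranked = rank_probes(make_expr(values, y))
        for probe in ranked.index:
            r = ranked.loc[probe, "r"]
            t = r * np.sqrt(8 / (1 - r**2))
            assert ranked.loc[probe, "p"] == pytest.approx(2 * stats.t.sf(abs(t), 8))


class TestPLSFit:
    def test_single_probe_single_component_equals_ols(self, rng):
        x = rng.normal(size=12)
        y = 2.0 * x + 1.0 + rng.normal(size=12) * 0.3
        expr = make_expr(x[None, :], y)
        model = fit_final_model(expr, n_selected=1, n_components=1)
        slope, intercept = np.polyfit(x, y, 1)
        pred = model.predict(expr.X())
        assert pred == pytest.approx(slope * x + intercept, abs=1e-9)

    def test_full_rank_pls_equals_multiple_least_squares(self, rng):
        X = rng.normal(size=(12, 3))
        y = X @ np.array([1.5, -2.0, 0.5]) + rng.normal(size=12) * 0.2
        expr = make_expr(X.T, y)
        model = fit_final_model(expr, n_selected=3, n_components=3)
        design = np.column_stack([X, np.ones(12)])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert model.predict(expr.X()) == pytest.approx(design @ beta, abs=1e-8)

    def test_refit_is_bit_identical(self, rng):
        X = rng.normal(size=(10, 20))
        y = rng.normal(size=10)
        expr = make_expr(X.T, y)
        a = fit_final_model(expr, n_selected=5, n_components=2)
        b = fit_final_model(expr, n_selected=5, n_components=2)
        assert np.array_equal(a.coef_, b.coef_)
        assert a.intercept_ == b.intercept_

    def test_component_request_beyond_rank_is_reduced(self, rng):
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        model = fit_final_model(make_expr(X.T, y), n_selected=2, n_components=8)
        assert model.n_components_ <= 2

    def test_training_predictions_match_training_rmsep(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        expr = make_expr(X.T, y)
        model = fit_final_model(expr, n_selected=6, n_components=2)
        pred = predict_index(model, expr)
        assert evaluate_rmsep(pred, y).rmsep == pytest.approx(model.training_rmsep_, abs=1e-12)

    def test_sklearn_contract(self, rng):
        model = SignatureRegressor(n_grid=(2,), max_components=2)
        assert clone(model).get_params() == model.get_params()
        X = pd.DataFrame(rng.normal(size=(8, 5)), columns=[f"p{i}" for i in range(5)])
        y = rng.normal(size=8)
        model.fit(X, y)
        assert hasattr(model, "coef_") and len(model.selected_probes_) == 2


class TestCrossValidation:
    def test_perfect_linear_probe_gives_zero_rmsep(self):
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        expr = make_expr(y[None, :] * 0.5 + 3.0, y)
        curve = loo_rmsep_curve(expr, n_grid=(1,), max_components=1)
        assert curve[1] == pytest.approx(0.0, abs=1e-8)

    def test_empty_grid_is_an_error(self, small_expression):
        expr, _ = small_expression
        with pytest.raises(ValueError, match="n_grid"):
            loo_rmsep_curve(expr, n_grid=())

    def test_permuted_phenotype_shows_no_skill(self, small_expression):
        expr, _ = small_expression
        rng = np.random.default_rng(31)
        tissues = expr.tissue_of.unique()
        perm = dict(zip(tissues, rng.permutation(
            [expr.phenotype[expr.tissue_of == t].iloc[0] for t in tissues])))
        shuffled = ExpressionMatrix(
            values=expr.values,
            phenotype=expr.tissue_of.map(perm),
            tissue_of=expr.tissue_of,
        )
        curve = loo_rmsep_curve(shuffled, n_grid=(5, 10), max_components=3)
        assert min(curve.values()) >= 0.8 * float(np.std(expr.phenotype))

    def test_held_out_tissue_phenotype_cannot_leak_into_its_prediction(self, small_expression):
        expr, _ = small_expression
        groups = expr.tissue_of.to_numpy()
        held = groups == "t0"

        def fit_with(pheno):
            return SignatureRegressor(n_grid=(5,), max_components=2).fit(
                expr.X(), pheno, groups=groups
            )

        honest = fit_with(expr.phenotype.to_numpy())
        corrupted_pheno = expr.phenotype.to_numpy().copy()
        corrupted_pheno[held] += 1000.0
        corrupted = fit_with(corrupted_pheno)
        for i in np.where(held)[0]:
            assert honest.cv_predictions_[5][i] == corrupted.cv_predictions_[5][i]

    def test_fold_reranking_changes_the_curve(self, small_expression):
        expr, _ = small_expression
        honest = loo_rmsep_curve(expr, n_grid=(5,), max_components=2, rerank_in_fold=True)
        leaky = loo_rmsep_curve(expr, n_grid=(5,), max_components=2, rerank_in_fold=False)
        assert honest[5] != leaky[5]

    def test_signature_size_recovery_within_factor_two(self, small_expression):
        expr, truth = small_expression
        planted = len(truth["signature_probes"])
        curve = loo_rmsep_curve(expr, n_grid=(5, 10, 20, 40, 80), max_components=4)
        best = min(curve, key=curve.get)
        assert planted / 2 <= best <= planted * 2


class TestPrediction:
    def test_missing_signature_probe_is_an_error(self, small_expression):
        expr, _ = small_expression
        model = fit_final_model(expr, n_selected=5, n_components=2)
        pruned = ExpressionMatrix(
            values=expr.values.drop(index=model.selected_probes_[0]),
            phenotype=expr.phenotype,
            tissue_of=expr.tissue_of,
        )
        with pytest.raises(KeyError, match=model.selected_probes_[0]):
            predict_index(model, pruned)

    def test_replicate_averaging_collapses_to_tissues(self, small_expression):
        expr, _ = small_expression
        model = fit_final_model(expr, n_selected=5, n_components=2)
        per_tissue = predict_index(model, expr, average_replicates=True)
        assert set(per_tissue.index) == set(expr.tissue_of.unique())

    def test_json_roundtrip_preserves_predictions(self, tmp_path, small_expression):
        expr, _ = small_expression
        model = fit_final_model(expr, n_selected=8, n_components=2)
        model.to_json(tmp_path / "model.json")
        loaded = SignatureRegressor.from_json(tmp_path / "model.json")
        assert np.array_equal(loaded.predict(expr.X()), model.predict(expr.X()))


class TestEvaluateRmsep:
    def test_identical_vectors_score_zero(self):
        assert evaluate_rmsep([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).rmsep == 0.0

    def test_constant_offset_scores_the_offset(self):
        score = evaluate_rmsep([1.0, 2.0, 3.0], [1.7, 2.7, 3.7])
        assert score.rmsep == pytest.approx(0.7, abs=1e-12)
        assert score.pearson_r == pytest.approx(1.0)

    def test_hand_sized_vectors(self):
        # sqrt((1 + 4 + 1)/3) by hand
        score = evaluate_rmsep([0.0, 2.0, 5.0], [1.0, 4.0, 4.0])
        assert score.rmsep == pytest.approx(np.sqrt(2.0), abs=1e-12)
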