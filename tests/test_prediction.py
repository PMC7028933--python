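"""The boosted-tree learner, the repeated-CV protocol, and the evaluation
statistics (accuracy CI, AUROC, NIR binomial test)."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icbrad import (
    BoostConfig,
    CVConfig,
    GradientBoostedTrees,
    ResponseModel,
    evaluate,
    feature_importance,
    fit_boosted_trees,
    repeated_cv_predict,
    tune,
)
from icbrad.prediction import auroc, clopper_pearson, default_tuning_grid


@pytest.fixture(scope="module")
def noisy_blobs():
    rng = np.random.default_rng(7)
    n = 60
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 5))
    X[:, 0] += 1.5 * y  # informative feature with overlap
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(5)]), y


class TestBoostedTrees:
    def test_separable_1d(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        cfg = BoostConfig(n_iterations=50, max_tree_depth=1, shrinkage=0.5,
                          min_terminal_node_size=1)
        model = fit_boosted_trees(X, y, cfg, seed=0)
        assert (model.predict(X) == y).all()
        proba = model.predict_proba(X)
        assert proba[0] < 0.1 and proba[3] > 0.9

    def test_zero_iterations_gives_prevalence(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1])
        model = fit_boosted_trees(X, y, BoostConfig(n_iterations=0), seed=0)
        assert np.allclose(model.predict_proba(X), 0.4)

    def test_training_loss_non_increasing(self, noisy_blobs):
        X, y = noisy_blobs
        model = fit_boosted_trees(
            X.to_numpy(), y,
            BoostConfig(n_iterations=80, max_tree_depth=2, shrinkage=0.1,
                        min_terminal_node_size=5),
            seed=1,
        )
        diffs = np.diff(model.train_losses_)
        assert np.all(diffs <= 1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_boosted_trees(np.zeros((4, 1)), np.zeros(4), BoostConfig())

    def test_deterministic_given_seed(self, noisy_blobs):
        X, y = noisy_blobs
        cfg = BoostConfig(n_iterations=30)
        p1 = fit_boosted_trees(X.to_numpy(), y, cfg, seed=5).predict_proba(X.to_numpy())
        p2 = fit_boosted_trees(X.to_numpy(), y, cfg, seed=5).predict_proba(X.to_numpy())
        assert (p1 == p2).all()


class TestFeatureImportance:
    def test_informative_feature_ranked_first(self, noisy_blobs):
        X, y = noisy_blobs
        model = fit_boosted_trees(X.to_numpy(), y, BoostConfig(n_iterations=50), 0)
        imp = feature_importance(model, X.columns)
        assert imp.index[0] == "f0"
        assert imp.sum() == pytest.approx(1.0)
        assert (imp >= 0).all()

    def test_unused_features_zero(self):
        X = np.column_stack([np.arange(20.0), np.zeros(20)])
        y = (np.arange(20) >= 10).astype(int)
        model = fit_boosted_trees(X, y, BoostConfig(n_iterations=10,
                                                    min_terminal_node_size=2), 0)
        assert model.feature_importances_[1] == 0.0

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError):
            _ = GradientBoostedTrees().feature_importances_


class TestTune:
    def test_single_point(self, noisy_blobs):
        X, y = noisy_blobs
        cfg = BoostConfig(n_iterations=10)
        assert tune(X, y, [cfg], CVConfig(k=3, repeats=1, seed=0)) is cfg

    def test_dominating_point_wins(self, noisy_blobs):
        X, y = noisy_blobs
        good = BoostConfig(n_iterations=60, max_tree_depth=2,
                           min_terminal_node_size=5)
        useless = BoostConfig(n_iterations=0)
        assert tune(X, y, [useless, good], CVConfig(k=3, repeats=1, seed=0)) is good

    def test_tie_breaks_to_fewer_iterations(self):
        # two configs that are literally identical learners -> tie on
        # accuracy; the smaller iteration count must win
        X = pd.DataFrame({"x": np.arange(20.0)})
        y = (np.arange(20) >= 10).astype(int)
        a = BoostConfig(n_iterations=40, max_tree_depth=1, min_terminal_node_size=2)
        b = BoostConfig(n_iterations=80, max_tree_depth=1, min_terminal_node_size=2)
        assert tune(X, y, [b, a], CVConfig(k=4, repeats=1, seed=0)) is a

    def test_default_grid_shape(self):
        grid = default_tuning_grid()
        assert len(grid) == 18
        assert {c.shrinkage for c in grid} == {0.1}


class TestRepeatedCV:
    def test_each_row_predicted_repeats_times(self, noisy_blobs):
        X, y = noisy_blobs
        preds = repeated_cv_predict(X, y, BoostConfig(n_iterations=10),
                                    CVConfig(k=5, repeats=2, seed=3))
        assert len(preds) == 2 * len(y)
        assert (preds.groupby("row").size() == 2).all()

    def test_leave_one_out_predicts_once(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=12)})
        y = np.array([0, 1] * 6)
        preds = repeated_cv_predict(X, y, BoostConfig(n_iterations=5),
                                    CVConfig(k=12, repeats=1, seed=0))
        assert len(preds) == 12
        assert set(preds["row"]) == set(range(12))

    def test_separable_data_recovered(self):
        rng = np.random.default_rng(1)
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame({"x": y * 10.0 + rng.normal(size=n)})
        preds = repeated_cv_predict(X, y, BoostConfig(n_iterations=30),
                                    CVConfig(seed=2))
        acc = ((preds["proba"] >= 0.5).astype(int) == preds["label"]).mean()
        assert acc >= 0.95

    def test_deterministic(self, noisy_blobs):
        X, y = noisy_blobs
        kw = dict(cfg=BoostConfig(n_iterations=10), cv=CVConfig(seed=9))
        p1 = repeated_cv_predict(X, y, **kw)
        p2 = repeated_cv_predict(X, y, **kw)
        pd.testing.assert_frame_equal(p1, p2)


class TestEvaluate:
    def test_perfect_predictions(self):
        preds = pd.DataFrame({"proba": [0.9, 0.9, 0.1, 0.1, 0.9, 0.1],
                              "label": [1, 1, 0, 0, 1, 0]})
        rep = evaluate(preds)
        assert rep.accuracy == 1.0
        assert rep.auroc == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.ci_high == 1.0

    def test_binomial_p_against_direct_summation(self):
        # 9 of 10 correct against NIR = 0.5
        preds = pd.DataFrame({
            "proba": [0.9] * 5 + [0.1] * 4 + [0.9],
            "label": [1] * 5 + [0] * 5,
        })
        rep = evaluate(preds)
        assert rep.no_information_rate == 0.5
        expected = sum(math.comb(10, k) for k in (9, 10)) / 2 ** 10
        assert rep.binomial_p == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(11 / 1024)

    def test_majority_class_predictor_is_null(self):
        preds = pd.DataFrame({"proba": [0.9] * 10,
                              "label": [1] * 6 + [0] * 4})
        rep = evaluate(preds)
        assert rep.accuracy == rep.no_information_rate == 0.6
        assert rep.binomial_p > 0.4
        assert rep.auroc is None or rep.auroc == 0.5

    def test_summary_mentions_key_metrics(self):
        preds = pd.DataFrame({"proba": [0.9, 0.1], "label": [1, 0]})
        text = evaluate(preds).summary()
        assert "accuracy" in text and "no-information rate" in text


class TestAUROC:
    def test_matches_pairwise_concordance(self):
        rng = np.random.default_rng(11)
        proba = np.round(rng.random(200), 2)  # introduce ties
        labels = rng.integers(0, 2, size=200)
        pos = proba[labels == 1]
        neg = proba[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert auroc(proba, labels) == pytest.approx(expected, rel=1e-12)

    def test_one_class_undefined(self):
        assert auroc(np.array([0.2, 0.8]), np.array([1, 1])) is None


class TestClopperPearson:
    @pytest.mark.parametrize("k,n", [(0, 10), (10, 10), (9, 10), (50, 148)])
    def test_matches_statsmodels_beta(self, k, n):
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = clopper_pearson(k, n)
        slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(slo, abs=1e-9)
        assert hi == pytest.approx(shi, abs=1e-9)

    def test_direct_beta_quantiles(self):
        lo, hi = clopper_pearson(3, 7)
        assert lo == pytest.approx(stats.beta.ppf(0.025, 3, 5), abs=1e-12)
        assert hi == pytest.approx(stats.beta.ppf(0.975, 4, 4), abs=1e-12)


class TestResponseModel:
    def test_cv_report_end_to_end(self, noisy_blobs):
        X, y = noisy_blobs
        model = ResponseModel(X, y, BoostConfig(n_iterations=40))
        rep = model.evaluate_cv(CVConfig(seed=4))
        assert rep.n == 2 * len(y)
        assert 0 <= rep.accuracy <= 1
        assert rep.feature_importances.index[0] == "f0"
        rep2 = ResponseModel(X, y, BoostConfig(n_iterations=40)).evaluate_cv(
            CVConfig(seed=4))
        assert rep.accuracy == rep2.accuracy
        assert rep.binomial_p == rep2.binomial_p

    def test_average_repeats_scores_each_animal_once(self, noisy_blobs):
        X, y = noisy_blobs
        model = ResponseModel(X, y, BoostConfig(n_iterations=20))
        pooled = model.evaluate_cv(CVConfig(seed=6))
        per_animal = model.evaluate_cv(CVConfig(seed=6), average_repeats=True)
        assert pooled.n == 2 * len(y)
        assert per_animal.n == len(y)

    def test_from_dataframe_merges_labels(self, noisy_blobs):
        X, y = noisy_blobs
        feats = X.copy()
        feats.insert(0, "animal_id", [f"a{i}" for i in range(len(X))])
        labels = pd.DataFrame({"animal_id": feats["animal_id"],
                               "responder": y})
        model = ResponseModel.from_dataframe(feats, labels)
        assert (model.y == y).all()
        assert model.X.shape == X.shape
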