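"""Design matrices, Yeo-Johnson transform, nested-CV evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spvscreen.modeling import (
    RECIPES,
    build_design_matrix,
    fit_select_evaluate,
    metrics_from_confusion,
    recipe_spec,
    transform_features,
)
from spvscreen.profiles import ConfigurationError
from spvscreen.stats_tests import mannwhitney_screen


def _inputs(n=20, n_snpsy=5, missing=()):
    rng = np.random.default_rng(0)
    ids = [f"u{i:02d}" for i in range(n)]
    snpsy = pd.DataFrame(
        rng.normal(size=(n, n_snpsy)),
        index=ids,
        columns=[f"s{i}" for i in range(n_snpsy)],
    )
    bow = pd.DataFrame(
        rng.random(size=(n, 4)), index=ids, columns=[f"bow_spv:w{i}" for i in range(4)]
    )
    image = pd.Series(rng.random(n), index=ids, name="image_score")
    for uid in missing:
        image.loc[uid] = np.nan
    bow_feature = pd.Series(rng.random(n), index=ids, name="bow_outputted")
    snpsy_feature = pd.Series(rng.random(n), index=ids, name="snpsy_outputted")
    return ids, snpsy, {"spv": bow}, bow_feature, snpsy_feature, image


class TestDesignMatrices:
    def test_ensemble_has_exactly_three_columns(self):
        ids, snpsy, bows, bf, sf, img = _inputs()
        X = build_design_matrix(
            "images_bow_snpsy_1", snpsy=snpsy, bow_matrices=bows,
            bow_feature=bf, snpsy_feature=sf, image=img, train_index=ids[:14],
        )
        assert X.shape[1] == 3

    def test_images_snpsy_width(self):
        ids, snpsy, bows, bf, sf, img = _inputs(n_snpsy=112)
        X = build_design_matrix(
            "images_snpsy", snpsy=snpsy, image=img, train_index=ids[:14]
        )
        assert X.shape[1] == 113

    def test_missing_images_dropped_only_for_ensemble(self):
        ids, snpsy, bows, bf, sf, img = _inputs(missing=("u01", "u05"))
        X1 = build_design_matrix(
            "images_bow_snpsy_1", snpsy=snpsy, bow_matrices=bows,
            bow_feature=bf, snpsy_feature=sf, image=img, train_index=ids[:14],
        )
        assert X1.shape[0] == 18  # two rows removed
        X2 = build_design_matrix(
            "images_snpsy", snpsy=snpsy, image=img, train_index=ids[:14]
        )
        assert X2.shape[0] == 20 and not X2.isna().any().any()

    def test_missing_images_imputed_with_train_mean(self):
        ids, snpsy, bows, bf, sf, img = _inputs(missing=("u19",))
        train = ids[:10]
        X = build_design_matrix(
            "images_snpsy", snpsy=snpsy, image=img, train_index=train
        )
        assert X.loc["u19", "image_score"] == pytest.approx(img.loc[train].mean())

    def test_selected_recipes_use_screening(self):
        ids, snpsy, bows, bf, sf, img = _inputs(n=30)
        y = np.array([1] * 15 + [0] * 15)
        snpsy.loc[:, "s0"] += 4 * y  # one clearly separated feature
        from spvscreen.modeling import pooled_feature_matrix

        pool = pooled_feature_matrix(snpsy, img, bows, ids)
        sel = mannwhitney_screen(pool, y, alpha=0.05)
        X1 = build_design_matrix(
            "selected_1", snpsy=snpsy, bow_matrices=bows, image=img,
            train_index=ids, selection=sel,
        )
        X2 = build_design_matrix(
            "selected_2", snpsy=snpsy, bow_matrices=bows, image=img,
            train_index=ids, selection=sel,
        )
        assert "s0" in X1.columns and set(X2.columns) <= set(X1.columns)

    def test_missing_inputs_raise_configuration_error(self):
        ids, snpsy, bows, bf, sf, img = _inputs()
        with pytest.raises(ConfigurationError):
            build_design_matrix("bow_snpsy", snpsy=snpsy)  # no bow_feature
        with pytest.raises(ConfigurationError):
            build_design_matrix("nonexistent")

    def test_all_recipes_have_specs(self):
        for r in RECIPES:
            assert recipe_spec(r).recipe_id == r


class TestTransform:
    def test_near_identity_on_standard_normal(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.normal(size=4000)})
        _, Z = transform_features(X)
        assert abs(stats.skew(Z["x"])) < 0.05
        assert np.corrcoef(X["x"], Z["x"])[0, 1] > 0.99

    def test_reduces_lognormal_skew(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.lognormal(0, 1, 3000)})
        _, Z = transform_features(X)
        assert abs(stats.skew(Z["x"])) < 0.3 < stats.skew(X["x"])

    def test_lambda_one_is_affine_identity(self):
        # closed form: for lambda=1 the Yeo-Johnson map is x -> x
        from scipy.stats import yeojohnson

        x = np.linspace(0, 5, 50)
        assert np.allclose(yeojohnson(x, lmbda=1.0), x)

    def test_fit_on_train_rows_only(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.lognormal(0, 1, 200)})
        ft, _ = transform_features(X.iloc[:100], X)
        ft2, _ = transform_features(X.iloc[:100])
        assert np.allclose(ft.lambdas_, ft2.lambdas_)

    def test_column_mismatch_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        ft, _ = transform_features(X)
        with pytest.raises(ValueError):
            ft.transform(X.rename(columns={"a": "b"}))


class TestMetrics:
    def test_hand_computed_confusion(self):
        """TP=22 FN=4 FP=3 TN=23 -> Pr=0.880, R~0.846, F1~0.863, Ac~0.865."""
        m = metrics_from_confusion(tp=22, fn=4, fp=3, tn=23)
        assert m["precision"] == pytest.approx(0.880, abs=5e-4)
        assert m["recall"] == pytest.approx(0.846, abs=5e-4)
        assert m["f1"] == pytest.approx(0.863, abs=5e-4)
        assert m["accuracy"] == pytest.approx(0.865, abs=5e-4)

    def test_degenerate_confusions(self):
        assert metrics_from_confusion(0, 0, 0, 10)["precision"] == 0.0
        assert metrics_from_confusion(10, 0, 0, 0)["accuracy"] == 1.0


class TestFitSelectEvaluate:
    def _task(self, n=120, informative=True, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 6))
        if informative:
            X[:, 0] += 8 * y
        split = int(0.7 * n)
        return (
            pd.DataFrame(X[:split]), y[:split],
            pd.DataFrame(X[split:]), y[split:],
        )

    def test_perfect_separation_gives_all_ones(self):
        Xtr, ytr, Xte, yte = self._task()
        rep = fit_select_evaluate(Xtr, ytr, Xte, yte, algorithms=("logistic",), seed=0)
        assert rep.precision == rep.recall == rep.f1 == rep.accuracy == rep.auc == 1.0
        assert rep.classifier == "logistic"

    def test_null_features_auc_near_half(self):
        aucs = []
        for seed in range(20):
            Xtr, ytr, Xte, yte = self._task(informative=False, seed=seed)
            rep = fit_select_evaluate(
                Xtr, ytr, Xte, yte, algorithms=("logistic",), seed=seed
            )
            aucs.append(rep.auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_small_class_reduces_folds_with_warning(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 4 + [0] * 8)
        X = pd.DataFrame(rng.normal(size=(12, 3)))
        with pytest.warns(UserWarning, match="reducing folds"):
            fit_select_evaluate(X, y, X, y, algorithms=("logistic",), seed=0)

    def test_family_selection_reports_all_candidates(self):
        Xtr, ytr, Xte, yte = self._task(n=60)
        rep = fit_select_evaluate(
            Xtr, ytr, Xte, yte, algorithms=("logistic", "svm"), seed=0
        )
        assert set(rep.family_cv_auc) == {"logistic", "svm"}
        assert rep.classifier in ("logistic", "svm")
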