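"""Feature-combination recipes, normalizing transform, and nested-CV evaluation.

Ten model recipes combine the three feature families (user-level BoW n-grams,
SNPSY, the image user score): the text baselines on the full profile and the
SPV, SNPSY alone, pairwise combinations through the *outputted feature*
mechanism, a three-column ensemble, and two feature-selected models screened
by Mann-Whitney P values at alpha = .05 / .001.

Evaluation follows a nested protocol on a stratified 70/30 split: features
are Yeo-Johnson power-transformed (fit on training rows only), the classifier
family (random forest, MLP, logistic, SVM) is chosen by mean 10-fold
cross-validated AUC on the training set, its hyperparameters by a 5-fold
grid search on AUC, and the final fit is reported on the held-out test set
with precision, recall, F1 and AUC referring to the positive (risk) class.
Stochastic learners are averaged over multiple seeded runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import PowerTransformer
from sklearn.svm import SVC

from .profiles import ConfigurationError
from .stats_tests import SelectionResult, mannwhitney_screen

#: Table-4-style recipe registry, in report order.
RECIPES: tuple[str, ...] = (
    "bow_full",
    "bow_spv",
    "snpsy",
    "bow_snpsy",
    "images_bow",
    "images_snpsy",
    "images_bow_snpsy_1",
    "images_bow_snpsy_2",
    "selected_1",
    "selected_2",
)

RECIPE_LABELS: dict[str, str] = {
    "bow_full": "BoW model - full profile (baseline 1)",
    "bow_spv": "BoW model - SPV (baseline 3)",
    "snpsy": "SNPSY model",
    "bow_snpsy": "BoW+SNPSY model",
    "images_bow": "Images+BoW model",
    "images_snpsy": "Images+SNPSY model",
    "images_bow_snpsy_1": "Images+BoW+SNPSY model 1",
    "images_bow_snpsy_2": "Images+BoW+SNPSY model 2",
    "selected_1": "Selected features model 1 (P<.05)",
    "selected_2": "Selected features model 2 (P<.001)",
}


@dataclass
class ModelRecipe:
    """Column recipe for one combination model."""

    recipe_id: str
    snpsy: bool = False
    bow_variant: str | None = None  # "full_profile" | "spv" -> raw BoW columns
    bow_feature: bool = False  # out-of-fold BoW probability column
    snpsy_feature: bool = False  # out-of-fold SNPSY probability column
    image: bool = False
    image_missing: str = "impute"  # "impute" (train mean) | "drop"
    selection_alpha: float | None = None  # screen the pooled feature space


def recipe_spec(recipe_id: str) -> ModelRecipe:
    specs = {
        "bow_full": ModelRecipe("bow_full", bow_variant="full_profile"),
        "bow_spv": ModelRecipe("bow_spv", bow_variant="spv"),
        "snpsy": ModelRecipe("snpsy", snpsy=True),
        "bow_snpsy": ModelRecipe("bow_snpsy", snpsy=True, bow_feature=True),
        "images_bow": ModelRecipe("images_bow", bow_variant="spv", image=True),
        "images_snpsy": ModelRecipe("images_snpsy", snpsy=True, image=True),
        "images_bow_snpsy_1": ModelRecipe(
            "images_bow_snpsy_1",
            bow_feature=True,
            snpsy_feature=True,
            image=True,
            image_missing="drop",
        ),
        "images_bow_snpsy_2": ModelRecipe(
            "images_bow_snpsy_2", snpsy=True, bow_feature=True, image=True
        ),
        "selected_1": ModelRecipe("selected_1", selection_alpha=0.05),
        "selected_2": ModelRecipe("selected_2", selection_alpha=0.001),
    }
    if recipe_id not in specs:
        raise ConfigurationError(f"unknown recipe {recipe_id!r}")
    return specs[recipe_id]


def build_design_matrix(
    recipe: str | ModelRecipe,
    snpsy: pd.DataFrame | None = None,
    bow_matrices: Mapping[str, pd.DataFrame] | None = None,
    bow_feature: pd.Series | None = None,
    snpsy_feature: pd.Series | None = None,
    image: pd.Series | None = None,
    train_index: Sequence | None = None,
    selection: SelectionResult | None = None,
) -> pd.DataFrame:
    """Assemble the user x feature matrix for one recipe.

    Inputs are pandas objects aligned on user id.  Missing image scores are
    imputed by the training-row mean, except for the three-column ensemble
    where rows with missing values are removed.  Selected-feature recipes
    require a precomputed :class:`SelectionResult` over the pooled feature
    space (SNPSY + image + SPV BoW columns).
    """
    spec = recipe_spec(recipe) if isinstance(recipe, str) else recipe

    if spec.selection_alpha is not None:
        if selection is None or snpsy is None or image is None:
            raise ConfigurationError(
                f"recipe {spec.recipe_id!r} needs snpsy, image and a SelectionResult"
            )
        pool = pooled_feature_matrix(snpsy, image, bow_matrices, train_index)
        chosen = selection.at_alpha(spec.selection_alpha).selected
        if not chosen:
            # degenerate small-sample case: keep the single best-P feature so
            # the recipe still yields a model
            chosen = [selection.table["p"].idxmin()]
            warnings.warn(
                f"no feature passed alpha={spec.selection_alpha}; "
                f"falling back to the top-ranked feature {chosen[0]!r}",
                stacklevel=2,
            )
        return pool[chosen]

    blocks: list[pd.DataFrame] = []
    if spec.image:
        if image is None:
            raise ConfigurationError(f"recipe {spec.recipe_id!r} needs image scores")
        img = _handle_missing_image(image, spec.image_missing, train_index)
        blocks.append(img.to_frame())
    if spec.bow_feature:
        if bow_feature is None:
            raise ConfigurationError(f"recipe {spec.recipe_id!r} needs bow_feature")
        blocks.append(bow_feature.rename("bow_outputted").to_frame())
    if spec.snpsy_feature:
        if snpsy_feature is None:
            raise ConfigurationError(f"recipe {spec.recipe_id!r} needs snpsy_feature")
        blocks.append(snpsy_feature.rename("snpsy_outputted").to_frame())
    if spec.snpsy:
        if snpsy is None:
            raise ConfigurationError(f"recipe {spec.recipe_id!r} needs snpsy table")
        blocks.append(snpsy)
    if spec.bow_variant is not None:
        if not bow_matrices or spec.bow_variant not in bow_matrices:
            raise ConfigurationError(
                f"recipe {spec.recipe_id!r} needs BoW matrix {spec.bow_variant!r}"
            )
        blocks.append(bow_matrices[spec.bow_variant])
    if not blocks:
        raise ConfigurationError(f"recipe {spec.recipe_id!r} selects no columns")

    X = pd.concat(blocks, axis=1, join="inner")
    if spec.image and spec.image_missing == "drop":
        X = X.dropna(axis=0)
    return X


def pooled_feature_matrix(
    snpsy: pd.DataFrame,
    image: pd.Series,
    bow_matrices: Mapping[str, pd.DataFrame] | None,
    train_index: Sequence | None,
) -> pd.DataFrame:
    """SNPSY + image + SPV BoW columns: the screening pool for selection."""
    blocks = [snpsy, _handle_missing_image(image, "impute", train_index).to_frame()]
    if bow_matrices and "spv" in bow_matrices:
        blocks.append(bow_matrices["spv"])
    return pd.concat(blocks, axis=1, join="inner")


def _handle_missing_image(
    image: pd.Series, policy: str, train_index: Sequence | None
) -> pd.Series:
    if policy == "drop":
        return image
    fill_rows = image.loc[train_index] if train_index is not None else image
    mean = fill_rows.mean()
    return image.fillna(0.0 if np.isnan(mean) else mean)


class FeatureTransform:
    """Per-column Yeo-Johnson power transform with standardization.

    Fit on training rows only, applied to all rows; the fitted lambdas are
    exposed for persistence/auditing.
    """

    def __init__(self) -> None:
        self._pt = PowerTransformer(method="yeo-johnson", standardize=True)
        self.columns_: list[str] | None = None

    def fit(self, X: pd.DataFrame) -> "FeatureTransform":
        self.columns_ = list(X.columns)
        self._pt.fit(X.to_numpy(dtype=float))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if list(X.columns) != self.columns_:
            raise ValueError("column mismatch between fit and transform")
        Z = self._pt.transform(X.to_numpy(dtype=float))
        return pd.DataFrame(Z, index=X.index, columns=self.columns_)

    @property
    def lambdas_(self) -> np.ndarray:
        return self._pt.lambdas_


def transform_features(
    X_train: pd.DataFrame, X_all: pd.DataFrame | None = None
) -> tuple[FeatureTransform, pd.DataFrame]:
    """Fit the Yeo-Johnson transform on training rows; apply to ``X_all``."""
    ft = FeatureTransform().fit(X_train)
    return ft, ft.transform(X_all if X_all is not None else X_train)


# -- classifiers ------------------------------------------------------------------

STOCHASTIC_FAMILIES = {"random_forest", "mlp"}
DEFAULT_ALGORITHMS = ("random_forest", "mlp", "logistic", "svm")


def _family_estimator(family: str, seed: int):
    if family == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if family == "svm":
        return SVC(probability=True, random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if family == "mlp":
        return MLPClassifier(hidden_layer_sizes=(16,), max_iter=100, random_state=seed)
    raise ConfigurationError(f"unknown classifier family {family!r}")


#: default hyperparameter grids (the study reports a grid search without
#: publishing the grid; these are conventional small grids).
DEFAULT_GRIDS: dict[str, dict] = {
    "logistic": {"C": [0.1, 1.0, 10.0]},
    "svm": {"C": [0.1, 1.0, 10.0], "kernel": ["rbf", "linear"]},
    "random_forest": {"max_depth": [None, 8], "max_features": ["sqrt"]},
    "mlp": {"alpha": [1e-4, 1e-2]},
}


@dataclass
class EvalReport:
    """Held-out metrics for the positive (risk) class plus model identity."""

    precision: float
    recall: float
    f1: float
    accuracy: float
    auc: float
    classifier: str
    best_params: dict = field(default_factory=dict)
    family_cv_auc: dict = field(default_factory=dict)
    n_train: int = 0
    n_test: int = 0
    model: object = None  # final fitted estimator (not serialized in tables)
    test_scores: np.ndarray | None = None
    test_ids: list = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "Pr": self.precision,
                "R": self.recall,
                "F1": self.f1,
                "Ac": self.accuracy,
                "AUC": self.auc,
                "Classifier": self.classifier,
            }
        )


def evaluate_scores(y_true, y_pred, y_score) -> dict[str, float]:
    pr, rc, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, pos_label=1, average="binary", zero_division=0
    )
    return {
        "precision": float(pr),
        "recall": float(rc),
        "f1": float(f1),
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "auc": float(roc_auc_score(y_true, y_score)),
    }


def metrics_from_confusion(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    """Pr/R/F1/accuracy from a confusion matrix (positive class)."""
    pr = tp / (tp + fp) if tp + fp else 0.0
    rc = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
    ac = (tp + tn) / (tp + fn + fp + tn)
    return {"precision": pr, "recall": rc, "f1": f1, "accuracy": ac}


def _safe_folds(requested: int, y: np.ndarray) -> int:
    counts = np.bincount(np.asarray(y).astype(int))
    feasible = int(counts[counts > 0].min())
    if feasible < requested:
        warnings.warn(
            f"reducing folds from {requested} to {feasible} (small class)",
            stacklevel=2,
        )
    return max(2, min(requested, feasible))


def fit_select_evaluate(
    X_train,
    y_train,
    X_test,
    y_test,
    algorithms: Sequence[str] = DEFAULT_ALGORITHMS,
    seed: int = 0,
    n_family_folds: int = 10,
    n_grid_folds: int = 5,
    n_runs: int = 3,
    grids: Mapping[str, dict] | None = None,
) -> EvalReport:
    """Choose a classifier family by 10-fold CV AUC, tune it by 5-fold grid
    search, fit on the full training set and report on the held-out test set."""
    Xtr = X_train.to_numpy(dtype=float) if isinstance(X_train, pd.DataFrame) else np.asarray(X_train, dtype=float)
    Xte = X_test.to_numpy(dtype=float) if isinstance(X_test, pd.DataFrame) else np.asarray(X_test, dtype=float)
    ytr = np.asarray(y_train).astype(int)
    yte = np.asarray(y_test).astype(int)
    grids = dict(grids) if grids is not None else DEFAULT_GRIDS

    family_folds = _safe_folds(n_family_folds, ytr)
    cv = StratifiedKFold(n_splits=family_folds, shuffle=True, random_state=seed)
    family_auc: dict[str, float] = {}
    for family in algorithms:
        est = _family_estimator(family, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = cross_val_score(est, Xtr, ytr, cv=cv, scoring="roc_auc")
        family_auc[family] = float(np.mean(scores))
    best_family = max(family_auc, key=family_auc.get)

    grid_folds = _safe_folds(n_grid_folds, ytr)
    grid_cv = StratifiedKFold(n_splits=grid_folds, shuffle=True, random_state=seed + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search = GridSearchCV(
            _family_estimator(best_family, seed),
            grids.get(best_family, {}),
            cv=grid_cv,
            scoring="roc_auc",
        ).fit(Xtr, ytr)
    best_params = dict(search.best_params_)

    run_seeds = (
        [seed + 10 * r for r in range(n_runs)]
        if best_family in STOCHASTIC_FAMILIES
        else [seed]
    )
    metric_runs = []
    final_model = None
    final_scores = None
    for rs in run_seeds:
        est = clone(_family_estimator(best_family, rs)).set_params(**best_params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xtr, ytr)
        pos = list(est.classes_).index(1)
        y_score = est.predict_proba(Xte)[:, pos]
        y_pred = est.predict(Xte)
        metric_runs.append(evaluate_scores(yte, y_pred, y_score))
        final_model, final_scores = est, y_score

    avg = {k: float(np.mean([m[k] for m in metric_runs])) for k in metric_runs[0]}
    return EvalReport(
        precision=avg["precision"],
        recall=avg["recall"],
        f1=avg["f1"],
        accuracy=avg["accuracy"],
        auc=avg["auc"],
        classifier=best_family,
        best_params=best_params,
        family_cv_auc=family_auc,
        n_train=len(ytr),
        n_test=len(yte),
        model=final_model,
        test_scores=final_scores,
    )


__all__ = [
    "RECIPES",
    "RECIPE_LABELS",
    "ModelRecipe",
    "recipe_spec",
    "build_design_matrix",
    "pooled_feature_matrix",
    "FeatureTransform",
    "transform_features",
    "fit_select_evaluate",
    "EvalReport",
    "evaluate_scores",
    "metrics_from_confusion",
    "mannwhitney_screen",
    "DEFAULT_GRIDS",
    "DEFAULT_ALGORITHMS",
]
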