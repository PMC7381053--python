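"""Statistical screening and comparison utilities.

* Mann-Whitney U feature screening (two-sided; exact distribution for small
  tie-free samples, tie-corrected normal approximation otherwise).
* Overlapping index (OVL): the integral of the pointwise minimum of two
  estimated densities — 1 for identical, 0 for disjoint distributions.
* DeLong's nonparametric test for the difference of two correlated ROC AUCs.
* Feature rankings by random-forest impurity decrease or point-biserial
  correlation with the class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

EXACT_MAX_COMBINED_N = 20


@dataclass
class SelectionResult:
    """Per-feature U statistics and P values with the selected set at alpha."""

    table: pd.DataFrame  # index: feature, columns: U, p, selected
    alpha: float

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def at_alpha(self, alpha: float) -> "SelectionResult":
        """Re-threshold the same P values at a different alpha (nested sets)."""
        table = self.table.copy()
        table["selected"] = table["p"] < alpha
        return SelectionResult(table=table, alpha=alpha)


def _mannwhitney_single(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return float(len(a) * len(b) / 2.0), 1.0
    pooled = np.concatenate([a, b])
    exact = (
        len(pooled) <= EXACT_MAX_COMBINED_N
        and np.unique(pooled).size == pooled.size
    )
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def mannwhitney_screen(
    X, y, alpha: float = 0.05, feature_names: list[str] | None = None
) -> SelectionResult:
    """Two-sided Mann-Whitney U test per feature; selected = {P < alpha}.

    ``y`` is binary (1 = positive class).  Small tie-free features use the
    exact null distribution; everything else the tie-corrected normal
    approximation.  Constant features get P = 1 (never selected).
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    mask_pos = y == 1
    if mask_pos.sum() < 3 or (~mask_pos).sum() < 3:
        raise ValueError("need at least 3 observations per class")
    A, B = X[mask_pos], X[~mask_pos]

    if A.shape[0] + B.shape[0] <= EXACT_MAX_COMBINED_N:
        stats_p = [_mannwhitney_single(A[:, j], B[:, j]) for j in range(X.shape[1])]
        U = np.array([s for s, _ in stats_p])
        p = np.array([q for _, q in stats_p])
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(
                A, B, alternative="two-sided", method="asymptotic", axis=0
            )
        U = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        constant = np.nanstd(X, axis=0) == 0
        p = np.where(np.isnan(p) | constant, 1.0, p)

    table = pd.DataFrame({"U": U, "p": p}, index=pd.Index(names, name="feature"))
    table["selected"] = table["p"] < alpha
    return SelectionResult(table=table, alpha=alpha)


def overlap_index(sample_a, sample_b, grid_size: int = 512) -> float:
    """Overlapping coefficient of two empirical densities.

    Gaussian KDE with Silverman bandwidth on a shared grid spanning the
    pooled range padded by three bandwidths; the pointwise minimum is
    integrated by the trapezoidal rule.  Zero-variance samples fall back to
    a shared-bin histogram estimate (logged).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.std(a) == 0 and np.std(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    if np.std(a) == 0 or np.std(b) == 0:
        logger.warning("zero-variance sample; overlap_index histogram fallback")
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        pad = 1e-9 + 0.05 * (hi - lo)
        edges = np.linspace(lo - pad, hi + pad, 65)
        pa, _ = np.histogram(a, bins=edges, density=False)
        pb, _ = np.histogram(b, bins=edges, density=False)
        return float(np.minimum(pa / a.size, pb / b.size).sum())

    kde_a = stats.gaussian_kde(a, bw_method="silverman")
    kde_b = stats.gaussian_kde(b, bw_method="silverman")
    bw = max(kde_a.factor * np.std(a), kde_b.factor * np.std(b))
    lo = min(a.min(), b.min()) - 3 * bw
    hi = max(a.max(), b.max()) + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    overlap = np.minimum(kde_a(grid), kde_b(grid))
    return float(np.clip(np.trapezoid(overlap, grid), 0.0, 1.0))


# -- DeLong test ------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """DeLong test for two correlated AUCs on paired scores.

    Returns ``(auc_a, auc_b, two-sided P)``.  Labels must contain both
    classes; score vectors must be paired on identical instances.
    """
    y = np.asarray(labels).astype(int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != y.shape or b.shape != y.shape:
        raise ValueError("scores and labels must have identical shape")
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if np.isclose(diff, 0.0) else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


def rank_features(
    X=None,
    y=None,
    mode: str = "impurity",
    model: RandomForestClassifier | None = None,
    feature_names: list[str] | None = None,
    seed: int = 0,
    n_estimators: int = 300,
) -> pd.DataFrame:
    """Rank features by impurity decrease or point-biserial class correlation.

    ``impurity`` averages each feature's impurity decrease across the trees
    of a random forest (a fitted model may be passed, otherwise one is fit);
    ``class_correlation`` uses |point-biserial r| with the binary label.
    Returns a DataFrame (feature, score) in descending score order.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy()
    if mode == "impurity":
        if model is None:
            if X is None or y is None:
                raise ValueError("impurity mode needs a fitted model or X, y")
            model = RandomForestClassifier(
                n_estimators=n_estimators, random_state=seed
            ).fit(X, y)
        scores = np.asarray(model.feature_importances_)
    elif mode == "class_correlation":
        if X is None or y is None:
            raise ValueError("class_correlation mode needs X and y")
        y = np.asarray(y, dtype=float)
        Xa = np.asarray(X, dtype=float)
        scores = np.zeros(Xa.shape[1])
        for j in range(Xa.shape[1]):
            col = Xa[:, j]
            if np.std(col) == 0 or np.std(y) == 0:
                scores[j] = 0.0
            else:
                scores[j] = abs(stats.pointbiserialr(y, col).statistic)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    names = feature_names or [f"f{i}" for i in range(scores.size)]
    out = pd.DataFrame({"feature": names, "score": scores})
    return out.sort_values("score", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
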