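"""Short-profile-version classifier (SPVC) and SPV construction.

The SPVC is a post-level binary classifier — word 1-5-gram tf-idf,
truncated-SVD dimensionality reduction, logistic scoring — trained on a
labeled corpus of suicide-related vs control posts.  Applied to a user's
full post stream, it retains at most the top-``k`` posts whose predicted
probability strictly exceeds the decision threshold (default 0.5); this
retained subset is the user's *short profile version* (SPV).  Users whose
posts all score at or below the threshold are carried forward with
``has_spv = False`` rather than dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.decomposition import TruncatedSVD
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .profiles import Post, UserProfile

POSITIVE_LABEL = "suicide_related"


class SpvcTrainingError(ValueError):
    """Raised for untrainable corpora (single class, too few posts)."""


class _Svd95(BaseEstimator, TransformerMixin):
    """Truncated SVD keeping components up to 95% explained variance.

    The component count is additionally capped (default 128) and by
    ``n_samples - 1``; SVD components are variance-ordered, so the cut is a
    column slice of a single decomposition.
    """

    def __init__(self, cap: int = 128, var_target: float = 0.95, random_state: int = 0):
        self.cap = cap
        self.var_target = var_target
        self.random_state = random_state

    def fit(self, X, y=None):
        m = int(min(self.cap, X.shape[0] - 1, X.shape[1] - 1))
        m = max(m, 1)
        self.svd_ = TruncatedSVD(n_components=m, random_state=self.random_state)
        self.svd_.fit(X)
        cum = np.cumsum(self.svd_.explained_variance_ratio_)
        hit = np.flatnonzero(cum >= self.var_target)
        self.n_components_ = int(hit[0] + 1) if hit.size else m
        return self

    def transform(self, X):
        return self.svd_.transform(X)[:, : self.n_components_]


def _build_pipeline(ngram_range: tuple[int, int], svd_cap: int, seed: int) -> Pipeline:
    return Pipeline(
        [
            (
                "tfidf",
                TfidfVectorizer(
                    lowercase=True,
                    token_pattern=r"(?u)\b\w+\b",
                    ngram_range=ngram_range,
                ),
            ),
            ("svd", _Svd95(cap=svd_cap, random_state=seed)),
            ("scale", StandardScaler()),
            ("lr", LogisticRegression(max_iter=2000, random_state=seed)),
        ]
    )


@dataclass
class SpvcModel:
    """Fitted SPVC: immutable after fit; scores posts in [0, 1]."""

    pipeline: Pipeline
    threshold: float = 0.5
    ngram_range: tuple[int, int] = (1, 5)
    seed: int = 0
    cv_report: dict = field(default_factory=dict)

    def score_posts(self, posts: Sequence[Post]) -> np.ndarray:
        if not posts:
            return np.empty(0)
        docs = [p.raw_text for p in posts]
        proba = self.pipeline.predict_proba(docs)
        pos_col = list(self.pipeline.classes_).index(POSITIVE_LABEL)
        return proba[:, pos_col]

    def score_post(self, post: Post) -> float:
        return float(self.score_posts([post])[0])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, path)
        sidecar = {
            "threshold": self.threshold,
            "ngram_range": list(self.ngram_range),
            "seed": self.seed,
            "cv_report": self.cv_report,
            "format_version": 1,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "SpvcModel":
        return joblib.load(path)


def train_spvc(
    corpus: Sequence[tuple[Post, str]],
    ngram_range: tuple[int, int] = (1, 5),
    threshold: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    svd_cap: int = 128,
    min_per_class: int = 20,
) -> SpvcModel:
    """Fit the SPVC and report stratified cross-validated Pr/R/F1.

    Raises :class:`SpvcTrainingError` if the corpus does not contain both
    classes with at least ``min_per_class`` posts each.
    """
    docs = [p.raw_text for p, _ in corpus]
    y = np.array([label for _, label in corpus])
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise SpvcTrainingError(f"corpus has a single class: {classes.tolist()}")
    if counts.min() < min_per_class:
        raise SpvcTrainingError(
            f"need >= {min_per_class} posts per class, got {dict(zip(classes, counts))}"
        )

    pipeline = _build_pipeline(ngram_range, svd_cap, seed)
    folds = min(n_folds, int(counts.min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    proba = cross_val_predict(clone(pipeline), docs, y, cv=cv, method="predict_proba")
    pos_col = int(np.argmax(classes == POSITIVE_LABEL))
    y_pred = np.where(proba[:, pos_col] > 0.5, POSITIVE_LABEL, classes[1 - pos_col])
    pr, rc, f1, _ = precision_recall_fscore_support(
        y, y_pred, pos_label=POSITIVE_LABEL, average="binary", zero_division=0
    )
    auc = roc_auc_score((y == POSITIVE_LABEL).astype(int), proba[:, pos_col])
    pipeline.fit(docs, y)
    model = SpvcModel(
        pipeline=pipeline,
        threshold=threshold,
        ngram_range=ngram_range,
        seed=seed,
        cv_report={
            "precision": float(pr),
            "recall": float(rc),
            "f1": float(f1),
            "auc": float(auc),
            "n_folds": folds,
        },
    )
    return model


@dataclass
class SpvResult:
    """Retained posts of one user, sorted by descending SPVC score."""

    user_id: str
    retained: list[tuple[Post, float]]
    has_spv: bool
    n_spv: int

    @property
    def posts(self) -> list[Post]:
        return [p for p, _ in self.retained]

    @property
    def scores(self) -> list[float]:
        return [s for _, s in self.retained]

    def to_dict(self) -> dict:
        return {
            "user_id": self.user_id,
            "has_spv": self.has_spv,
            "n_spv": self.n_spv,
            "retained": [
                {"post_id": p.post_id, "score": round(float(s), 6)}
                for p, s in self.retained
            ],
        }


def build_spv(
    model: SpvcModel,
    profile: UserProfile,
    k: int = 15,
    threshold: float | None = None,
    scores: np.ndarray | None = None,
) -> SpvResult:
    """Select at most the ``k`` highest-scoring posts strictly above threshold.

    Ties on score are broken by recency (more recent first), then post id.
    ``scores`` may be supplied to reuse a precomputed score vector (it must
    align with ``profile.posts``).
    """
    thr = model.threshold if threshold is None else threshold
    if scores is None:
        scores = model.score_posts(profile.posts)
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(profile.posts):
        raise ValueError("scores must align with profile.posts")
    keep = np.flatnonzero(scores > thr)
    ranked = sorted(
        keep.tolist(),
        key=lambda i: (
            -scores[i],
            -profile.posts[i].created_at.timestamp(),
            profile.posts[i].post_id,
        ),
    )[:k]
    retained = [(profile.posts[i], float(scores[i])) for i in ranked]
    return SpvResult(
        user_id=profile.user_id,
        retained=retained,
        has_spv=bool(retained),
        n_spv=len(retained),
    )


def build_spvs(
    model: SpvcModel,
    profiles: Sequence[UserProfile],
    k: int = 15,
    threshold: float | None = None,
) -> dict[str, SpvResult]:
    """Batch SPV construction; scores each user's posts in one pass."""
    out: dict[str, SpvResult] = {}
    for profile in profiles:
        out[profile.user_id] = build_spv(model, profile, k=k, threshold=threshold)
    return out


def write_spvs_jsonl(spvs: dict[str, SpvResult], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for user_id in sorted(spvs):
            fh.write(json.dumps(spvs[user_id].to_dict(), sort_keys=True) + "\n")
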