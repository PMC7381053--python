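"""User-level n-gram text models and the out-of-fold "outputted feature".

Each user is represented by one document: the concatenation of the
preprocessed text of their posts, either the full profile or the SPV subset.
Documents are vectorized as tf-idf over word 1-5-grams with a document
frequency floor (n-grams seen in fewer than ``df_floor`` of documents are
dropped — misspellings and elongations rarely repeat across users).

The *outputted feature* reduces the whole n-gram matrix to a single
probability column for downstream combination models.  For training users
the probability comes from a classifier fit on folds that exclude the user
(out-of-fold stacking, which avoids the leakage of predicting a user with a
model that saw it); for test users it comes from a model fit on the full
training set.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.base import clone
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .profiles import UserProfile
from .spvc import SpvResult

_EMOTICON_RE = re.compile(
    r"[\U0001F000-\U0001FAFF☀-➿←-⇿️]"
    r"|(?<!\w)(?:[:;=x8][\'\-o\^]?[)(\]\[dpo3*/\\|]+)(?!\w)",
    re.IGNORECASE,
)
_MONEY_RE = re.compile(r"(?:[$€£]\s?\d+(?:[.,]\d+)?|\d+(?:[.,]\d+)?\s?[$€£])")
_PHONE_RE = re.compile(r"(?<!\d)\+?\d[\d\s\-]{6,}\d(?!\d)")
_HASHTAG_RE = re.compile(r"#\w+")
_DIGIT_RE = re.compile(r"\d+(?:[.,]\d+)?")
_TOKEN_RE = re.compile(r"<\w+>|[^\W\d_]+")


def preprocess_text(raw: str) -> list[str]:
    """Lowercased tokens with money / phone / digit / hashtag / emoticon
    spans replaced by placeholder tokens; deterministic."""
    text = _EMOTICON_RE.sub(" <emoticon> ", raw)
    text = _MONEY_RE.sub(" <money> ", text)
    text = _PHONE_RE.sub(" <phone> ", text)
    text = _HASHTAG_RE.sub(" <hashtag> ", text)
    text = _DIGIT_RE.sub(" <digit> ", text)
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class UserDocument:
    """One user's concatenated (preprocessed) text, full-profile or SPV."""

    user_id: str
    text: str
    variant: str  # "full_profile" | "spv"


def build_user_documents(
    profiles: Sequence[UserProfile],
    spvs: dict[str, SpvResult] | None = None,
    variant: str = "full_profile",
    max_tokens: int | None = 2000,
) -> list[UserDocument]:
    """Concatenate post texts per user; SPV variant uses retained posts only.

    ``max_tokens`` caps the concatenated document length (long full profiles
    otherwise blow up the 4/5-gram vocabulary); ``None`` disables the cap.
    Empty documents are allowed only for users without an SPV.
    """
    if variant not in ("full_profile", "spv"):
        raise ValueError(f"unknown variant {variant!r}")
    docs = []
    for profile in profiles:
        if variant == "spv":
            if spvs is None:
                raise ValueError("spv variant requires spvs")
            posts = spvs[profile.user_id].posts
        else:
            posts = profile.posts
        tokens: list[str] = []
        for p in posts:
            tokens.extend(preprocess_text(p.raw_text))
            if max_tokens is not None and len(tokens) >= max_tokens:
                tokens = tokens[:max_tokens]
                break
        docs.append(UserDocument(profile.user_id, " ".join(tokens), variant))
    return docs


class BowFitError(ValueError):
    """Vectorization failed (e.g. empty vocabulary after filtering)."""


def _identity(x):  # module-level for picklability
    return x


@dataclass
class BowModel:
    """Fitted user-level tf-idf n-gram vectorizer plus its manifest."""

    vectorizer: TfidfVectorizer
    manifest: dict = field(default_factory=dict)

    @property
    def vocabulary_size(self) -> int:
        return len(self.vectorizer.vocabulary_)

    def transform(self, documents: Sequence[UserDocument]) -> sp.csr_matrix:
        return self.vectorizer.transform([d.text for d in documents])

    @property
    def feature_names(self) -> list[str]:
        return list(self.vectorizer.get_feature_names_out())

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, path)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True)
        )

    @classmethod
    def load(cls, path: str | Path) -> "BowModel":
        return joblib.load(path)


def fit_user_bow(
    documents: Sequence[UserDocument],
    ngram_range: tuple[int, int] = (1, 5),
    df_floor: float = 0.05,
    stopwords: Sequence[str] | None = None,
    sublinear_tf: bool = False,
) -> tuple[BowModel, sp.csr_matrix]:
    """Fit tf-idf over word n-grams with a raw document-frequency floor.

    An n-gram is retained iff its document frequency is at least
    ``ceil(df_floor * n_documents)`` (the floor applies to raw counts,
    before weighting).  Raises :class:`BowFitError` when nothing survives.
    """
    if len(documents) < 2:
        raise BowFitError("need at least 2 documents")
    n = len(documents)
    min_df = max(1, int(np.ceil(df_floor * n)))
    stop = list(stopwords) if stopwords else None
    vectorizer = TfidfVectorizer(
        lowercase=False,
        tokenizer=str.split,
        preprocessor=_identity,
        token_pattern=None,
        ngram_range=ngram_range,
        min_df=min_df,
        stop_words=stop,
        sublinear_tf=sublinear_tf,
        norm="l2",
    )
    try:
        X = vectorizer.fit_transform([d.text for d in documents])
    except ValueError as exc:
        raise BowFitError(
            f"empty vocabulary after filtering (n={n}, min_df={min_df}, "
            f"ngram_range={ngram_range}): {exc}"
        ) from exc
    stop_hash = hashlib.sha256(
        "\n".join(sorted(stop or [])).encode()
    ).hexdigest()[:16]
    model = BowModel(
        vectorizer=vectorizer,
        manifest={
            "ngram_range": list(ngram_range),
            "df_floor": df_floor,
            "min_df": min_df,
            "n_documents": n,
            "vocabulary_size": len(vectorizer.vocabulary_),
            "stopword_list_sha256_16": stop_hash,
            "sublinear_tf": sublinear_tf,
            "tfidf_norm": "l2",
            "variant": documents[0].variant,
        },
    )
    return model, X


@dataclass
class OutputtedFeature:
    """Out-of-fold probabilities for train users, full-fit for test users."""

    train: np.ndarray
    test: np.ndarray | None
    folds: np.ndarray  # fold id per training user

    def __post_init__(self) -> None:
        assert np.all((self.train >= 0) & (self.train <= 1))


def bow_outputted_feature(
    X_train,
    y_train,
    X_test=None,
    n_folds: int = 10,
    seed: int = 0,
    estimator=None,
) -> OutputtedFeature:
    """Cross-validated predicted probability of the positive class.

    Training rows are scored by a classifier fit on the folds that exclude
    them (stratified, seeded); test rows by a classifier fit on the whole
    training set.  The per-fold classifier defaults to L2 logistic
    regression.
    """
    y = np.asarray(y_train)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outputted feature requires both classes in y_train")
    counts = np.array([(y == c).sum() for c in classes])
    folds = int(min(n_folds, counts.min()))
    if folds < 2:
        raise ValueError("need at least 2 members per class for folding")
    base = estimator if estimator is not None else LogisticRegression(
        max_iter=2000, random_state=seed
    )

    oof = np.empty(len(y))
    fold_ids = np.empty(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        est = clone(base)
        est.fit(X_train[tr], y[tr])
        pos = list(est.classes_).index(1) if 1 in est.classes_ else 1
        oof[te] = est.predict_proba(X_train[te])[:, pos]
        fold_ids[te] = fold

    test_probs = None
    if X_test is not None:
        est = clone(base)
        est.fit(X_train, y)
        pos = list(est.classes_).index(1) if 1 in est.classes_ else 1
        test_probs = est.predict_proba(X_test)[:, pos]
    return OutputtedFeature(train=oof, test=test_probs, folds=fold_ids)
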