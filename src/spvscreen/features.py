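"""SNPSY feature bank: behavioral, tweet-statistic, relational, lexicon and
sentiment features per user.

The behavioral core is the circadian pair of ratios STTR/DTTR (sleep-time /
daytime tweets ratio).  The day is divided into 8 fixed 3-hour UTC slots;
the post count ``t[i]`` of each slot is computed over the user's full
in-window profile, the minimum over the 8 *circular* adjacent slot-pair sums
is taken (first and last slots are adjacent), and that minimum is normalized
by the user's in-window post total ``T``:

    STTR = min_i (t[i] + t[(i+1) mod 8]) / T,      DTTR = 1 - STTR

All other SPV-sourced features are computed over the user's short profile
version; users without an SPV (or with too few SPV posts for a median) get
NaN entries which the modeling stage imputes with training-set medians.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lexicon import Lexicon, PolarityScorer
from .profiles import CollectionWindow, Post, UserProfile
from .spvc import SpvResult

N_SLOTS = 8
SLOT_HOURS = 3

BEHAVIORAL_FEATURES = (
    "weekday_ratio",
    "weekend_ratio",
    "median_gap_seconds",
    "sttr",
    "dttr",
    "q1_ratio",
    "q2_ratio",
    "q3_ratio",
    "q4_ratio",
)
STATISTIC_FEATURES = (
    "spv_ratio",
    "median_spvc_score",
    "median_tweet_length",
    "n_spv",
    "statuses_total",
)
RELATIONAL_FEATURES = (
    "followers",
    "friends",
    "favorites_given",
    "median_favorites",
    "median_retweets",
)
SENTIMENT_FEATURE = "sentiment_median"
IMAGE_FEATURE = "image_score"


class DegenerateFeatureError(ValueError):
    """A feature is undefined for this input (e.g. T = 0); caller imputes."""


def slot_histogram(posts: list[Post]) -> np.ndarray:
    """Post counts per 3-hour UTC slot; slot i covers hours [3i, 3i+3)."""
    counts = np.zeros(N_SLOTS, dtype=int)
    for post in posts:
        counts[post.created_at.hour // SLOT_HOURS] += 1
    return counts


def sttr(hist: np.ndarray, T: int) -> float:
    """Minimum circular adjacent slot-pair count, normalized by ``T``."""
    hist = np.asarray(hist)
    if T <= 0:
        raise DegenerateFeatureError("T must be positive to define STTR")
    if hist.sum() > T:
        raise ValueError("slot histogram counts more posts than T")
    pair_sums = hist + np.roll(hist, -1)
    return float(pair_sums.min()) / T


def dttr(sttr_value: float) -> float:
    return 1.0 - sttr_value


def _median_or_nan(values) -> float:
    arr = np.asarray(list(values), dtype=float)
    return float(np.median(arr)) if arr.size else float("nan")


def behavioral_features(
    profile: UserProfile, spv: SpvResult, window: CollectionWindow
) -> dict[str, float]:
    """Weekday/weekend ratios, median inter-post gap and quarterly ratios over
    SPV posts; STTR/DTTR over the full in-window profile."""
    out: dict[str, float] = {}
    spv_posts = sorted(spv.posts, key=lambda p: p.created_at)
    n = len(spv_posts)
    if n:
        weekday = sum(1 for p in spv_posts if p.created_at.weekday() < 5)
        out["weekday_ratio"] = weekday / n
        out["weekend_ratio"] = (n - weekday) / n
    else:
        out["weekday_ratio"] = float("nan")
        out["weekend_ratio"] = float("nan")

    if n >= 2:
        times = np.array([p.created_at.timestamp() for p in spv_posts])
        out["median_gap_seconds"] = float(np.median(np.diff(times)))
    else:
        out["median_gap_seconds"] = float("nan")

    T = profile.n_posts
    if T > 0:
        out["sttr"] = sttr(slot_histogram(profile.posts), T)
        out["dttr"] = dttr(out["sttr"])
        quarters = np.zeros(4)
        for p in spv_posts:
            if p.created_at.year == window.year:
                quarters[(p.created_at.month - 1) // 3] += 1
        for q in range(4):
            out[f"q{q + 1}_ratio"] = quarters[q] / T
    else:
        for name in ("sttr", "dttr", "q1_ratio", "q2_ratio", "q3_ratio", "q4_ratio"):
            out[name] = float("nan")
    return out


def tweet_statistics(profile: UserProfile, spv: SpvResult) -> dict[str, float]:
    T = profile.n_posts
    return {
        "spv_ratio": spv.n_spv / T if T > 0 else float("nan"),
        "median_spvc_score": _median_or_nan(spv.scores),
        "median_tweet_length": _median_or_nan(len(p.tokens) for p in spv.posts),
        "n_spv": float(spv.n_spv),
        "statuses_total": float(profile.statuses_total),
    }


def relational_features(profile: UserProfile, spv: SpvResult) -> dict[str, float]:
    return {
        "followers": float(profile.followers_count),
        "friends": float(profile.friends_count),
        "favorites_given": float(profile.favorites_given),
        "median_favorites": _median_or_nan(p.favorite_count for p in spv.posts),
        "median_retweets": _median_or_nan(p.retweet_count for p in spv.posts),
    }


def lexicon_counts(tokens: list[str], lexicon: Lexicon) -> dict[str, float]:
    """Per-category phrase-match rate over a token sequence.

    Matching is greedy left-to-right, longest-match-first and non-overlapping
    within a category; each category's count is divided by the total token
    length.  Zero tokens yield all-zero rates (degenerate input; the caller
    tracks the flag).
    """
    n = len(tokens)
    out = {f"lex_{name}": 0.0 for name in lexicon.names}
    if n == 0:
        return out
    for name, phrases in lexicon.categories.items():
        by_len: dict[int, set[tuple[str, ...]]] = {}
        for phrase in phrases:
            by_len.setdefault(len(phrase), set()).add(phrase)
        lengths = sorted(by_len, reverse=True)
        count = 0
        i = 0
        while i < n:
            for L in lengths:
                if i + L <= n and tuple(tokens[i : i + L]) in by_len[L]:
                    count += 1
                    i += L
                    break
            else:
                i += 1
        out[f"lex_{name}"] = count / n
    return out


def sentiment_feature(spv: SpvResult, scorer: PolarityScorer) -> float:
    """Median per-post polarity over SPV posts (NaN when the SPV is empty)."""
    return _median_or_nan(scorer(p) for p in spv.posts)


def image_user_score(image_scores: list[float]) -> float:
    """Arithmetic mean of per-image scores; NaN marks a missing score."""
    return float(np.mean(image_scores)) if image_scores else float("nan")


def assemble_snpsy(
    profile: UserProfile,
    spv: SpvResult,
    lexicon: Lexicon,
    scorer: PolarityScorer,
    window: CollectionWindow,
) -> tuple[dict[str, float], dict]:
    """One named SNPSY vector (9 behavioral + 5 statistics + 5 relational +
    one per lexicon category + 1 sentiment) plus a provenance record."""
    spv_tokens: list[str] = []
    for p in spv.posts:
        spv_tokens.extend(p.tokens)

    vector: dict[str, float] = {}
    vector.update(behavioral_features(profile, spv, window))
    vector.update(tweet_statistics(profile, spv))
    vector.update(relational_features(profile, spv))
    vector.update(lexicon_counts(spv_tokens, lexicon))
    vector[SENTIMENT_FEATURE] = sentiment_feature(spv, scorer)

    provenance = {
        "user_id": profile.user_id,
        "has_spv": spv.has_spv,
        "lexicon_degenerate": len(spv_tokens) == 0,
        "imputed": sorted(k for k, v in vector.items() if np.isnan(v)),
    }
    return vector, provenance


def snpsy_feature_names(lexicon: Lexicon) -> list[str]:
    return (
        list(BEHAVIORAL_FEATURES)
        + list(STATISTIC_FEATURES)
        + list(RELATIONAL_FEATURES)
        + [f"lex_{name}" for name in lexicon.names]
        + [SENTIMENT_FEATURE]
    )


def snpsy_table(
    profiles: list[UserProfile],
    spvs: dict[str, SpvResult],
    lexicon: Lexicon,
    scorer: PolarityScorer,
    window: CollectionWindow,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort-level SNPSY feature table plus per-user provenance sidecar."""
    rows, prov = [], []
    for profile in profiles:
        vec, p = assemble_snpsy(profile, spvs[profile.user_id], lexicon, scorer, window)
        vec["user_id"] = profile.user_id
        rows.append(vec)
        prov.append(p)
    df = pd.DataFrame(rows).set_index("user_id")[snpsy_feature_names(lexicon)]
    prov_df = pd.DataFrame(prov).set_index("user_id")
    return df, prov_df


def image_score_series(profiles: list[UserProfile]) -> pd.Series:
    """Per-user mean image score (NaN = missing), indexed by user id."""
    return pd.Series(
        {p.user_id: image_user_score(p.image_scores) for p in profiles},
        name=IMAGE_FEATURE,
    )


def median_impute(df: pd.DataFrame, train_index) -> pd.DataFrame:
    """Fill NaNs with per-feature medians computed on training rows only."""
    medians = df.loc[train_index].median()
    return df.fillna(medians.fillna(0.0))
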