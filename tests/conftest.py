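"""Shared fixtures: synthetic cohorts, fitted classifiers, the default experiment.

Heavy artifacts (the full default experiment, the separable SPVC) are
session-scoped so the acceptance checks and unit tests share one fit.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from spvscreen.experiment import ExperimentConfig, ScreeningExperiment
from spvscreen.lexicon import Lexicon
from spvscreen.profiles import Post, UserProfile
from spvscreen.synthetic import CohortConfig, generate_cohort, generate_tweet_corpus
from spvscreen.spvc import train_spvc

UTC = timezone.utc


def make_post(
    post_id: str = "p0",
    when: datetime | None = None,
    tokens: tuple[str, ...] = ("hola", "mundo"),
    retweets: int = 0,
    favorites: int = 0,
) -> Post:
    when = when or datetime(2019, 6, 1, 12, 0, tzinfo=UTC)
    return Post(
        post_id=post_id,
        created_at=when,
        tokens=tokens,
        raw_text=" ".join(tokens),
        retweet_count=retweets,
        favorite_count=favorites,
    )


def make_profile(user_id="u0", posts=(), group="risk", **kw) -> UserProfile:
    return UserProfile(user_id=user_id, posts=list(posts), group=group, **kw)


def posts_at_hours(hours, day=1, tokens=("hola", "mundo")):
    return [
        make_post(
            post_id=f"p{i:03d}",
            when=datetime(2019, 3, day, h, 10, tzinfo=UTC) + timedelta(minutes=i),
            tokens=tokens,
        )
        for i, h in enumerate(hours)
    ]


def small_cohort_config(seed=11, n_per_group=10, count_scale=1 / 8) -> CohortConfig:
    cfg = CohortConfig(seed=seed, n_per_group=n_per_group)
    return cfg.scaled_counts(count_scale)


@pytest.fixture(scope="session")
def lexicon() -> Lexicon:
    return Lexicon.default()


@pytest.fixture(scope="session")
def small_cohort(lexicon):
    return generate_cohort(small_cohort_config(), lexicon)


@pytest.fixture(scope="session")
def separable_spvc(lexicon):
    """SPVC trained on a clearly separable synthetic corpus (n=1000)."""
    cfg = CohortConfig(seed=21)
    corpus = generate_tweet_corpus(cfg, 500, 500, lexicon)
    return train_spvc(corpus, seed=0)


@pytest.fixture(scope="session")
def default_results():
    """The full default experiment (84 users per group), fitted once."""
    config = ExperimentConfig(seed=7)
    return ScreeningExperiment.from_config(config).fit()
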