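"""SNPSY feature extraction: circadian ratios, statistics, lexicon counting."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spvscreen.features import (
    DegenerateFeatureError,
    assemble_snpsy,
    behavioral_features,
    dttr,
    image_user_score,
    lexicon_counts,
    relational_features,
    sentiment_feature,
    slot_histogram,
    snpsy_feature_names,
    sttr,
    tweet_statistics,
)
from spvscreen.lexicon import Lexicon, LexiconError, LexiconPolarityScorer
from spvscreen.profiles import CollectionWindow, UserProfile
from spvscreen.spvc import SpvResult

from conftest import make_post, posts_at_hours

UTC = timezone.utc
WINDOW = CollectionWindow(
    datetime(2019, 1, 1, tzinfo=UTC), datetime(2020, 1, 1, tzinfo=UTC)
)


def brute_force_sttr(hist, T):
    """Independent oracle: enumerate all 8 circular adjacent pair sums."""
    pairs = [hist[i] + hist[(i + 1) % 8] for i in range(8)]
    return min(pairs) / T


def spv_of(posts, scores=None):
    scores = scores or [0.8] * len(posts)
    retained = sorted(zip(posts, scores), key=lambda t: -t[1])
    return SpvResult(
        user_id="u", retained=list(retained), has_spv=bool(posts), n_spv=len(posts)
    )


class TestSlotHistogram:
    def test_direct_binning(self):
        # hours 0 and 0 fall in slot 0 ([0, 3)); hour 4 in slot 1 ([3, 6))
        posts = posts_at_hours([0, 0, 4])
        assert slot_histogram(posts).tolist() == [2, 1, 0, 0, 0, 0, 0, 0]

    def test_empty(self):
        assert slot_histogram([]).tolist() == [0] * 8

    def test_one_post_per_hour(self):
        posts = posts_at_hours(list(range(24)))
        assert slot_histogram(posts).tolist() == [3] * 8


class TestSttr:
    def test_uniform(self):
        assert sttr(np.full(8, 5), 40) == 0.25

    def test_single_slot_concentration(self):
        assert sttr(np.array([40, 0, 0, 0, 0, 0, 0, 0]), 40) == 0.0

    def test_worked_example(self):
        # minimum circular pair is (1,2) = 0 + 1
        assert sttr(np.array([5, 0, 1, 2, 10, 10, 10, 2]), 40) == 1 / 40

    def test_undefined_for_zero_T(self):
        with pytest.raises(DegenerateFeatureError):
            sttr(np.zeros(8), 0)

    def test_counts_exceeding_T_rejected(self):
        with pytest.raises(ValueError):
            sttr(np.full(8, 10), 40)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        hist=st.lists(st.integers(0, 50), min_size=8, max_size=8),
        extra=st.integers(0, 100),
    )
    def test_matches_brute_force_enumeration(self, hist, extra):
        T = sum(hist) + extra + 1
        assert sttr(np.array(hist), T) == brute_force_sttr(hist, T)


class TestDttr:
    @pytest.mark.parametrize("v,expected", [(0.0, 1.0), (0.25, 0.75), (0.02, 0.98)])
    def test_complement(self, v, expected):
        assert dttr(v) == pytest.approx(expected)


class TestBehavioral:
    def test_weekend_only_spv(self):
        posts = [
            make_post(post_id=f"p{i}", when=datetime(2019, 3, 2 + 7 * i, 10, tzinfo=UTC))
            for i in range(3)  # Saturdays
        ]
        profile = UserProfile(user_id="u", posts=posts, group="risk")
        out = behavioral_features(profile, spv_of(posts), WINDOW)
        assert out["weekend_ratio"] == 1.0 and out["weekday_ratio"] == 0.0

    def test_median_gap(self):
        base = datetime(2019, 4, 1, 9, 0, tzinfo=UTC)
        posts = [
            make_post(post_id=f"p{i}", when=base + timedelta(seconds=s))
            for i, s in enumerate((0, 60, 180))
        ]
        profile = UserProfile(user_id="u", posts=posts, group="risk")
        out = behavioral_features(profile, spv_of(posts), WINDOW)
        assert out["median_gap_seconds"] == 90.0

    def test_quarterly_normalization(self):
        spv_posts = [
            make_post(post_id=f"s{i}", when=datetime(2019, 2, 1 + i, 8, tzinfo=UTC))
            for i in range(10)
        ]
        filler = [
            make_post(post_id=f"f{i}", when=datetime(2019, 7, 1, 8, tzinfo=UTC) + timedelta(minutes=i))
            for i in range(990)
        ]
        profile = UserProfile(user_id="u", posts=spv_posts + filler, group="risk")
        out = behavioral_features(profile, spv_of(spv_posts), WINDOW)
        assert out["q1_ratio"] == pytest.approx(0.01)
        assert out["q2_ratio"] == out["q3_ratio"] == out["q4_ratio"] == 0.0

    def test_weekday_weekend_sum_to_one(self, small_cohort, separable_spvc):
        from spvscreen.spvc import build_spvs

        spvs = build_spvs(separable_spvc, small_cohort[:6])
        for u in small_cohort[:6]:
            out = behavioral_features(u, spvs[u.user_id], WINDOW)
            if spvs[u.user_id].n_spv:
                assert out["weekday_ratio"] + out["weekend_ratio"] == pytest.approx(1)
            assert out["sttr"] + out["dttr"] == pytest.approx(1, abs=1e-12)

    def test_empty_spv_imputable(self):
        posts = posts_at_hours([10, 11])
        profile = UserProfile(user_id="u", posts=posts, group="risk")
        out = behavioral_features(profile, spv_of([]), WINDOW)
        assert np.isnan(out["median_gap_seconds"]) and np.isnan(out["weekday_ratio"])
        assert np.isfinite(out["sttr"])  # full-profile feature survives


class TestTweetStatistics:
    def test_spv_ratio(self):
        posts = posts_at_hours([10] * 300)
        profile = UserProfile(user_id="u", posts=posts, group="risk")
        out = tweet_statistics(profile, spv_of(posts[:15]))
        assert out["spv_ratio"] == pytest.approx(0.05)
        assert out["n_spv"] == 15

    def test_median_spvc_score(self):
        posts = posts_at_hours([10, 11, 12])
        profile = UserProfile(user_id="u", posts=posts, group="risk")
        out = tweet_statistics(profile, spv_of(posts, scores=[0.9, 0.7, 0.8]))
        assert out["median_spvc_score"] == pytest.approx(0.8)

    def test_median_tweet_length(self):
        lengths = (13, 11, 20, 5, 13)
        posts = [
            make_post(post_id=f"p{i}", tokens=tuple(f"w{j}" for j in range(L)))
            for i, L in enumerate(lengths)
        ]
        profile = UserProfile(user_id="u", posts=posts, group="risk")
        out = tweet_statistics(profile, spv_of(posts))
        assert out["median_tweet_length"] == 13


class TestRelational:
    def test_metadata_passthrough(self):
        profile = UserProfile(user_id="u", posts=[], friends_count=372, group="risk")
        out = relational_features(profile, spv_of([]))
        assert out["friends"] == 372.0

    def test_median_retweets(self):
        posts = [make_post(post_id=f"p{i}", retweets=r) for i, r in enumerate((0, 0, 5))]
        profile = UserProfile(user_id="u", posts=posts, group="risk")
        assert relational_features(profile, spv_of(posts))["median_retweets"] == 0.0

    def test_no_spv_still_emits_metadata(self):
        profile = UserProfile(user_id="u", posts=[], followers_count=9, group="risk")
        out = relational_features(profile, spv_of([]))
        assert out["followers"] == 9.0
        assert np.isnan(out["median_favorites"]) and np.isnan(out["median_retweets"])


class TestLexiconCounts:
    def test_constructed_match(self):
        lex = Lexicon.from_mapping({"suicide_explicit": ["quiero morir"]})
        out = lexicon_counts(["me", "quiero", "morir", "hoy"], lex)
        assert out["lex_suicide_explicit"] == pytest.approx(0.25)

    def test_nonoverlapping_greedy_scan(self):
        lex = Lexicon.from_mapping({"c": ["morir"]})
        assert lexicon_counts(["morir", "morir"], lex)["lex_c"] == 1.0

    def test_longest_match_first(self):
        lex = Lexicon.from_mapping({"c": ["quiero morir", "morir"]})
        # the bigram consumes both tokens: one match over 2 tokens
        assert lexicon_counts(["quiero", "morir"], lex)["lex_c"] == pytest.approx(0.5)

    def test_empty_tokens_all_zero(self, lexicon):
        out = lexicon_counts([], lexicon)
        assert set(out.values()) == {0.0}

    def test_rates_bounded_by_one(self, lexicon):
        toks = ["no", "quiero", "morir"] * 30
        assert all(0 <= v <= 1 for v in lexicon_counts(toks, lexicon).values())

    def test_empty_category_rejected_at_load(self):
        with pytest.raises(LexiconError):
            Lexicon.from_mapping({"ok": ["hola"], "empty": []})

    def test_overlong_phrase_rejected(self):
        with pytest.raises(LexiconError):
            Lexicon.from_mapping({"c": ["uno dos tres cuatro"]})


class TestSentimentAndImages:
    def test_median_polarity(self):
        posts = posts_at_hours([10, 11, 12])
        scores = iter([0.2, 0.8, 0.5])
        assert sentiment_feature(spv_of(posts), lambda p: next(scores)) == 0.5

    def test_constant_scorer(self):
        posts = posts_at_hours([10, 11])
        assert sentiment_feature(spv_of(posts), lambda p: 0.7) == pytest.approx(0.7)

    def test_default_scorer_positive_tokens(self):
        post = make_post(tokens=("feliz", "genial", "amor"))
        assert LexiconPolarityScorer()(post) > 0.5

    def test_default_scorer_negative_tokens(self):
        post = make_post(tokens=("triste", "llorar", "dolor"))
        assert LexiconPolarityScorer()(post) < 0.5

    def test_image_mean(self):
        assert image_user_score([0.2, 0.4]) == pytest.approx(0.3)

    def test_image_missing_marker(self):
        assert np.isnan(image_user_score([]))

    def test_image_single(self):
        assert image_user_score([0.24]) == pytest.approx(0.24)


class TestAssemble:
    def _profile(self):
        posts = posts_at_hours([9, 10, 11], tokens=("quiero", "morir", "hoy"))
        return UserProfile(user_id="u", posts=posts, group="risk"), spv_of(posts)

    def test_width_with_toy_lexicon(self):
        lex = Lexicon.from_mapping({"a": ["uno"], "b": ["dos"], "c": ["tres"]})
        profile, spv = self._profile()
        vec, _ = assemble_snpsy(profile, spv, lex, lambda p: 0.5, WINDOW)
        assert len(vec) == 23  # 9 behavioral + 5 statistics + 5 relational + 3 + 1

    def test_width_with_92_categories(self):
        lex = Lexicon.from_mapping({f"cat{i:02d}": [f"palabra{i}"] for i in range(92)})
        profile, spv = self._profile()
        vec, _ = assemble_snpsy(profile, spv, lex, lambda p: 0.5, WINDOW)
        assert len(vec) == 112
        assert len(snpsy_feature_names(lex)) == 112

    def test_deterministic_for_identical_users(self, lexicon):
        profile, spv = self._profile()
        a, _ = assemble_snpsy(profile, spv, lexicon, lambda p: 0.5, WINDOW)
        b, _ = assemble_snpsy(profile, spv, lexicon, lambda p: 0.5, WINDOW)
        assert a == b

    def test_provenance_flags_imputed(self, lexicon):
        profile = UserProfile(user_id="u", posts=posts_at_hours([10]), group="risk")
        vec, prov = assemble_snpsy(profile, spv_of([]), lexicon, lambda p: 0.5, WINDOW)
        assert not prov["has_spv"] or prov["lexicon_degenerate"]
        assert "median_spvc_score" in prov["imputed"]
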