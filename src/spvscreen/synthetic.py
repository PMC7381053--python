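"""Synthetic cohort and corpus generation.

Generates labeled user profiles for three groups — suicidal-ideation risk,
focused control (controls who do use suicide-related vocabulary: news,
opinion, trivialization) and generic control (random users) — with the
group contrasts the downstream analysis assumes:

* risk users write shorter posts, post relatively more during the night
  band, emit more first-person and suicide-lexicon phrases, and follow
  fewer accounts;
* focused controls use suicide vocabulary at a lower rate and in a
  news/report framing (few first-person tokens);
* generic controls produce far fewer posts and almost no suicide
  vocabulary.

Post text is a token stream drawn from per-group mixtures over a filler
vocabulary and the lexicon phrase banks, so lexicon counting and n-gram
models see real signal.  Default calibration anchors (group medians for
tweet length, image score, friends) follow the descriptive statistics of
the study cohort this generator emulates; tweet-count medians default to a
desk-scale ~1/3.5 of the full-scale cohort (see ``CohortConfig.full_scale``).
Everything is overridable in :class:`CohortConfig` and all randomness flows
from its mandatory seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

from .lexicon import Lexicon
from .profiles import (
    GROUPS,
    CollectionWindow,
    ConfigurationError,
    Post,
    UserProfile,
)

RISK, FOCUSED, GENERIC = GROUPS

def _syllabic_words(n: int) -> tuple[str, ...]:
    """Deterministic pseudo-Spanish filler words (broad, Zipf-like tail)."""
    syllables = (
        "ma ri to ca le su ne pa do vi ba mo te la go cu fe ni ra so".split()
    )
    words = []
    i = 0
    while len(words) < n:
        a, b, c = (
            syllables[i % 20],
            syllables[(i // 20) % 20],
            syllables[(i // 400) % 20],
        )
        words.append(a + b + c)
        i += 1
    return tuple(dict.fromkeys(words))[:n]


#: generic, topic-neutral filler vocabulary: common Spanish words plus a broad
#: synthetic tail so the type distribution is wide, as in real text.
FILLER_VOCABULARY: tuple[str, ...] = tuple(
    """
    hoy dia manana tarde noche semana casa calle ciudad gente amigo familia
    partido futbol musica cancion concierto pelicula serie libro foto video
    juego viaje playa montana lluvia sol frio calor comida cena cafe
    desayuno fiesta cumple regalo perro gato coche tren avion bici clase
    examen curso profe compa equipo gol punto tele radio memes tuit mensaje
    llamada finde plan parque cine bar restaurante pizza tortilla helado
    fruta mercado tienda ropa zapatos camisa moda pelo corte gimnasio
    partida torneo liga temporada capitulo estreno cartelera entrada boleto
    vecino barrio plaza puente feriado vacaciones maleta mapa ruta camino
    rio lago bosque flor arbol cielo estrella luna nube viento tormenta
    paraguas bufanda guantes otono invierno primavera verano siesta paseo
    """.split()
) + _syllabic_words(440)

#: per-emission-unit phrase rates (risk, focused_control, generic_control).
DEFAULT_EMISSION_RATES: dict[str, tuple[float, float, float]] = {
    "first_person": (0.100, 0.030, 0.025),
    "suicide_explicit": (0.040, 0.008, 0.0010),
    "suicide_methods": (0.010, 0.005, 0.0005),
    "self_harm": (0.008, 0.0025, 0.0003),
    "self_loathing": (0.015, 0.0015, 0.0005),
    "depression": (0.050, 0.010, 0.0040),
    "anxiety": (0.030, 0.007, 0.0030),
    "insomnia": (0.012, 0.003, 0.0010),
    "negations": (0.060, 0.040, 0.0350),
    "feelings": (0.040, 0.010, 0.0060),
    "social_support_lack": (0.012, 0.002, 0.0005),
    "health": (0.012, 0.008, 0.0040),
    "work": (0.008, 0.020, 0.0300),
    "money": (0.006, 0.015, 0.0250),
    "news_media": (0.001, 0.030, 0.0040),
    "positive_emotion": (0.010, 0.030, 0.0350),
}

#: categories silenced for the deterministic "no SPV" slice of focused
#: controls (news-account-like profiles with no personal/emotional content).
_PERSONAL_CATEGORIES = (
    "first_person",
    "suicide_explicit",
    "suicide_methods",
    "self_harm",
    "self_loathing",
    "depression",
    "anxiety",
    "insomnia",
    "feelings",
    "social_support_lack",
)


def _per_group(risk: float, focused: float, generic: float) -> dict[str, float]:
    return {RISK: risk, FOCUSED: focused, GENERIC: generic}


@dataclass
class CohortConfig:
    """Generative parameters for one synthetic cohort.

    All count-like quantities are log-normal with the given group median and
    a shared log-scale sigma; posting hours follow a night-band mixture
    (mass ``night_mass`` uniform on ``quiet_band``, the rest uniform over
    the remaining hours); image scores are Beta with the given group median
    at fixed concentration.  ``seed`` is mandatory.
    """

    seed: int
    n_per_group: int = 84
    window: CollectionWindow = field(
        default_factory=lambda: CollectionWindow(
            datetime(2019, 1, 1, tzinfo=timezone.utc),
            datetime(2020, 1, 1, tzinfo=timezone.utc),
        )
    )
    tweet_count_median: dict[str, float] = field(
        default_factory=lambda: _per_group(800.0, 850.0, 205.0)
    )
    tweet_count_sigma: float = 0.5
    tweet_length_median: dict[str, float] = field(
        default_factory=lambda: _per_group(11.0, 19.0, 14.0)
    )
    tweet_length_sigma: float = 0.45
    night_mass: dict[str, float] = field(
        default_factory=lambda: _per_group(0.045, 0.030, 0.020)
    )
    quiet_band: tuple[int, int] = (3, 9)  # UTC hours [start, end)
    weekday_mass: dict[str, float] = field(
        default_factory=lambda: _per_group(0.66, 0.72, 0.74)
    )
    friends_median: dict[str, float] = field(
        default_factory=lambda: _per_group(372.0, 578.5, 610.0)
    )
    followers_median: dict[str, float] = field(
        default_factory=lambda: _per_group(410.0, 560.0, 650.0)
    )
    favorites_given_median: dict[str, float] = field(
        default_factory=lambda: _per_group(1500.0, 1200.0, 500.0)
    )
    relational_sigma: float = 0.45
    favorite_rate_mean: dict[str, float] = field(
        default_factory=lambda: _per_group(2.0, 4.0, 1.0)
    )
    retweet_rate_mean: dict[str, float] = field(
        default_factory=lambda: _per_group(0.5, 2.0, 0.3)
    )
    n_images_median: dict[str, float] = field(
        default_factory=lambda: _per_group(130.0, 860.0, 55.0)
    )
    n_images_sigma: float = 0.6
    image_score_median: dict[str, float] = field(
        default_factory=lambda: _per_group(0.24, 0.23, 0.23)
    )
    image_beta_concentration: float = 10.0
    missing_image_fraction: float = 0.02
    no_spv_fraction: float = 0.05
    emission_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            cat: _per_group(*rates) for cat, rates in DEFAULT_EMISSION_RATES.items()
        }
    )
    separation: float = 1.0  # corpus-level risk/generic vocabulary contrast
    corpus_boost: float = 2.5  # curation factor for corpus positives' personal/suicide rates

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")
        for name in ("night_mass", "weekday_mass"):
            for g, v in getattr(self, name).items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError(f"{name}[{g}]={v} outside [0, 1]")
        for frac in (self.missing_image_fraction, self.no_spv_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("fractions must lie in [0, 1]")
        for name in (
            "tweet_count_median",
            "tweet_length_median",
            "friends_median",
            "followers_median",
            "favorites_given_median",
            "n_images_median",
        ):
            for g, v in getattr(self, name).items():
                if v <= 0:
                    raise ConfigurationError(f"{name}[{g}]={v} must be positive")
        for cat, rates in self.emission_rates.items():
            for g, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ConfigurationError(f"emission rate {cat}[{g}]={r} invalid")
        for g in GROUPS:
            total = sum(rates[g] for rates in self.emission_rates.values())
            if total >= 0.9:
                raise ConfigurationError(
                    f"emission rates for {g} sum to {total:.2f}; leave filler mass"
                )

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def full_scale(cls, seed: int, **overrides) -> "CohortConfig":
        """Tweet volumes matching the full-scale study cohort medians."""
        overrides.setdefault(
            "tweet_count_median", _per_group(2797.5, 2984.0, 716.0)
        )
        overrides.setdefault(
            "n_images_median", _per_group(450.0, 2998.0, 190.0)
        )
        return cls(seed=seed, **overrides)

    @classmethod
    def null(cls, seed: int, **overrides) -> "CohortConfig":
        """All groups share the generic-control parameters (no planted effects)."""
        cfg = cls(seed=seed, **overrides)
        for name in (
            "tweet_count_median",
            "tweet_length_median",
            "night_mass",
            "weekday_mass",
            "friends_median",
            "followers_median",
            "favorites_given_median",
            "favorite_rate_mean",
            "retweet_rate_mean",
            "n_images_median",
            "image_score_median",
        ):
            d = getattr(cfg, name)
            for g in GROUPS:
                d[g] = d[GENERIC]
        for cat in cfg.emission_rates:
            for g in GROUPS:
                cfg.emission_rates[cat][g] = cfg.emission_rates[cat][GENERIC]
        cfg.no_spv_fraction = 0.0
        return cfg

    def scaled_counts(self, factor: float) -> "CohortConfig":
        """Copy with tweet/image counts scaled by ``factor`` (replicate runs)."""
        return replace(
            self,
            tweet_count_median={
                g: max(20.0, v * factor) for g, v in self.tweet_count_median.items()
            },
            n_images_median={
                g: max(5.0, v * factor) for g, v in self.n_images_median.items()
            },
        )


# -- emission machinery -----------------------------------------------------------


class _UnitTable:
    """Flattened sampling table: one row per phrase/filler 'emission unit'."""

    def __init__(self, rates: Mapping[str, float], lexicon: Lexicon):
        units: list[tuple[str, ...]] = []
        probs: list[float] = []
        for cat, phrases in lexicon.categories.items():
            rate = rates.get(cat, 0.0)
            if rate <= 0:
                continue
            for phrase in phrases:
                units.append(phrase)
                probs.append(rate / len(phrases))
        total_rate = sum(probs)
        if total_rate > 0.95:  # keep some filler mass whatever the rates
            probs = [p * 0.95 / total_rate for p in probs]
        filler_mass = 1.0 - sum(probs)
        for word in FILLER_VOCABULARY:
            units.append((word,))
            probs.append(filler_mass / len(FILLER_VOCABULARY))
        self.units = units
        self.probs = np.asarray(probs)
        self.probs /= self.probs.sum()
        self.lengths = np.array([len(u) for u in units])
        self.mean_unit_len = float(self.lengths @ self.probs)

    def sample_posts(
        self, rng: np.random.Generator, token_targets: np.ndarray
    ) -> list[tuple[str, ...]]:
        """Draw one token tuple per post, each close to its target length."""
        units_per_post = np.maximum(
            1, np.round(token_targets / self.mean_unit_len).astype(int)
        )
        total = int(units_per_post.sum())
        draws = rng.choice(len(self.units), size=total, p=self.probs)
        out: list[tuple[str, ...]] = []
        offset = 0
        for n_units in units_per_post:
            toks: list[str] = []
            for uid in draws[offset : offset + n_units]:
                toks.extend(self.units[uid])
            offset += n_units
            out.append(tuple(toks))
        return out


@lru_cache(maxsize=64)
def _beta_params(median: float, concentration: float) -> tuple[float, float]:
    """Beta(a, b) with a + b = concentration and the requested median."""

    def f(a: float) -> float:
        return beta_dist.ppf(0.5, a, concentration - a) - median

    a = brentq(f, 1e-3, concentration - 1e-3)
    return a, concentration - a


def generate_image_scores(
    group: str,
    n_images: int,
    seed: int | np.random.Generator,
    config: CohortConfig | None = None,
) -> list[float]:
    """Beta-distributed per-image scores with the group's configured median."""
    if n_images < 0:
        raise ValueError("n_images must be nonnegative")
    if n_images == 0:
        return []
    median = (config.image_score_median if config else _per_group(0.24, 0.23, 0.23))[
        group
    ]
    conc = config.image_beta_concentration if config else 10.0
    a, b = _beta_params(median, conc)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [float(x) for x in rng.beta(a, b, size=n_images)]


def _window_dates(window: CollectionWindow) -> tuple[np.ndarray, np.ndarray]:
    """Epoch seconds (UTC midnight) of weekday and weekend days in-window."""
    n_days = int(window.seconds // 86400)
    weekdays, weekends = [], []
    for i in range(max(n_days, 1)):
        day = window.start + timedelta(days=i)
        (weekdays if day.weekday() < 5 else weekends).append(day.timestamp())
    return np.asarray(weekdays), np.asarray(weekends)


def _sample_hours(
    rng: np.random.Generator, n: int, night_mass: float, quiet_band: tuple[int, int]
) -> np.ndarray:
    lo, hi = quiet_band
    band = hi - lo
    night = rng.random(n) < night_mass
    hours = np.empty(n)
    hours[night] = lo + rng.random(int(night.sum())) * band
    u = rng.random(int((~night).sum())) * (24 - band)
    hours[~night] = np.where(u < lo, u, u + band)
    return hours


def _lognormal(
    rng: np.random.Generator, median: float, sigma: float, size: int | None = None
):
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=size)


def _user_rates(config: CohortConfig, group: str, silence_personal: bool) -> dict:
    rates = {cat: r[group] for cat, r in config.emission_rates.items()}
    if silence_personal:
        for cat in _PERSONAL_CATEGORIES:
            rates[cat] = 0.0
    return rates


def _generate_user(
    rng: np.random.Generator,
    config: CohortConfig,
    group: str,
    index: int,
    lexicon: Lexicon,
    unit_table: _UnitTable,
    missing_images: bool,
) -> UserProfile:
    user_id = f"{group}-{index:03d}"
    n_posts = max(5, int(round(_lognormal(rng, config.tweet_count_median[group], config.tweet_count_sigma))))

    # timestamps: weekday/weekend day choice, then night-band hour mixture
    wk_dates, we_dates = _window_dates_cached(config.window)
    is_weekday = rng.random(n_posts) < config.weekday_mass[group]
    day_secs = np.empty(n_posts)
    n_wk = int(is_weekday.sum())
    day_secs[is_weekday] = rng.choice(wk_dates, size=n_wk)
    day_secs[~is_weekday] = rng.choice(we_dates, size=n_posts - n_wk)
    hours = _sample_hours(rng, n_posts, config.night_mass[group], config.quiet_band)
    epoch = day_secs + hours * 3600.0
    epoch.sort()

    lengths = np.clip(
        np.round(_lognormal(rng, config.tweet_length_median[group], config.tweet_length_sigma, n_posts)),
        3,
        60,
    )
    token_lists = unit_table.sample_posts(rng, lengths)
    favs = rng.poisson(config.favorite_rate_mean[group], n_posts)
    rts = rng.poisson(config.retweet_rate_mean[group], n_posts)

    posts = [
        Post(
            post_id=f"{user_id}-p{i:05d}",
            created_at=datetime.fromtimestamp(float(epoch[i]), tz=timezone.utc),
            tokens=token_lists[i],
            raw_text=" ".join(token_lists[i]),
            retweet_count=int(rts[i]),
            favorite_count=int(favs[i]),
        )
        for i in range(n_posts)
    ]

    if missing_images:
        image_scores: list[float] = []
    else:
        n_img = max(1, int(round(_lognormal(rng, config.n_images_median[group], config.n_images_sigma))))
        image_scores = generate_image_scores(group, n_img, rng, config)

    return UserProfile(
        user_id=user_id,
        posts=posts,
        followers_count=int(round(_lognormal(rng, config.followers_median[group], config.relational_sigma))),
        friends_count=int(round(_lognormal(rng, config.friends_median[group], config.relational_sigma))),
        favorites_given=int(round(_lognormal(rng, config.favorites_given_median[group], config.relational_sigma))),
        statuses_total=n_posts + int(rng.poisson(0.25 * n_posts)),
        image_scores=image_scores,
        group=group,
    )


_date_cache: dict[CollectionWindow, tuple[np.ndarray, np.ndarray]] = {}


def _window_dates_cached(window: CollectionWindow) -> tuple[np.ndarray, np.ndarray]:
    if window not in _date_cache:
        _date_cache[window] = _window_dates(window)
    return _date_cache[window]


def generate_cohort(
    config: CohortConfig, lexicon: Lexicon | None = None
) -> list[UserProfile]:
    """Generate ``3 * n_per_group`` labeled profiles (risk, focused, generic).

    Deterministic for a fixed config (seed included); a configured fraction
    of focused controls (rounded to a fixed count) is generated with all
    personal/emotional emissions silenced so the "user left without an SPV"
    path is always exercised.
    """
    lexicon = lexicon or Lexicon.default()
    rng = np.random.default_rng(config.seed)
    tables: dict[tuple, _UnitTable] = {}

    def table_for(group: str, silenced: bool) -> _UnitTable:
        key = (group, silenced)
        if key not in tables:
            tables[key] = _UnitTable(_user_rates(config, group, silenced), lexicon)
        return tables[key]

    n_silenced = int(round(config.no_spv_fraction * config.n_per_group))
    n_missing = int(round(config.missing_image_fraction * config.n_per_group))
    profiles: list[UserProfile] = []
    for group in GROUPS:
        for i in range(config.n_per_group):
            silenced = group == FOCUSED and i >= config.n_per_group - n_silenced
            profiles.append(
                _generate_user(
                    rng,
                    config,
                    group,
                    i,
                    lexicon,
                    table_for(group, silenced),
                    missing_images=i < n_missing,
                )
            )
    return profiles


def generate_tweet_corpus(
    config: CohortConfig,
    n_pos: int,
    n_neg: int,
    lexicon: Lexicon | None = None,
    seed: int | None = None,
) -> list[tuple[Post, str]]:
    """Labeled post-level training corpus for the SPV classifier.

    Positives draw *heavily* from the suicide/personal phrase templates: the
    risk-group rates for personal/emotional categories are multiplied by
    ``config.corpus_boost``, emulating a curated training set of clearly
    suicide-related posts and clinician phrases rather than a raw slice of
    risk users' streams.  Negatives use the generic-control mixture;
    ``config.separation`` interpolates the positive rates between the two
    (0 = identical vocabularies, the null corpus).
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    lexicon = lexicon or Lexicon.default()
    rng = np.random.default_rng(config.seed + 101 if seed is None else seed)
    gen_rates = {cat: r[GENERIC] for cat, r in config.emission_rates.items()}
    curated = {
        cat: min(0.3, r[RISK] * (config.corpus_boost if cat in _PERSONAL_CATEGORIES else 1.0))
        for cat, r in config.emission_rates.items()
    }
    s = config.separation
    pos_rates = {
        cat: gen_rates[cat] + s * (curated[cat] - gen_rates[cat]) for cat in gen_rates
    }
    pos_table = _UnitTable(pos_rates, lexicon)
    neg_table = _UnitTable(gen_rates, lexicon)
    # the separation knob also interpolates post length, so s=0 makes the two
    # classes generatively identical (a true null corpus)
    len_gen = config.tweet_length_median[GENERIC]
    len_pos = len_gen + s * (config.tweet_length_median[RISK] - len_gen)

    corpus: list[tuple[Post, str]] = []
    for label, n, table, med in (
        ("suicide_related", n_pos, pos_table, len_pos),
        ("control", n_neg, neg_table, len_gen),
    ):
        lengths = np.clip(
            np.round(_lognormal(rng, med, config.tweet_length_sigma, n)), 3, 60
        )
        token_lists = table.sample_posts(rng, lengths)
        when = config.window.start
        span = config.window.seconds
        offsets = rng.random(n) * span
        for i in range(n):
            corpus.append(
                (
                    Post(
                        post_id=f"corpus-{label}-{i:05d}",
                        created_at=when + timedelta(seconds=float(offsets[i])),
                        tokens=token_lists[i],
                        raw_text=" ".join(token_lists[i]),
                    ),
                    label,
                )
            )
    order = rng.permutation(len(corpus))
    return [corpus[i] for i in order]
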