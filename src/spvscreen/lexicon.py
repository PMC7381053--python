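"""Lexicon categories (LIWC-style word/phrase lists) and the default polarity scorer.

A lexicon is a mapping from category name to a set of phrases of one to three
tokens.  Category counts are later normalized by the token length of the text
they are counted over, so every lexicon feature is a rate in [0, 1].

The package ships a small synthetic Spanish lexicon for testing and
simulation; the proprietary dictionaries used in production settings are
loaded from the same JSON format (``{"category": ["phrase", ...], ...}``).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .profiles import Post

_TOKEN_RE = re.compile(r"[a-z0-9áéíóúüñ<>_]+")


def simple_tokenize(text: str) -> list[str]:
    """Lowercase, punctuation-stripped whitespace tokens."""
    return _TOKEN_RE.findall(text.lower())


class LexiconError(ValueError):
    """Malformed lexicon file (empty category, over-long phrase...)."""


@dataclass(frozen=True)
class Lexicon:
    """Validated category -> tuple-of-phrase-tuples mapping."""

    categories: Mapping[str, tuple[tuple[str, ...], ...]]

    def __post_init__(self) -> None:
        if not self.categories:
            raise LexiconError("lexicon has no categories")
        for name, phrases in self.categories.items():
            if not phrases:
                raise LexiconError(f"lexicon category {name!r} is empty")
            for phrase in phrases:
                if not 1 <= len(phrase) <= 3:
                    raise LexiconError(
                        f"phrase {' '.join(phrase)!r} in {name!r} must have 1-3 tokens"
                    )

    @property
    def names(self) -> list[str]:
        return list(self.categories)

    def __len__(self) -> int:
        return len(self.categories)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[str]]) -> "Lexicon":
        cats: dict[str, tuple[tuple[str, ...], ...]] = {}
        for name, phrases in mapping.items():
            if name.startswith("_"):
                continue  # underscore keys are file metadata
            tokenized = tuple(
                tuple(simple_tokenize(p)) for p in phrases if simple_tokenize(p)
            )
            cats[name] = tokenized
        return cls(categories=cats)

    @classmethod
    def from_json(cls, path: str | Path) -> "Lexicon":
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls.from_mapping(json.load(fh))

    @classmethod
    def default(cls) -> "Lexicon":
        """The synthetic lexicon shipped with the package."""
        ref = resources.files("spvscreen.data").joinpath("lexicon_synthetic.json")
        return cls.from_mapping(json.loads(ref.read_text(encoding="utf-8")))


def default_stopwords() -> list[str]:
    ref = resources.files("spvscreen.data").joinpath("stopwords_es.txt")
    words = []
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.append(line)
    return words


class LexiconPolarityScorer:
    """Per-post polarity in [0, 1] from positive/negative word lists.

    score = 0.5 + 0.5 * (n_pos - n_neg) / max(1, n_pos + n_neg); a post with
    no opinionated tokens scores the neutral 0.5.  This is the package's
    default pluggable scorer; any callable Post -> [0, 1] may replace it.
    """

    def __init__(self, positive: set[str] | None = None, negative: set[str] | None = None):
        if positive is None or negative is None:
            ref = resources.files("spvscreen.data").joinpath(
                "sentiment_words_synthetic.json"
            )
            data = json.loads(ref.read_text(encoding="utf-8"))
            positive = positive if positive is not None else set(data["positive"])
            negative = negative if negative is not None else set(data["negative"])
        self.positive = set(positive)
        self.negative = set(negative)

    def __call__(self, post: Post) -> float:
        tokens = post.tokens if post.tokens else tuple(simple_tokenize(post.raw_text))
        n_pos = sum(1 for t in tokens if t in self.positive)
        n_neg = sum(1 for t in tokens if t in self.negative)
        return 0.5 + 0.5 * (n_pos - n_neg) / max(1, n_pos + n_neg)


PolarityScorer = Callable[[Post], float]
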