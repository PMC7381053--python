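"""Core domain containers: posts, user profiles, collection windows, JSONL I/O.

A :class:`Post` is one timestamped text item with engagement metadata; a
:class:`UserProfile` is a user's chronological post stream plus account-level
relational metadata, per-image scores and a group label.  Profiles are the
atomic unit the whole screening pipeline operates on.

Timestamps are UTC throughout (post creation times on public platforms are
reported in UTC and user location is generally unknown), serialized as
ISO-8601 strings in JSONL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Sequence

GROUPS = ("risk", "focused_control", "generic_control")


class ConfigurationError(ValueError):
    """Invalid configuration (bad window, missing field, bad rate...)."""


@dataclass(frozen=True)
class CollectionWindow:
    """Half-open UTC time window [start, end) over which posts were collected."""

    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        start = _as_utc(self.start)
        end = _as_utc(self.end)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if end <= start:
            raise ConfigurationError(
                f"collection window end ({end}) must be after start ({start})"
            )

    @property
    def seconds(self) -> float:
        return (self.end - self.start).total_seconds()

    @property
    def year(self) -> int:
        """Calendar year anchoring the fixed quarterly bins."""
        return self.start.year

    def contains(self, when: datetime) -> bool:
        return self.start <= _as_utc(when) < self.end


def _as_utc(when: datetime) -> datetime:
    if when.tzinfo is None:
        return when.replace(tzinfo=timezone.utc)
    return when.astimezone(timezone.utc)


@dataclass(frozen=True)
class Post:
    """One post: identifier, UTC creation time, tokens, raw text, engagement."""

    post_id: str
    created_at: datetime
    tokens: tuple[str, ...]
    raw_text: str
    retweet_count: int = 0
    favorite_count: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "created_at", _as_utc(self.created_at))
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if self.retweet_count < 0 or self.favorite_count < 0:
            raise ValueError("engagement counts must be nonnegative")
        if self.raw_text and not self.tokens:
            raise ValueError("tokens must be nonempty when raw_text is nonempty")

    def to_dict(self) -> dict:
        return {
            "post_id": self.post_id,
            "created_at": self.created_at.isoformat().replace("+00:00", "Z"),
            "tokens": list(self.tokens),
            "raw_text": self.raw_text,
            "retweet_count": self.retweet_count,
            "favorite_count": self.favorite_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Post":
        return cls(
            post_id=d["post_id"],
            created_at=datetime.fromisoformat(d["created_at"].replace("Z", "+00:00")),
            tokens=tuple(d["tokens"]),
            raw_text=d["raw_text"],
            retweet_count=int(d.get("retweet_count", 0)),
            favorite_count=int(d.get("favorite_count", 0)),
        )


@dataclass
class UserProfile:
    """A user's post stream plus relational metadata, image scores and label.

    ``posts`` is kept sorted ascending by ``created_at``.  ``statuses_total``
    is the lifetime post count of the account and is at least the number of
    posts inside the collection window; the in-window post count is the
    normalizer ``T`` used by the circadian posting-time ratios.
    """

    user_id: str
    posts: list[Post] = field(default_factory=list)
    followers_count: int = 0
    friends_count: int = 0
    favorites_given: int = 0
    statuses_total: int = 0
    image_scores: list[float] = field(default_factory=list)
    group: str = "generic_control"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        self.posts = sorted(self.posts, key=lambda p: (p.created_at, p.post_id))
        if self.statuses_total < len(self.posts):
            self.statuses_total = len(self.posts)
        for v in (self.followers_count, self.friends_count, self.favorites_given):
            if v < 0:
                raise ValueError("account metadata counts must be nonnegative")
        for s in self.image_scores:
            if not 0.0 <= s <= 1.0:
                raise ValueError("image scores must lie in [0, 1]")

    @property
    def n_posts(self) -> int:
        """In-window post count ``T`` (all carried posts are in-window)."""
        return len(self.posts)

    def to_dict(self) -> dict:
        return {
            "user_id": self.user_id,
            "group": self.group,
            "followers_count": self.followers_count,
            "friends_count": self.friends_count,
            "favorites_given": self.favorites_given,
            "statuses_total": self.statuses_total,
            "image_scores": [round(float(s), 6) for s in self.image_scores],
            "posts": [p.to_dict() for p in self.posts],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UserProfile":
        return cls(
            user_id=d["user_id"],
            posts=[Post.from_dict(p) for p in d["posts"]],
            followers_count=int(d["followers_count"]),
            friends_count=int(d["friends_count"]),
            favorites_given=int(d["favorites_given"]),
            statuses_total=int(d["statuses_total"]),
            image_scores=[float(s) for s in d.get("image_scores", [])],
            group=d["group"],
        )


def write_users_jsonl(profiles: Iterable[UserProfile], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for profile in profiles:
            fh.write(json.dumps(profile.to_dict(), sort_keys=True) + "\n")


def read_users_jsonl(path: str | Path) -> list[UserProfile]:
    with Path(path).open("r", encoding="utf-8") as fh:
        return [UserProfile.from_dict(json.loads(line)) for line in fh if line.strip()]


def write_corpus_jsonl(
    corpus: Sequence[tuple[Post, str]], path: str | Path
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for post, label in corpus:
            rec = post.to_dict()
            rec["label"] = label
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_corpus_jsonl(path: str | Path) -> list[tuple[Post, str]]:
    out: list[tuple[Post, str]] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            label = rec.pop("label")
            out.append((Post.from_dict(rec), label))
    return out


def iter_posts(profiles: Iterable[UserProfile]) -> Iterator[Post]:
    for profile in profiles:
        yield from profile.posts
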