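"""Word-list resources driving all scoring stages.

Four closed resources are consumed, never fitted here: a +1/-1 valence
lexicon, a truncated LDA word-topic table (word -> p(topic|word), at most
20 words listed per topic), a LIWC-style category lexicon, and an activity
lexicon (optionally with two raters' labels per term).  All load from the
plain CSV schemas documented on each class, so real resources can be
dropped in for the synthetic stand-ins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["ValenceLexicon", "TopicTable", "CategoryLexicon", "ActivityLexicon"]

MAX_WORDS_PER_TOPIC = 20


@dataclass(frozen=True)
class ValenceLexicon:
    """Polarity word list: word -> valence in {+1, -1}.

    The positive and negative sets must be disjoint.
    """

    valence: dict[str, int]

    def __post_init__(self) -> None:
        bad = {w: v for w, v in self.valence.items() if v not in (1, -1)}
        if bad:
            raise ValueError(f"valence must be +1 or -1, got {bad}")

    @property
    def positive(self) -> frozenset[str]:
        return frozenset(w for w, v in self.valence.items() if v == 1)

    @property
    def negative(self) -> frozenset[str]:
        return frozenset(w for w, v in self.valence.items() if v == -1)

    def __contains__(self, word: str) -> bool:
        return word in self.valence

    def __len__(self) -> int:
        return len(self.valence)

    def flipped(self) -> "ValenceLexicon":
        """Sign-swapped copy (used by symmetry checks)."""
        return ValenceLexicon({w: -v for w, v in self.valence.items()})

    @classmethod
    def from_csv(cls, path: str | Path) -> "ValenceLexicon":
        """Read CSV ``word,valence``."""
        df = pd.read_csv(path, dtype={"word": str, "valence": int})
        dup = df["word"][df["word"].duplicated()]
        if len(dup):
            raise ValueError(f"word(s) listed with both signs: {sorted(set(dup))}")
        return cls(dict(zip(df["word"], df["valence"])))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.valence.items()), columns=["word", "valence"]
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class TopicTable:
    """Truncated word-topic table: topic_id -> [(word, p(t|w)), ...].

    Each topic lists at most 20 words (a threshold was applied to the
    word-topic probabilities, truncating the table).  A word may appear
    under several topics; a word listed under exactly one topic carries
    p(t|w) = 1 there.  For any word the listed probabilities sum to <= 1.
    """

    topics: dict[int, tuple[tuple[str, float], ...]]
    _word_topics: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        wt: dict[str, list[tuple[int, float]]] = {}
        for tid, entries in self.topics.items():
            if len(entries) > MAX_WORDS_PER_TOPIC:
                raise ValueError(
                    f"topic {tid} lists {len(entries)} words "
                    f"(> {MAX_WORDS_PER_TOPIC})"
                )
            for word, p in entries:
                if not 0.0 < p <= 1.0:
                    raise ValueError(f"p(t|w) out of (0,1]: {word!r}={p}")
                wt.setdefault(word, []).append((tid, p))
        for word, hits in wt.items():
            if sum(p for _, p in hits) > 1.0 + 1e-9:
                raise ValueError(f"sum of p(t|w) over topics > 1 for {word!r}")
        object.__setattr__(self, "_word_topics", wt)

    @property
    def topic_ids(self) -> list[int]:
        return sorted(self.topics)

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self._word_topics)

    def word_topics(self, word: str) -> list[tuple[int, float]]:
        """Topics listing ``word`` with their p(t|w); empty if unlisted."""
        return list(self._word_topics.get(word, ()))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TopicTable":
        """Read CSV ``topic_id,word,p_tw``."""
        df = pd.read_csv(path, dtype={"topic_id": int, "word": str, "p_tw": float})
        topics: dict[int, list[tuple[str, float]]] = {}
        for tid, word, p in df.itertuples(index=False):
            topics.setdefault(int(tid), []).append((word, float(p)))
        return cls({t: tuple(v) for t, v in topics.items()})

    def to_csv(self, path: str | Path) -> None:
        rows = [
            (tid, w, p)
            for tid in self.topic_ids
            for w, p in self.topics[tid]
        ]
        pd.DataFrame(rows, columns=["topic_id", "word", "p_tw"]).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class CategoryLexicon:
    """Closed-vocabulary (LIWC-style) category lexicon: name -> word set."""

    categories: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        empty = [c for c, ws in self.categories.items() if not ws]
        if empty:
            raise ValueError(f"empty categories: {empty}")

    @property
    def names(self) -> list[str]:
        return sorted(self.categories)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CategoryLexicon":
        """Read CSV ``category,word``."""
        df = pd.read_csv(path, dtype=str)
        cats = {
            c: frozenset(sub["word"]) for c, sub in df.groupby("category")
        }
        return cls(cats)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            (c, w) for c in self.names for w in sorted(self.categories[c])
        ]
        pd.DataFrame(rows, columns=["category", "word"]).to_csv(path, index=False)


@dataclass(frozen=True)
class ActivityLexicon:
    """Manually defined activity word lists (e.g. housework -> vacuum, dishes).

    Terms may be single words or space-separated bigrams (matched as token
    bigrams).  Optionally each term carries two raters' categorical labels,
    used for the inter-rater Cohen's kappa check.
    """

    activities: dict[str, tuple[str, ...]]
    ratings: pd.DataFrame | None = None  # columns: activity, word, rating_a, rating_b

    def __post_init__(self) -> None:
        empty = [a for a, ws in self.activities.items() if not ws]
        if empty:
            raise ValueError(f"empty activities: {empty}")

    @property
    def names(self) -> list[str]:
        return sorted(self.activities)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ActivityLexicon":
        """Read CSV ``activity,word[,rating_a,rating_b]``."""
        df = pd.read_csv(path, dtype=str)
        acts = {
            a: tuple(sub["word"]) for a, sub in df.groupby("activity")
        }
        ratings = None
        if {"rating_a", "rating_b"} <= set(df.columns):
            ratings = df[["activity", "word", "rating_a", "rating_b"]].copy()
        return cls(acts, ratings)

    def to_csv(self, path: str | Path) -> None:
        if self.ratings is not None:
            self.ratings.to_csv(path, index=False)
            return
        rows = [(a, w) for a in self.names for w in self.activities[a]]
        pd.DataFrame(rows, columns=["activity", "word"]).to_csv(path, index=False)
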