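"""Cleaning and tokenization of social-media status text.

The cleaning pipeline runs in a fixed order:

1. hyperlink removal,
2. digit removal,
3. smiley ("emoticon") conversion to word tokens,
4. removal of all remaining punctuation, lowercasing,
5. whitespace tokenization.

Smileys are sequences of punctuation characters, so they must be converted
to alphabetic tokens *before* the punctuation strip; hyperlinks are dropped
first so fragments such as ``:/`` inside a URL never match a smiley
pattern.  Stop words are deliberately kept: downstream scoring uses
pre-defined word lists that already account for them.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SmileyMap",
    "DEFAULT_SMILEY_MAP",
    "convert_smileys",
    "clean_status",
    "tokenize",
    "preprocess_status",
]

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_DIGIT_RE = re.compile(r"\d+")
_NON_ALPHA_RE = re.compile(r"[^A-Za-z\s]+")
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class SmileyMap:
    """Ordered map from punctuation emoticon patterns to word tokens.

    Patterns are literal punctuation sequences matched longest-first, so
    ``:-)`` wins over ``:-`` or ``:)`` and variants collapse onto a single
    concept token (e.g. both ``:)`` and ``:-)`` become ``happyface``).
    Replacement tokens must be lowercase alphabetic words.
    """

    pairs: tuple[tuple[str, str], ...]
    _regex: re.Pattern = field(init=False, repr=False, compare=False)
    _lookup: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for pat, rep in self.pairs:
            if not pat:
                raise ValueError("empty smiley pattern")
            if not (rep.isalpha() and rep == rep.lower()):
                raise ValueError(
                    f"smiley replacement {rep!r} must be a lowercase word"
                )
        ordered = sorted(self.pairs, key=lambda pr: len(pr[0]), reverse=True)
        regex = re.compile("|".join(re.escape(p) for p, _ in ordered))
        object.__setattr__(self, "_regex", regex)
        object.__setattr__(self, "_lookup", dict(self.pairs))

    def apply(self, text: str) -> str:
        return self._regex.sub(lambda m: f" {self._lookup[m.group(0)]} ", text)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SmileyMap":
        """Read a ``pattern,replacement`` CSV (no header row required)."""
        pairs = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row or row[0] == "pattern":
                    continue
                pairs.append((row[0], row[1]))
        return cls(tuple(pairs))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["pattern", "replacement"])
            writer.writerows(self.pairs)


#: Default emoticon inventory.  Only ":-)"->happyface and ":-("->sadface are
#: normative; the remaining variants are a pragmatic default and the map is
#: fully editable / replaceable from CSV.
DEFAULT_SMILEY_MAP = SmileyMap(
    (
        (":-)", "happyface"),
        (":)", "happyface"),
        ("=)", "happyface"),
        (":-D", "happyface"),
        (":D", "happyface"),
        (":-(", "sadface"),
        (":(", "sadface"),
        ("=(", "sadface"),
        (":'(", "sadface"),
    )
)


def convert_smileys(text: str, smiley_map: SmileyMap = DEFAULT_SMILEY_MAP) -> str:
    """Replace every emoticon occurrence with its word token.

    Idempotent on text without smileys; replacement tokens are plain words
    and can never re-match a punctuation pattern.
    """
    return smiley_map.apply(text)


def clean_status(text: str) -> str:
    """Strip hyperlinks, digits and punctuation; lowercase; tidy whitespace.

    Assumes smiley conversion has already been applied where wanted (the
    inserted tokens are alphabetic and survive unchanged).  Idempotent.
    """
    text = _URL_RE.sub(" ", text)
    text = _DIGIT_RE.sub("", text)
    text = _NON_ALPHA_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip().lower()


def tokenize(text: str) -> list[str]:
    """Whitespace-split a cleaned status into an ordered token list."""
    return text.split()


def preprocess_status(
    text: str, smiley_map: SmileyMap = DEFAULT_SMILEY_MAP
) -> list[str]:
    """Full cleaning pass raw text -> token list (see module docstring)."""
    text = _URL_RE.sub(" ", text)
    text = _DIGIT_RE.sub("", text)
    text = convert_smileys(text, smiley_map)
    return tokenize(clean_status(text))


def preprocess_texts(
    texts: Iterable[str], smiley_map: SmileyMap = DEFAULT_SMILEY_MAP
) -> list[list[str]]:
    """Vectorized convenience: preprocess a sequence of raw statuses."""
    return [preprocess_status(t, smiley_map) for t in texts]
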