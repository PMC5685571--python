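"""In-memory containers for per-user status corpora.

``UserCorpus`` holds raw statuses (one text record per status, with user
id).  ``TokenizedCorpus`` is its preprocessed, exploded form: every token
is a row, with integer codes into a shared vocabulary, which lets all
downstream scoring run as vectorized numpy/scipy operations.
``UserDocument`` is the per-user concatenated bag of tokens used by the
topic and category scorers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_SMILEY_MAP, SmileyMap, preprocess_status

__all__ = [
    "UserCorpus",
    "TokenizedCorpus",
    "UserDocument",
    "read_statuses",
    "write_statuses",
    "read_outcomes",
    "write_outcomes",
]


@dataclass(frozen=True)
class UserCorpus:
    """Raw per-user status updates.

    ``statuses`` has columns ``user_id`` (str) and ``text`` (str), one row
    per status update, in a deterministic order.
    """

    statuses: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"user_id", "text"} - set(self.statuses.columns)
        if missing:
            raise ValueError(f"statuses frame missing columns {sorted(missing)}")

    @property
    def user_ids(self) -> list[str]:
        return sorted(self.statuses["user_id"].unique())

    @property
    def n_statuses(self) -> pd.Series:
        """Status count per user (sorted by user id)."""
        return self.statuses.groupby("user_id").size().sort_index()

    def __len__(self) -> int:
        return len(self.statuses)

    def filter_min_statuses(self, min_statuses: int) -> "UserCorpus":
        """Retention filter: drop users with fewer than ``min_statuses``."""
        counts = self.statuses.groupby("user_id")["text"].transform("size")
        kept = self.statuses[counts >= min_statuses].reset_index(drop=True)
        return UserCorpus(kept)

    def tokenize(self, smiley_map: SmileyMap = DEFAULT_SMILEY_MAP) -> "TokenizedCorpus":
        return TokenizedCorpus.from_corpus(self, smiley_map)


@dataclass(frozen=True)
class TokenizedCorpus:
    """Preprocessed corpus in exploded (one row per token) form.

    Users are ordered by sorted user id; statuses keep corpus order.
    ``token_code`` indexes into ``vocab``; ``token_status`` maps each token
    to its status row; ``status_user`` maps each status to its user index.
    """

    user_ids: np.ndarray          # (n_users,) str, sorted
    status_user: np.ndarray       # (n_statuses,) int
    vocab: np.ndarray             # (n_words,) str
    token_code: np.ndarray        # (n_tokens,) int
    token_status: np.ndarray      # (n_tokens,) int

    @classmethod
    def from_corpus(
        cls, corpus: UserCorpus, smiley_map: SmileyMap = DEFAULT_SMILEY_MAP
    ) -> "TokenizedCorpus":
        df = corpus.statuses
        user_ids, user_codes = np.unique(df["user_id"].to_numpy(), return_inverse=True)
        token_lists = [preprocess_status(t, smiley_map) for t in df["text"]]
        lengths = np.fromiter((len(t) for t in token_lists), int, len(token_lists))
        flat = [w for toks in token_lists for w in toks]
        if flat:
            codes, vocab = pd.factorize(np.asarray(flat, dtype=object))
            vocab = np.asarray(vocab, dtype=object)
        else:
            codes, vocab = np.empty(0, int), np.empty(0, object)
        token_status = np.repeat(np.arange(len(df)), lengths)
        return cls(user_ids, user_codes, vocab, np.asarray(codes), token_status)

    @property
    def n_users(self) -> int:
        return len(self.user_ids)

    @property
    def n_statuses_total(self) -> int:
        return len(self.status_user)

    @property
    def token_user(self) -> np.ndarray:
        return self.status_user[self.token_status]

    def statuses_per_user(self) -> np.ndarray:
        return np.bincount(self.status_user, minlength=self.n_users)

    def status_tokens(self) -> list[list[str]]:
        """Token list per status (materialized; test/oracle convenience)."""
        order = np.argsort(self.token_status, kind="stable")
        words = self.vocab[self.token_code[order]]
        bounds = np.bincount(self.token_status, minlength=self.n_statuses_total)
        out, pos = [], 0
        for n in bounds:
            out.append(list(words[pos : pos + n]))
            pos += n
        return out

    def user_word_counts(self):
        """Sparse users x vocab count matrix (CSR)."""
        from scipy import sparse

        data = np.ones(len(self.token_code), dtype=np.float64)
        mat = sparse.coo_matrix(
            (data, (self.token_user, self.token_code)),
            shape=(self.n_users, len(self.vocab)),
        )
        return mat.tocsr()

    def user_documents(self) -> list["UserDocument"]:
        """Per-user concatenated documents, in user-id order."""
        counts = self.user_word_counts()
        n_statuses = self.statuses_per_user()
        docs = []
        for i, uid in enumerate(self.user_ids):
            row = counts.getrow(i)
            ctr = Counter(
                {self.vocab[j]: int(c) for j, c in zip(row.indices, row.data)}
            )
            docs.append(UserDocument(uid, ctr, int(n_statuses[i])))
        return docs


@dataclass(frozen=True)
class UserDocument:
    """All of one user's statuses concatenated into a single bag of tokens."""

    user_id: str
    counts: Counter
    n_statuses: int

    @property
    def total_words(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_token_lists(
        cls, user_id: str, statuses: list[list[str]]
    ) -> "UserDocument":
        ctr: Counter = Counter()
        for toks in statuses:
            ctr.update(toks)
        return cls(user_id, ctr, len(statuses))


# ---------------------------------------------------------------------------
# Plain-text IO: line-delimited statuses and CSV outcomes.


def write_statuses(corpus: UserCorpus, path: str | Path) -> None:
    """Write line-delimited ``user_id<TAB>status_text`` records (UTF-8).

    Tabs and newlines inside a status are flattened to spaces so the format
    stays one record per line.
    """
    df = corpus.statuses.copy()
    df["text"] = df["text"].str.replace(r"[\t\r\n]+", " ", regex=True)
    df.to_csv(path, sep="\t", header=False, index=False, encoding="utf-8")


def read_statuses(path: str | Path) -> UserCorpus:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"status file not found: {path}")
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            uid, _, text = line.partition("\t")
            rows.append((uid, text))
    return UserCorpus(pd.DataFrame(rows, columns=["user_id", "text"], dtype=str))


def write_outcomes(outcomes: pd.DataFrame, path: str | Path) -> None:
    """Write the self-report table as CSV ``user_id,swl,cesd``."""
    outcomes[["user_id", "swl", "cesd"]].to_csv(path, index=False)


def read_outcomes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"outcome file not found: {path}")
    df = pd.read_csv(path, dtype={"user_id": str})
    missing = {"user_id", "swl", "cesd"} - set(df.columns)
    if missing:
        raise ValueError(f"outcome file missing columns {sorted(missing)}")
    return df
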