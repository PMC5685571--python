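"""Closed-vocabulary category counts and topic scores from a truncated table.

Two topic scorers are provided.

*Word count*: a document token listed under k topics adds 1 to each of
those k topic scores, ignoring p(t|w).  A user who writes "driveway"
(listed only under the winter-traffic topic) raises that topic's score by
1, exactly as a user writing "ice" (listed under six topics) raises all
six by 1.

*Probability (truncated-table)*: p(t|u) = sum_w p(t|w) * p(w|u) with
p(w|u) = count(w)/total words, summed only over words the truncated table
lists under t.  Because truncation forces p(t|w) = 1 for words kept in a
single topic while shared words keep small probabilities, this scorer
stretches the spread between a user's high and low topic scores; the word
count scorer compresses it (max/min ratio over positive scores is
smaller).  ``compare_scoring_ratio`` measures exactly that.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from .affect import AFFECT_FEATURES
from .corpus import TokenizedCorpus, UserDocument
from .lexicons import CategoryLexicon, TopicTable

__all__ = [
    "category_counts",
    "topic_wordcount_scores",
    "topic_probability_scores",
    "compare_scoring_ratio",
    "category_matrix",
    "topic_wordcount_matrix",
    "topic_probability_matrix",
    "assemble_feature_matrix",
]


def category_counts(
    doc: UserDocument, lexicon: CategoryLexicon, normalize: bool = True
) -> pd.Series:
    """Per-category token counts for one user document.

    With ``normalize=True`` (default) counts are divided by the user's
    status count — the same normalizer used for sentiment, since status
    counts, not word counts, index how much a user writes.  Raw counts are
    returned with ``normalize=False``.
    """
    out = {}
    for name in lexicon.names:
        words = lexicon.categories[name]
        c = sum(cnt for w, cnt in doc.counts.items() if w in words)
        out[name] = c / doc.n_statuses if normalize else float(c)
    return pd.Series(out, dtype=float)


def topic_wordcount_scores(doc: UserDocument, table: TopicTable) -> pd.Series:
    """Word-count topic scores: each use of a listed word adds 1 per topic."""
    scores = dict.fromkeys(table.topic_ids, 0.0)
    for word, cnt in doc.counts.items():
        for tid, _p in table.word_topics(word):
            scores[tid] += cnt
    return pd.Series(scores, dtype=float).sort_index()


def topic_probability_scores(doc: UserDocument, table: TopicTable) -> pd.Series:
    """Truncated-table p(t|u) scores: sum_w p(t|w) * count(w)/total."""
    total = doc.total_words
    if total == 0:
        raise ValueError(
            f"user {doc.user_id!r} has an empty document; p(w|u) is undefined"
        )
    scores = dict.fromkeys(table.topic_ids, 0.0)
    for word, cnt in doc.counts.items():
        for tid, p in table.word_topics(word):
            scores[tid] += p * cnt / total
    return pd.Series(scores, dtype=float).sort_index()


def compare_scoring_ratio(
    doc: UserDocument, table: TopicTable
) -> tuple[float, float]:
    """(max/min over positive scores) for the word-count and probability scorers."""
    ratios = []
    for scores in (
        topic_wordcount_scores(doc, table),
        topic_probability_scores(doc, table),
    ):
        pos = scores[scores > 0]
        if len(pos) < 2:
            raise ValueError(
                "need >= 2 strictly positive topic scores to form a ratio "
                f"(got {len(pos)})"
            )
        ratios.append(float(pos.max() / pos.min()))
    return ratios[0], ratios[1]


# ---------------------------------------------------------------------------
# Vectorized corpus-level variants (same semantics, sparse matrix algebra).


def _vocab_topic_matrix(
    tok: TokenizedCorpus, table: TopicTable, weighted: bool
) -> tuple[sparse.csr_matrix, list[int]]:
    tids = table.topic_ids
    tpos = {t: j for j, t in enumerate(tids)}
    rows, cols, data = [], [], []
    windex = {w: i for i, w in enumerate(tok.vocab)}
    for tid, entries in table.topics.items():
        for word, p in entries:
            i = windex.get(word)
            if i is None:
                continue
            rows.append(i)
            cols.append(tpos[tid])
            data.append(p if weighted else 1.0)
    mat = sparse.coo_matrix(
        (data, (rows, cols)), shape=(len(tok.vocab), len(tids))
    )
    return mat.tocsr(), tids


def topic_wordcount_matrix(
    tok: TokenizedCorpus, table: TopicTable, normalize: bool = True
) -> pd.DataFrame:
    """Users x topics word-count scores (optionally per-status normalized)."""
    counts = tok.user_word_counts()
    wt, tids = _vocab_topic_matrix(tok, table, weighted=False)
    scores = np.asarray((counts @ wt).todense())
    if normalize:
        scores = scores / tok.statuses_per_user()[:, None]
    return pd.DataFrame(
        scores, index=pd.Index(tok.user_ids, name="user_id"), columns=tids
    )


def topic_probability_matrix(
    tok: TokenizedCorpus, table: TopicTable
) -> pd.DataFrame:
    counts = tok.user_word_counts()
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        empty = tok.user_ids[totals == 0]
        raise ValueError(f"empty documents for users {list(empty)}")
    wt, tids = _vocab_topic_matrix(tok, table, weighted=True)
    scores = np.asarray((counts @ wt).todense()) / totals[:, None]
    return pd.DataFrame(
        scores, index=pd.Index(tok.user_ids, name="user_id"), columns=tids
    )


def category_matrix(
    tok: TokenizedCorpus, lexicon: CategoryLexicon, normalize: bool = True
) -> pd.DataFrame:
    counts = tok.user_word_counts()
    names = lexicon.names
    windex = {w: i for i, w in enumerate(tok.vocab)}
    rows, cols = [], []
    for j, name in enumerate(names):
        for word in lexicon.categories[name]:
            i = windex.get(word)
            if i is not None:
                rows.append(i)
                cols.append(j)
    ind = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(tok.vocab), len(names))
    ).tocsr()
    scores = np.asarray((counts @ ind).todense())
    if normalize:
        scores = scores / tok.statuses_per_user()[:, None]
    return pd.DataFrame(
        scores, index=pd.Index(tok.user_ids, name="user_id"), columns=names
    )


def assemble_feature_matrix(
    affect: pd.DataFrame,
    categories: pd.DataFrame,
    topics: pd.DataFrame,
) -> pd.DataFrame:
    """Column-concatenate affect, category and topic features per user.

    Feature names are namespaced (``affect:``, ``cat:``, ``topic:``) so no
    collision is possible; rows are sorted by user id; user sets must match
    exactly.
    """
    blocks = {"affect": affect[list(AFFECT_FEATURES)], "cat": categories, "topic": topics}
    users = sorted(affect.index)
    for name, block in blocks.items():
        missing = set(users) ^ set(block.index)
        if missing:
            raise ValueError(
                f"user sets differ in block {name!r}: {sorted(missing)[:10]}"
            )
    parts = []
    for ns, block in blocks.items():
        part = block.loc[users].copy()
        part.columns = [f"{ns}:{c}" for c in part.columns]
        parts.append(part)
    out = pd.concat(parts, axis=1)
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing entries in feature columns {bad}")
    return out
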