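"""Valence word counting and user-level affect features.

Each status gets an integer valence sum (+1 per positive lexicon word, -1
per negative, repeats counted) and a ternary polarity by its sign.  The
four affect features of a user are

* ``mean_sentiment`` — sum of all valence sums divided by the number of
  status updates (status count, not word count, is the normalizer: status
  lengths are too uneven for per-word rates),
* ``pos_freq`` / ``neg_freq`` — proportions of positive / negative
  statuses among all of the user's statuses (neutral statuses stay in the
  denominator),
* ``pos_neg_ratio`` — (#positive+1)/(#negative+1); the add-one smoothing
  keeps the ratio defined for the many users with zero negative statuses.
  The raw #pos/#neg ratio is exposed as well (NaN when #neg = 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import TokenizedCorpus
from .lexicons import ValenceLexicon

__all__ = [
    "StatusScore",
    "AffectFeatures",
    "score_status",
    "user_affect_features",
    "corpus_status_scores",
    "affect_feature_frame",
    "affect_swl_correlations",
]

AFFECT_FEATURES = ("mean_sentiment", "pos_freq", "neg_freq", "pos_neg_ratio")


@dataclass(frozen=True)
class StatusScore:
    valence_sum: int

    @property
    def polarity(self) -> str:
        if self.valence_sum > 0:
            return "positive"
        if self.valence_sum < 0:
            return "negative"
        return "neutral"


@dataclass(frozen=True)
class AffectFeatures:
    mean_sentiment: float
    pos_freq: float
    neg_freq: float
    pos_neg_ratio: float
    pos_neg_ratio_raw: float  # NaN when the user has no negative statuses
    n_statuses: int


def score_status(tokens: Sequence[str], lexicon: ValenceLexicon) -> StatusScore:
    """Valence sum of one status: +1 per positive hit, -1 per negative."""
    pos, neg = lexicon.positive, lexicon.negative
    total = 0
    for tok in tokens:
        if tok in pos:
            total += 1
        elif tok in neg:
            total -= 1
    return StatusScore(total)


def user_affect_features(scores: Iterable[StatusScore]) -> AffectFeatures:
    """Aggregate one user's status scores into the four affect features."""
    sums = [s.valence_sum for s in scores]
    n = len(sums)
    if n == 0:
        raise ValueError(
            "user has zero statuses; should have been removed by the "
            "minimum-status retention filter"
        )
    n_pos = sum(1 for v in sums if v > 0)
    n_neg = sum(1 for v in sums if v < 0)
    return AffectFeatures(
        mean_sentiment=sum(sums) / n,
        pos_freq=n_pos / n,
        neg_freq=n_neg / n,
        pos_neg_ratio=(n_pos + 1) / (n_neg + 1),
        pos_neg_ratio_raw=n_pos / n_neg if n_neg else float("nan"),
        n_statuses=n,
    )


def corpus_status_scores(
    tok: TokenizedCorpus, lexicon: ValenceLexicon
) -> np.ndarray:
    """Vectorized per-status valence sums, in corpus status order."""
    word_val = np.zeros(len(tok.vocab), dtype=np.int64)
    for i, w in enumerate(tok.vocab):
        word_val[i] = lexicon.valence.get(w, 0)
    token_val = word_val[tok.token_code]
    sums = np.zeros(tok.n_statuses_total, dtype=np.int64)
    np.add.at(sums, tok.token_status, token_val)
    return sums


def affect_feature_frame(
    tok: TokenizedCorpus, lexicon: ValenceLexicon
) -> pd.DataFrame:
    """Per-user affect features, indexed by user id (sorted).

    Columns: the four modeling features plus ``pos_neg_ratio_raw`` and
    ``n_statuses``.
    """
    sums = corpus_status_scores(tok, lexicon)
    nu = tok.n_users
    n = np.bincount(tok.status_user, minlength=nu).astype(float)
    total = np.bincount(tok.status_user, weights=sums, minlength=nu)
    n_pos = np.bincount(tok.status_user, weights=(sums > 0), minlength=nu)
    n_neg = np.bincount(tok.status_user, weights=(sums < 0), minlength=nu)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(n_neg > 0, n_pos / np.maximum(n_neg, 1), np.nan)
    return pd.DataFrame(
        {
            "mean_sentiment": total / n,
            "pos_freq": n_pos / n,
            "neg_freq": n_neg / n,
            "pos_neg_ratio": (n_pos + 1) / (n_neg + 1),
            "pos_neg_ratio_raw": raw,
            "n_statuses": n.astype(int),
        },
        index=pd.Index(tok.user_ids, name="user_id"),
    )


def affect_swl_correlations(
    features: pd.DataFrame, swl: pd.Series
) -> pd.DataFrame:
    """Pairwise Pearson correlations among {SWL} | affect features.

    Returns a square frame of r values (two-sided p values in the
    ``.attrs['p']`` companion frame).  A constant column yields NaN, never
    a silent 0.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 users for correlations")
    cols = {"swl": swl.reindex(features.index)}
    for name in AFFECT_FEATURES:
        cols[name] = features[name]
    df = pd.DataFrame(cols)
    names = list(df.columns)
    r = pd.DataFrame(np.nan, index=names, columns=names)
    p = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        for b in names:
            x, y = df[a].to_numpy(float), df[b].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                continue  # undefined: leave as NaN
            res = stats.pearsonr(x[ok], y[ok])
            r.loc[a, b], p.loc[a, b] = res.statistic, res.pvalue
    r.attrs["p"] = p
    return r
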