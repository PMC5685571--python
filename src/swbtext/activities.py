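"""Activity-conditioned sentiment and inter-rater agreement.

A status matches an activity iff it contains at least one of the
activity's terms (single tokens, or adjacent token bigrams for two-word
terms); one status may match several activities.  Per activity, the mean
per-status sentiment of its matched statuses is standardized across
activities into z-scores (population-SD convention), the same form in
which experience-sampling studies report activity affect.  Means rather
than raw sums are standardized because sums scale with corpus size; the
raw sum is still reported.

Cohen's kappa quantifies agreement of the two raters who labelled the
activity terms; its two-sided p value uses the large-sample normal
approximation of kappa's standard error under independence.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .corpus import TokenizedCorpus
from .lexicons import ActivityLexicon

__all__ = [
    "match_activity_statuses",
    "activity_z_scores",
    "ActivityResult",
    "cohens_kappa",
    "kappa_from_table",
    "load_default_activity_lexicon",
]


def load_default_activity_lexicon() -> ActivityLexicon:
    """Packaged activity lexicon (synthetic stand-in, with rater labels)."""
    path = resources.files("swbtext.data") / "activity_terms_synthetic.csv"
    with resources.as_file(path) as p:
        return ActivityLexicon.from_csv(p)


def match_activity_statuses(
    tok: TokenizedCorpus, lexicon: ActivityLexicon
) -> dict[str, np.ndarray]:
    """Map each activity to the (sorted) indices of statuses mentioning it."""
    order = np.argsort(tok.token_status, kind="stable")
    status_of = tok.token_status[order]
    words = tok.vocab[tok.token_code[order]]
    # bigram text per adjacent token pair within the same status
    same = np.zeros(len(words), dtype=bool)
    if len(words) > 1:
        same[:-1] = status_of[1:] == status_of[:-1]
    out: dict[str, np.ndarray] = {}
    word_arr = words.astype(object)
    for name in lexicon.names:
        hit = np.zeros(len(words), dtype=bool)
        for term in lexicon.activities[name]:
            parts = term.split()
            if len(parts) == 1:
                hit |= word_arr == parts[0]
            elif len(parts) == 2:
                pair = same & (word_arr == parts[0])
                pair[:-1] &= word_arr[1:] == parts[1]
                hit |= pair
            else:
                raise ValueError(f"activity term too long (max bigram): {term!r}")
        out[name] = np.unique(status_of[hit])
    return out


@dataclass(frozen=True)
class ActivityResult:
    activity: str
    n_statuses: int
    sentiment_sum: float
    mean_sentiment: float
    z_score: float


def activity_z_scores(
    matches: dict[str, np.ndarray], status_scores: np.ndarray
) -> pd.DataFrame:
    """Standardize per-activity mean sentiment into cross-activity z-scores.

    Only activities with at least one matched status are standardized
    (their z-scores have mean 0 and population SD 1); at least two such
    activities are required.
    """
    status_scores = np.asarray(status_scores, dtype=float)
    rows = []
    for name in sorted(matches):
        idx = matches[name]
        if len(idx) == 0:
            continue
        vals = status_scores[idx]
        rows.append((name, len(idx), float(vals.sum()), float(vals.mean())))
    if len(rows) < 2:
        raise ValueError(
            f"need >= 2 activities with matched statuses, got {len(rows)}"
        )
    df = pd.DataFrame(
        rows, columns=["activity", "n_statuses", "sentiment_sum", "mean_sentiment"]
    )
    means = df["mean_sentiment"].to_numpy()
    sd = means.std()  # population convention
    if sd == 0:
        df["z_score"] = 0.0
    else:
        df["z_score"] = (means - means.mean()) / sd
    return df


def kappa_from_table(table: np.ndarray) -> float:
    """Cohen's kappa from a square agreement (confusion) table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0 or table.shape[0] != table.shape[1]:
        raise ValueError("agreement table must be square and non-empty")
    po = np.trace(table) / n
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    pe = float(pa @ pb)
    if pe == 1.0:
        raise ValueError("both raters constant and identical: kappa undefined")
    return (po - pe) / (1.0 - pe)


def cohens_kappa(ratings_a, ratings_b) -> tuple[float, float]:
    """Chance-corrected agreement of two raters, with a two-sided p value.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e = sum_i p_a(i) p_b(i).  The p value tests kappa = 0 with the
    normal approximation var_0 = [p_e + p_e^2 - sum_i p_a(i) p_b(i)
    (p_a(i)+p_b(i))] / (n (1-p_e)^2).
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape:
        raise ValueError("rating vectors must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 rated items")
    labels = np.unique(np.concatenate([a, b]))
    k = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((k, k))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    kappa = kappa_from_table(table)
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    pe = float(pa @ pb)
    var0 = (pe + pe**2 - float((pa * pb * (pa + pb)).sum())) / (
        n * (1.0 - pe) ** 2
    )
    if var0 <= 0:
        return float(kappa), float("nan")
    from scipy import stats

    z = kappa / np.sqrt(var0)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(kappa), float(p)
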