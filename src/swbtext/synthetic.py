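"""Synthetic status corpora with planted ground truth.

Real per-user social-media data with linked well-being self-reports cannot
be redistributed, so every pipeline stage is exercised on generated
corpora that reproduce the statistical structure the analysis assumes:

* heavy-tailed per-user status counts (negative binomial) with the
  >= 30-status retention filter applied, leaving ~2000 of 2500 users at
  the defaults;
* a latent satisfaction-with-life (SWL) score per user, truncated normal
  on [1, 7] with mean 4.2; the observed self-report adds noise;
* positively skewed sentiment: the baseline probability that an emitted
  valence word is positive is ~0.6, rising weakly with latent SWL, so
  most users post more positive than negative statuses and mean sentiment
  correlates with SWL at r ~ 0.2;
* a truncated word-topic table in which some words live in exactly one
  topic (p(t|w) = 1) and others are shared across several topics with
  small probabilities — the truncation pathology the two topic scorers
  treat differently;
* ten "informative" topics whose usage propensity rises with latent SWL,
  carrying most of the recoverable signal;
* a CES-D depression score loading negatively on latent SWL, on the
  person's trait positivity and weakly on topical interests, emitted for
  a subset of users (0-60 scale by default; the range is configurable);
* activity mentions whose co-occurring valence words are shifted per
  activity (e.g. mentions of death/disease skew strongly negative).

Raw status text includes emoticons, hyperlinks, digits and stray
punctuation so the cleaning stage is genuinely exercised; after
preprocessing the emitted tokens are recovered exactly.  A single seed
fans out to per-stage seeds through ``numpy.random.SeedSequence``, so
identical seeds give byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .activities import load_default_activity_lexicon
from .corpus import (
    UserCorpus,
    UserDocument,
    read_outcomes,
    read_statuses,
    write_outcomes,
    write_statuses,
)
from .lexicons import (
    MAX_WORDS_PER_TOPIC,
    ActivityLexicon,
    CategoryLexicon,
    TopicTable,
    ValenceLexicon,
)

__all__ = [
    "GenConfig",
    "GroundTruth",
    "SyntheticData",
    "GenerationError",
    "generate_lexicon",
    "generate_topic_table",
    "generate_category_lexicon",
    "generate_users",
    "generate_dataset",
    "sample_document",
    "write_corpus",
    "read_corpus",
]


class GenerationError(RuntimeError):
    pass


#: Per-activity shift of the positive-valence emission probability for
#: statuses mentioning that activity (qualitative ordering of the
#: experience-sampling comparison: worship/holidays high, death low).
ACTIVITY_VALENCE_SHIFT = {
    "religion": 0.15,
    "holiday": 0.12,
    "talk_to_friend": 0.10,
    "chores": 0.08,
    "family": 0.06,
    "meal": 0.06,
    "school": -0.10,
    "maths": -0.12,
    "death_disease": -0.25,
}

_POS_SMILEYS = (":-)", ":)", "=)")
_NEG_SMILEYS = (":-(", ":(")


@dataclass(frozen=True)
class GenConfig:
    """Generator conditions (defaults are the package's study conditions)."""

    n_users: int = 2500
    mean_statuses: float = 60.0
    nb_dispersion: float = 3.0
    min_statuses: int = 30
    swl_mean: float = 4.2
    swl_sd: float = 1.3
    noise_sd: float = 0.5          # self-report noise (short-term test-retest ~0.87)
    n_topics: int = 200
    words_per_topic: int = 20
    n_informative_topics: int = 10
    topic_effect: float = 0.45     # log-propensity shift per SWL z-unit
    topic_noise: float = 0.25      # user-level topical-interest slack (log scale)
    affect_effect: float = 0.02    # positive-emission slope per SWL z-unit
    affect_noise: float = 0.08     # user-level slack around that slope
    base_positive: float = 0.60
    valence_rate: float = 0.06
    smiley_rate: float = 0.01
    topic_rate: float = 0.18
    n_pos_words: int = 150
    n_neg_words: int = 150
    n_categories: int = 66
    n_responsive_categories: int = 6
    responsive_pool_size: int = 25
    cat_effect: float = 0.08       # responsive-category tilt per SWL z-unit
    responsive_rate: float = 0.15  # share of filler tokens from responsive pools
    n_filler_words: int = 600
    cesd_slope: float = -2.4
    cesd_affect_slope: float = -1.2  # CES-D loading per SD of the positivity trait
    cesd_topic_slope: float = -0.4  # CES-D loading per SD of topical slack
    cesd_noise: float = 10.0
    cesd_intercept: float = 30.0
    cesd_fraction: float = 0.19
    cesd_range: tuple[float, float] = (0.0, 60.0)
    activity_rate: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative_topics > self.n_topics:
            raise ValueError("n_informative_topics exceeds n_topics")
        if self.words_per_topic > MAX_WORDS_PER_TOPIC:
            raise ValueError(f"words_per_topic > {MAX_WORDS_PER_TOPIC}")
        if self.min_statuses < 1:
            raise ValueError("min_statuses must be >= 1")
        if self.cesd_slope >= 0:
            raise ValueError("cesd_slope must be negative")
        for name in ("mean_statuses", "swl_sd", "noise_sd", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-user truth: latent SWL, self-report, CES-D, emission prob."""

    users: pd.DataFrame  # user_id, latent_swl, swl_report, cesd, p_positive
    informative_topics: tuple[int, ...]

    @property
    def outcomes(self) -> pd.DataFrame:
        """Observable self-report table ``user_id,swl,cesd``."""
        out = self.users[["user_id", "swl_report", "cesd"]].copy()
        return out.rename(columns={"swl_report": "swl"})


@dataclass(frozen=True)
class SyntheticData:
    config: GenConfig
    lexicon: ValenceLexicon
    table: TopicTable
    categories: CategoryLexicon
    activities: ActivityLexicon
    corpus: UserCorpus
    truth: GroundTruth


# ---------------------------------------------------------------------------
# word pools

_ONSETS = "b bl br d dr f fl g gr k kl l m n p pr r s sk sl st t tr v w z".split()
_VOWELS = "a e i o u ai ea ou".split()


def _pseudo_words(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    """Distinct pronounceable pseudo-words, avoiding ``taken``."""
    out: list[str] = []
    seen = set(taken)
    while len(out) < n:
        syls = rng.integers(2, 4)
        w = "".join(
            _ONSETS[rng.integers(len(_ONSETS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(syls)
        )
        if w not in seen:
            seen.add(w)
            out.append(w)
    return out


_RESERVED = {"happyface", "sadface"}


def generate_lexicon(n_pos: int, n_neg: int, seed: int) -> ValenceLexicon:
    """Valence lexicon with n_pos +1 words and n_neg -1 words.

    The reserved emoticon tokens ``happyface`` (+1) and ``sadface`` (-1)
    are always included; the remaining words are distinct pseudo-words, so
    no word can carry both signs.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(seed)
    words = _pseudo_words(rng, n_pos + n_neg - 2, _RESERVED)
    pos = ["happyface"] + words[: n_pos - 1]
    neg = ["sadface"] + words[n_pos - 1 :]
    val = {w: 1 for w in pos}
    val.update({w: -1 for w in neg})
    return ValenceLexicon(val)


def generate_topic_table(
    n_topics: int, words_per_topic: int, seed: int, taken: set[str] | None = None
) -> TopicTable:
    """Truncated topic table with planted truncation pathologies.

    Roughly one sixth of the word slots hold *shared* words listed under
    2-6 topics with small p(t|w) values summing to < 1; every remaining
    slot holds a word exclusive to its topic, carrying p(t|w) = 1 exactly
    as truncation forces in the published-table situation.
    """
    if words_per_topic > MAX_WORDS_PER_TOPIC:
        raise ValueError(f"words_per_topic > {MAX_WORDS_PER_TOPIC}")
    if n_topics < 1 or words_per_topic < 1:
        raise ValueError("need at least one topic and one word per topic")
    rng = np.random.default_rng(seed)
    capacity = {t: words_per_topic for t in range(n_topics)}
    topics: dict[int, list[tuple[str, float]]] = {t: [] for t in range(n_topics)}
    taken = set(taken or ()) | _RESERVED

    n_shared = (n_topics * words_per_topic) // 6 if n_topics > 1 else 0
    shared_words = _pseudo_words(rng, n_shared, taken)
    taken.update(shared_words)
    for word in shared_words:
        open_topics = [t for t, c in capacity.items() if c > 0]
        if len(open_topics) < 2:
            break
        k = int(rng.integers(2, min(6, len(open_topics)) + 1))
        chosen = rng.choice(open_topics, size=k, replace=False)
        total = rng.uniform(0.5, 0.95)
        probs = rng.dirichlet(np.ones(k)) * total
        probs = np.clip(probs, 1e-3, None)
        for t, p in zip(chosen, probs):
            topics[int(t)].append((word, float(p)))
            capacity[int(t)] -= 1

    n_exclusive = sum(capacity.values())
    exclusive_words = iter(_pseudo_words(rng, n_exclusive, taken))
    for t in range(n_topics):
        while capacity[t] > 0:
            topics[t].append((next(exclusive_words), 1.0))
            capacity[t] -= 1
    return TopicTable({t: tuple(v) for t, v in topics.items()})


def _responsive_pools(
    filler_words: list[str], n_pools: int, pool_size: int
) -> list[list[str]]:
    """Leading slices of the filler vocabulary reserved for the
    SWL-responsive categories (shared convention between the category
    lexicon and the token emitter)."""
    need = n_pools * pool_size
    if len(filler_words) < need:
        raise ValueError(
            f"filler vocabulary too small for {n_pools} responsive pools "
            f"({len(filler_words)} < {need})"
        )
    return [
        filler_words[i * pool_size : (i + 1) * pool_size] for i in range(n_pools)
    ]


def generate_category_lexicon(
    cfg: GenConfig,
    lexicon: ValenceLexicon,
    table: TopicTable,
    informative_topics: tuple[int, ...],
    filler_words: list[str],
    seed: int,
) -> CategoryLexicon:
    """LIWC-style category lexicon with realistic overlap structure.

    ``posemo``/``negemo`` sample the valence lexicon; the SWL-responsive
    filler pools become categories of their own (closed-vocabulary signal
    the topic table does not carry); a handful of topic-linked categories
    borrow words from (partly informative) topics; the remainder sample
    neutral filler words.
    """
    n_categories = cfg.n_categories
    if n_categories < 2:
        raise ValueError("need at least posemo/negemo")
    rng = np.random.default_rng(seed)

    def _sample(pool, k):
        pool = sorted(pool)
        k = min(k, len(pool))
        return frozenset(rng.choice(pool, size=k, replace=False))

    cats: dict[str, frozenset[str]] = {
        "posemo": _sample(lexicon.positive, 30),
        "negemo": _sample(lexicon.negative, 30),
    }
    nxt = 3
    n_resp = min(cfg.n_responsive_categories, n_categories - 2)
    for pool in _responsive_pools(
        filler_words, n_resp, cfg.responsive_pool_size
    ):
        cats[f"cat{nxt:02d}"] = frozenset(pool)
        nxt += 1
    n_linked = min(8, n_categories - nxt + 1)
    tids = table.topic_ids
    for i in range(n_linked):
        if i < len(informative_topics):
            base = informative_topics[i]
        else:
            base = tids[int(rng.integers(len(tids)))]
        extra = tids[int(rng.integers(len(tids)))]
        pool = {w for w, _ in table.topics[base]} | {
            w for w, _ in table.topics[extra]
        }
        cats[f"cat{nxt:02d}"] = _sample(pool, 20)
        nxt += 1
    plain_filler = filler_words[cfg.n_responsive_categories * cfg.responsive_pool_size :]
    while nxt <= n_categories:
        cats[f"cat{nxt:02d}"] = _sample(plain_filler, 25)
        nxt += 1
    return CategoryLexicon(cats)


# ---------------------------------------------------------------------------
# user / corpus generation


def _truncnorm(rng, n, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_users(
    cfg: GenConfig,
    lexicon: ValenceLexicon,
    table: TopicTable,
    activities: ActivityLexicon | None = None,
    filler_words: list[str] | None = None,
    seed: int | None = None,
) -> tuple[UserCorpus, GroundTruth]:
    """Generate the retained user corpus and its planted ground truth.

    See the module docstring for the emission model.  Raises
    :class:`GenerationError` if the >= ``min_statuses`` retention filter
    removes every drawn user.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pos_words = np.array(sorted(lexicon.positive), dtype=object)
    neg_words = np.array(sorted(lexicon.negative), dtype=object)
    if filler_words is None:
        filler_words = _pseudo_words(
            rng, cfg.n_filler_words, set(lexicon.valence) | table.vocabulary
        )
    filler = np.array(filler_words, dtype=object)

    # --- users ------------------------------------------------------------
    latent = _truncnorm(rng, cfg.n_users, cfg.swl_mean, cfg.swl_sd, 1.0, 7.0)
    p_nb = cfg.nb_dispersion / (cfg.nb_dispersion + cfg.mean_statuses)
    counts = rng.negative_binomial(cfg.nb_dispersion, p_nb, size=cfg.n_users)
    keep = counts >= cfg.min_statuses
    if not keep.any():
        raise GenerationError(
            f"retention filter (min_statuses={cfg.min_statuses}) removed all "
            f"{cfg.n_users} users; raise mean_statuses"
        )
    user_ids = np.array([f"u{i:05d}" for i in np.flatnonzero(keep)], dtype=object)
    latent = latent[keep]
    counts = counts[keep].astype(np.int64)
    nk = len(user_ids)

    z = (latent - cfg.swl_mean) / cfg.swl_sd
    # trait positivity: weak SWL link plus independent person-level slack
    affect_trait = cfg.affect_effect * z + rng.normal(0.0, cfg.affect_noise, nk)
    affect_std = affect_trait / np.hypot(cfg.affect_effect, cfg.affect_noise)
    p_pos = np.clip(cfg.base_positive + affect_trait, 0.05, 0.95)

    # per-user topical-interest propensity: SWL-linked plus independent slack
    theta = cfg.topic_effect * z + rng.normal(0.0, cfg.topic_noise, nk)
    eta_std = (theta - cfg.topic_effect * z) / cfg.topic_noise

    ninf = cfg.n_informative_topics
    inf_ids = np.arange(ninf)
    noninf_ids = np.arange(ninf, cfg.n_topics)
    if ninf and len(noninf_ids):
        w_inf = ninf * np.exp(theta)
        p_inf_user = w_inf / (w_inf + len(noninf_ids))
    elif ninf:
        p_inf_user = np.ones(nk)
    else:
        p_inf_user = np.zeros(nk)

    # flattened topic word lists for vectorized word draws
    tids = table.topic_ids
    topic_words = [np.array([w for w, _ in table.topics[t]], dtype=object) for t in tids]
    t_lens = np.array([len(tw) for tw in topic_words])
    t_offsets = np.concatenate([[0], np.cumsum(t_lens[:-1])]) if tids else np.array([0])
    t_flat = (
        np.concatenate(topic_words) if tids else np.empty(0, dtype=object)
    )

    # --- statuses ---------------------------------------------------------
    S = int(counts.sum())
    status_user = np.repeat(np.arange(nk), counts)
    comp = rng.choice(3, size=S, p=[0.11, 0.65, 0.24])
    lengths = np.select(
        [comp == 0, comp == 1, comp == 2],
        [
            rng.integers(1, 4, size=S),
            rng.integers(4, 21, size=S),
            rng.integers(21, 36, size=S),
        ],
    ).astype(np.int64)

    act_names: list[str] = []
    single_terms: list[np.ndarray] = []
    if activities is not None and cfg.activity_rate > 0:
        for name in activities.names:
            terms = [t for t in activities.activities[name] if " " not in t]
            if terms:
                act_names.append(name)
                single_terms.append(np.array(terms, dtype=object))
    if act_names:
        is_act = rng.random(S) < cfg.activity_rate
        act_idx = rng.integers(0, len(act_names), size=S)
        shifts = np.array(
            [ACTIVITY_VALENCE_SHIFT.get(n, 0.0) for n in act_names]
        )
        status_shift = np.where(is_act, shifts[act_idx], 0.0)
    else:
        is_act = np.zeros(S, dtype=bool)
        act_idx = np.zeros(S, dtype=np.int64)
        status_shift = np.zeros(S)

    # --- tokens -----------------------------------------------------------
    T = int(lengths.sum())
    token_status = np.repeat(np.arange(S), lengths)
    token_user = status_user[token_status]

    u = rng.random(T)
    vr, sr, tr = cfg.valence_rate, cfg.smiley_rate, cfg.topic_rate
    is_val = u < vr
    is_smiley = (u >= vr) & (u < vr + sr)
    is_topic = (u >= vr + sr) & (u < vr + sr + tr)
    is_fill = ~(is_val | is_smiley | is_topic)

    p_eff = np.clip(p_pos[token_user] + status_shift[token_status], 0.02, 0.98)
    positive = rng.random(T) < p_eff

    n_resp = cfg.n_responsive_categories
    resp_take = n_resp * cfg.responsive_pool_size
    plain_filler = filler[resp_take:] if len(filler) > resp_take else filler

    words = np.empty(T, dtype=object)
    fill_idx = np.flatnonzero(is_fill)
    if n_resp and len(filler) > resp_take and cfg.responsive_rate > 0:
        pools = [
            np.array(p, dtype=object)
            for p in _responsive_pools(list(filler), n_resp, cfg.responsive_pool_size)
        ]
        signs = np.array([1.0 if c % 2 == 0 else -1.0 for c in range(n_resp)])
        logits = cfg.cat_effect * np.outer(z, signs)  # (nk, n_resp)
        pw = np.exp(logits)
        pw /= pw.sum(axis=1, keepdims=True)
        cum = np.cumsum(pw, axis=1)
        resp = rng.random(len(fill_idx)) < cfg.responsive_rate
        resp_tok = fill_idx[resp]
        u_pool = rng.random(len(resp_tok))
        pool_idx = (u_pool[:, None] > cum[token_user[resp_tok]]).sum(axis=1)
        pool_idx = np.minimum(pool_idx, n_resp - 1)
        within = rng.integers(0, cfg.responsive_pool_size, len(resp_tok))
        pool_flat = np.concatenate(pools)
        words[resp_tok] = pool_flat[
            pool_idx * cfg.responsive_pool_size + within
        ]
        plain_tok = fill_idx[~resp]
    else:
        plain_tok = fill_idx
    words[plain_tok] = plain_filler[
        rng.integers(0, len(plain_filler), len(plain_tok))
    ]
    vp = is_val & positive
    vn = is_val & ~positive
    words[vp] = pos_words[rng.integers(0, len(pos_words), vp.sum())]
    words[vn] = neg_words[rng.integers(0, len(neg_words), vn.sum())]
    sp = is_smiley & positive
    sn = is_smiley & ~positive
    pos_sm = np.array(_POS_SMILEYS, dtype=object)
    neg_sm = np.array(_NEG_SMILEYS, dtype=object)
    words[sp] = pos_sm[rng.integers(0, len(pos_sm), sp.sum())]
    words[sn] = neg_sm[rng.integers(0, len(neg_sm), sn.sum())]
    if is_topic.any() and len(tids):
        nt = is_topic.sum()
        take_inf = rng.random(nt) < p_inf_user[token_user[is_topic]]
        tcode = np.empty(nt, dtype=np.int64)
        if ninf:
            tcode[take_inf] = inf_ids[rng.integers(0, ninf, take_inf.sum())]
        if len(noninf_ids):
            tcode[~take_inf] = noninf_ids[
                rng.integers(0, len(noninf_ids), (~take_inf).sum())
            ]
        else:
            tcode[~take_inf] = inf_ids[
                rng.integers(0, max(ninf, 1), (~take_inf).sum())
            ]
        widx = t_offsets[tcode] + rng.integers(0, t_lens[tcode])
        words[is_topic] = t_flat[widx]
    elif is_topic.any():
        words[is_topic] = filler[rng.integers(0, len(filler), is_topic.sum())]

    # plant one activity term at the start of each activity status
    starts = np.concatenate([[0], np.cumsum(lengths[:-1])])
    for j in np.flatnonzero(is_act):
        terms = single_terms[act_idx[j]]
        words[starts[j]] = terms[rng.integers(0, len(terms))]

    # --- raw text assembly (noise exercises the cleaning stage) -----------
    cap = rng.random(S) < 0.30
    bang = rng.random(S) < 0.10
    url = rng.random(S) < 0.08
    year = rng.random(S) < 0.05
    year_vals = rng.integers(2009, 2012, size=S)
    url_n = rng.integers(100, 1000, size=S)

    texts = []
    wl = words.tolist()
    for j in range(S):
        toks = wl[starts[j] : starts[j] + lengths[j]]
        if cap[j]:
            toks = [toks[0].capitalize(), *toks[1:]] if toks else toks
        s = " ".join(toks)
        if year[j]:
            s = f"{s} {year_vals[j]}"
        if url[j]:
            s = f"{s} http://pic.example.com/p{url_n[j]}"
        if bang[j]:
            s = s + "!!"
        texts.append(s)

    corpus = UserCorpus(
        pd.DataFrame(
            {"user_id": user_ids[status_user], "text": texts},
        ).astype({"user_id": str, "text": str})
    )

    # --- outcomes ---------------------------------------------------------
    swl_report = np.clip(latent + rng.normal(0.0, cfg.noise_sd, nk), 1.0, 7.0)
    cesd = (
        cfg.cesd_intercept
        + cfg.cesd_slope * (latent - cfg.swl_mean)
        + cfg.cesd_affect_slope * affect_std
        + cfg.cesd_topic_slope * eta_std
        + rng.normal(0.0, cfg.cesd_noise, nk)
    )
    cesd = np.clip(cesd, *cfg.cesd_range)
    has_cesd = rng.random(nk) < cfg.cesd_fraction
    cesd = np.where(has_cesd, cesd, np.nan)

    truth = GroundTruth(
        users=pd.DataFrame(
            {
                "user_id": user_ids,
                "latent_swl": latent,
                "swl_report": swl_report,
                "cesd": cesd,
                "p_positive": p_pos,
                "topic_propensity": theta,
            }
        ),
        informative_topics=tuple(int(t) for t in inf_ids),
    )
    return corpus, truth


def generate_dataset(cfg: GenConfig) -> SyntheticData:
    """Generate every resource and the corpus from one master seed.

    The master seed fans out to per-stage seeds (lexicon, topic table,
    categories, users) via ``SeedSequence``, so any stage can be re-run in
    isolation.
    """
    stage_seeds = [
        int(s.generate_state(1)[0] & 0x7FFFFFFF)
        for s in np.random.SeedSequence(cfg.seed).spawn(5)
    ]
    lexicon = generate_lexicon(cfg.n_pos_words, cfg.n_neg_words, stage_seeds[0])
    table = generate_topic_table(
        cfg.n_topics, cfg.words_per_topic, stage_seeds[1], taken=set(lexicon.valence)
    )
    filler = _pseudo_words(
        np.random.default_rng(stage_seeds[2]),
        cfg.n_filler_words,
        set(lexicon.valence) | table.vocabulary,
    )
    activities = load_default_activity_lexicon()
    categories = generate_category_lexicon(
        cfg,
        lexicon,
        table,
        tuple(range(cfg.n_informative_topics)),
        filler,
        stage_seeds[3],
    )
    corpus, truth = generate_users(
        cfg, lexicon, table, activities=activities, filler_words=filler,
        seed=stage_seeds[4],
    )
    return SyntheticData(cfg, lexicon, table, categories, activities, corpus, truth)


def sample_document(
    table: TopicTable, seed: int, n_tokens: int | None = None
) -> UserDocument:
    """Random user document over a topic table's vocabulary.

    Draws tokens from a few focal topics (mixing exclusive p=1 words and
    shared low-p words) plus off-table filler, reproducing the short,
    topically concentrated shape of status-update documents.  Used for the
    scorer-comparison fixtures.
    """
    rng = np.random.default_rng(seed)
    tids = table.topic_ids
    if n_tokens is None:
        n_tokens = int(rng.integers(20, 101))
    k = int(rng.integers(2, min(6, len(tids)) + 1))
    focal = rng.choice(tids, size=k, replace=False)
    tokens: list[str] = []
    for _ in range(n_tokens):
        r = rng.random()
        if r < 0.6:
            t = focal[rng.integers(0, k)]
            entries = table.topics[int(t)]
            tokens.append(entries[rng.integers(0, len(entries))][0])
        else:
            tokens.append(f"off{rng.integers(0, 50):02d}")
    n_statuses = max(1, n_tokens // 10)
    return UserDocument.from_token_lists(
        f"doc{seed}", [tokens[i::n_statuses] for i in range(n_statuses)]
    )


# ---------------------------------------------------------------------------
# on-disk round trip


def write_corpus(
    corpus: UserCorpus,
    truth: GroundTruth,
    directory: str | Path,
    *,
    lexicon: ValenceLexicon | None = None,
    table: TopicTable | None = None,
    categories: CategoryLexicon | None = None,
    activities: ActivityLexicon | None = None,
) -> dict[str, Path]:
    """Write corpus + outcomes (and any resources) in the documented formats.

    Returns the mapping of artifact name to path.  Round-trips losslessly
    through :func:`read_corpus` / the resource ``from_csv`` readers.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        probe = directory / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to directory {directory}: {exc}") from exc
    paths = {
        "statuses": directory / "statuses.tsv",
        "outcomes": directory / "outcomes.csv",
    }
    write_statuses(corpus, paths["statuses"])
    write_outcomes(truth.outcomes, paths["outcomes"])
    if lexicon is not None:
        paths["lexicon"] = directory / "valence_lexicon.csv"
        lexicon.to_csv(paths["lexicon"])
    if table is not None:
        paths["topics"] = directory / "topic_table.csv"
        table.to_csv(paths["topics"])
    if categories is not None:
        paths["categories"] = directory / "category_lexicon.csv"
        categories.to_csv(paths["categories"])
    if activities is not None:
        paths["activities"] = directory / "activity_lexicon.csv"
        activities.to_csv(paths["activities"])
    return paths


def read_corpus(directory: str | Path) -> tuple[UserCorpus, pd.DataFrame]:
    """Read back ``statuses.tsv`` and ``outcomes.csv`` from a directory."""
    directory = Path(directory)
    return (
        read_statuses(directory / "statuses.tsv"),
        read_outcomes(directory / "outcomes.csv"),
    )
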