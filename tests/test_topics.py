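"""Category counts and the two topic scorers on the truncated table."""

import numpy as np
import pandas as pd
import pytest

from swbtext.corpus import UserDocument
from swbtext.lexicons import CategoryLexicon, TopicTable
from swbtext.topics import (
    assemble_feature_matrix,
    category_counts,
    category_matrix,
    compare_scoring_ratio,
    topic_probability_matrix,
    topic_probability_scores,
    topic_wordcount_matrix,
    topic_wordcount_scores,
)


def doc_from(tokens, user_id="u"):
    return UserDocument.from_token_lists(user_id, [list(tokens)])


def brute_wordcount(doc, table):
    scores = {t: 0.0 for t in table.topic_ids}
    for t in table.topic_ids:
        for word, _p in table.topics[t]:
            for tok, cnt in doc.counts.items():
                if tok == word:
                    scores[t] += cnt
    return scores


def brute_probability(doc, table):
    total = doc.total_words
    scores = {t: 0.0 for t in table.topic_ids}
    for t in table.topic_ids:
        for word, p in table.topics[t]:
            for tok, cnt in doc.counts.items():
                if tok == word:
                    scores[t] += p * cnt / total
    return scores


def test_exclusive_word_scores_its_single_topic(winter_table):
    doc = doc_from(["driveway"])
    wc = topic_wordcount_scores(doc, winter_table)
    assert wc[1] == 1 and wc.drop(1).eq(0).all()
    prob = topic_probability_scores(doc, winter_table)
    assert prob[1] == pytest.approx(1.0)  # p(t|w)=1 forced by truncation


def test_shared_word_scores_all_its_topics(winter_table):
    doc = doc_from(["ice"])
    wc = topic_wordcount_scores(doc, winter_table)
    assert wc.eq(1).all() and len(wc) == 6  # same +1 in all six topics


def test_probability_score_halves_with_unlisted_word(winter_table):
    prob = topic_probability_scores(doc_from(["ice", "x"]), winter_table)
    assert prob[1] == pytest.approx(0.049 / 2)


def test_empty_document(winter_table):
    empty = UserDocument.from_token_lists("u", [[]])
    assert topic_wordcount_scores(empty, winter_table).eq(0).all()
    with pytest.raises(ValueError, match="empty"):
        topic_probability_scores(empty, winter_table)


def test_wordcount_additivity(winter_table, rng):
    vocab = ["driveway", "ice", "snow", "w2", "w3", "off"]
    for _ in range(20):
        a = doc_from(rng.choice(vocab, size=8))
        b = doc_from(rng.choice(vocab, size=5))
        ab = UserDocument("u", a.counts + b.counts, 2)
        total = topic_wordcount_scores(ab, winter_table)
        assert np.allclose(
            total,
            topic_wordcount_scores(a, winter_table)
            + topic_wordcount_scores(b, winter_table),
        )


def test_probability_scale_invariance(winter_table):
    from collections import Counter

    doc = doc_from(["driveway", "ice", "snow", "off"])
    doubled = UserDocument("u", Counter({w: 2 * c for w, c in doc.counts.items()}), 2)
    assert np.allclose(
        topic_probability_scores(doc, winter_table),
        topic_probability_scores(doubled, winter_table),
    )
    assert np.allclose(
        2 * topic_wordcount_scores(doc, winter_table),
        topic_wordcount_scores(doubled, winter_table),
    )


def test_exclusive_only_table_probabilities_bounded():
    table = TopicTable({1: (("a", 1.0), ("b", 1.0)), 2: (("c", 1.0),)})
    doc = doc_from(["a", "b", "c", "zz"])
    assert topic_probability_scores(doc, table).sum() <= 1.0 + 1e-12


def test_both_scorers_match_brute_force(winter_table, rng):
    vocab = ["driveway", "ice", "snow", "w2", "w4", "off", "qq"]
    for _ in range(200):
        doc = doc_from(rng.choice(vocab, size=rng.integers(1, 15)))
        wc = topic_wordcount_scores(doc, winter_table)
        assert {t: wc[t] for t in wc.index} == brute_wordcount(doc, winter_table)
        prob = topic_probability_scores(doc, winter_table)
        brute = brute_probability(doc, winter_table)
        assert all(abs(prob[t] - brute[t]) <= 1e-12 for t in prob.index)


def test_matrix_paths_match_per_document_functions(small_data, small_tok):
    wc = topic_wordcount_matrix(small_tok, small_data.table, normalize=False)
    prob = topic_probability_matrix(small_tok, small_data.table)
    cats = category_matrix(small_tok, small_data.categories, normalize=False)
    docs = {d.user_id: d for d in small_tok.user_documents()}
    for uid in small_tok.user_ids[:5]:
        doc = docs[uid]
        assert np.allclose(
            wc.loc[uid], topic_wordcount_scores(doc, small_data.table)
        )
        assert np.allclose(
            prob.loc[uid], topic_probability_scores(doc, small_data.table), atol=1e-12
        )
        assert np.allclose(
            cats.loc[uid],
            category_counts(doc, small_data.categories, normalize=False),
        )


def test_category_counts_normalized_by_status_count():
    lex = CategoryLexicon({"negemo": frozenset({"sad"})})
    doc = UserDocument.from_token_lists("u", [["sad", "sad"], ["run"]])
    assert category_counts(doc, lex)["negemo"] == pytest.approx(1.0)  # 2 hits / 2 statuses
    assert category_counts(doc, lex, normalize=False)["negemo"] == 2
    assert category_counts(doc, CategoryLexicon({"x": frozenset({"zz"})}))["x"] == 0


def test_compare_scoring_ratio_symmetric_case():
    table = TopicTable({1: (("a", 0.3),), 2: (("b", 0.3),)})
    doc = doc_from(["a", "b"])
    r_wc, r_prob = compare_scoring_ratio(doc, table)
    assert r_wc == pytest.approx(1.0)
    assert r_prob == pytest.approx(1.0)


def test_compare_scoring_ratio_truncation_pathology():
    # exclusive word with p=1 vs shared word with small p: the probability
    # scorer stretches the spread, the word-count scorer does not
    table = TopicTable({1: (("solo", 1.0),), 2: (("common", 0.05),)})
    doc = doc_from(["solo", "common"])
    r_wc, r_prob = compare_scoring_ratio(doc, table)
    assert r_wc == pytest.approx(1.0)
    assert r_prob == pytest.approx(20.0)
    assert r_wc <= r_prob


def test_compare_scoring_ratio_needs_two_positive(winter_table):
    with pytest.raises(ValueError, match="positive"):
        compare_scoring_ratio(doc_from(["driveway"]), winter_table)


def test_assemble_feature_matrix(small_data, small_tok):
    from swbtext.affect import affect_feature_frame

    aff = affect_feature_frame(small_tok, small_data.lexicon)
    cats = category_matrix(small_tok, small_data.categories)
    tops = topic_wordcount_matrix(small_tok, small_data.table)
    X = assemble_feature_matrix(aff, cats, tops)
    assert list(X.index) == sorted(small_tok.user_ids)
    assert X.shape[1] == 4 + cats.shape[1] + tops.shape[1]
    assert len(set(X.columns)) == X.shape[1]
    assert not X.isna().any().any()
    prefixes = {c.split(":")[0] for c in X.columns}
    assert prefixes == {"affect", "cat", "topic"}


def test_assemble_feature_matrix_user_mismatch(small_data, small_tok):
    from swbtext.affect import affect_feature_frame

    aff = affect_feature_frame(small_tok, small_data.lexicon)
    cats = category_matrix(small_tok, small_data.categories)
    tops = topic_wordcount_matrix(small_tok, small_data.table).iloc[1:]
    with pytest.raises(ValueError, match="user sets differ"):
        assemble_feature_matrix(aff, cats, tops)
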