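"""Synthetic corpus generator: planted structure and round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from swbtext import GenConfig
from swbtext.synthetic import (
    GenerationError,
    generate_dataset,
    generate_lexicon,
    generate_topic_table,
    generate_users,
    read_corpus,
    sample_document,
    write_corpus,
)


class TestLexiconGeneration:
    def test_minimal_case_is_exactly_the_reserved_tokens(self):
        lex = generate_lexicon(1, 1, seed=0)
        assert lex.valence == {"happyface": 1, "sadface": -1}

    def test_cardinality_and_disjoint_signs(self):
        lex = generate_lexicon(100, 100, seed=1)
        assert len(lex.valence) == 200
        assert len(lex.positive) == 100 and len(lex.negative) == 100
        assert not lex.positive & lex.negative

    def test_deterministic(self):
        assert generate_lexicon(40, 30, seed=9).valence == generate_lexicon(
            40, 30, seed=9
        ).valence

    def test_rejects_empty_sides(self):
        with pytest.raises(ValueError):
            generate_lexicon(0, 5, seed=0)


class TestTopicTableGeneration:
    def test_single_topic_single_word(self):
        table = generate_topic_table(1, 1, seed=0)
        ((word, p),) = table.topics[0]
        assert p == 1.0

    def test_exclusive_words_have_unit_probability(self):
        table = generate_topic_table(20, 10, seed=3)
        for word in table.vocabulary:
            hits = table.word_topics(word)
            if len(hits) == 1:
                assert hits[0][1] == 1.0

    def test_has_shared_words_with_subunit_mass(self):
        table = generate_topic_table(20, 10, seed=3)
        shared = [w for w in table.vocabulary if len(table.word_topics(w)) > 1]
        assert shared  # truncation pathology planted
        for w in shared:
            total = sum(p for _, p in table.word_topics(w))
            assert total <= 1.0
            assert all(p < 1.0 for _, p in table.word_topics(w))

    def test_word_planted_in_k_topics_appears_k_times(self):
        table = generate_topic_table(30, 15, seed=5)
        by_k = {}
        for w in table.vocabulary:
            by_k.setdefault(len(table.word_topics(w)), w)
        k = max(by_k)
        assert k >= 2
        word = by_k[k]
        listed = sum(
            1 for entries in table.topics.values() for w, _ in entries if w == word
        )
        assert listed == k

    def test_capacity_respected(self):
        table = generate_topic_table(25, 7, seed=1)
        assert all(len(v) <= 7 for v in table.topics.values())


class TestUserGeneration:
    def test_retention_filter(self, small_data, small_config):
        counts = small_data.corpus.n_statuses
        assert (counts >= small_config.min_statuses).all()

    def test_all_users_filtered_is_explicit_error(self):
        cfg = GenConfig(n_users=30, mean_statuses=1.0, min_statuses=30, seed=0)
        lex = generate_lexicon(5, 5, seed=0)
        table = generate_topic_table(5, 5, seed=0)
        with pytest.raises(GenerationError, match="retention"):
            generate_users(cfg, lex, table)

    def test_identical_seeds_identical_corpora(self, small_config):
        a = generate_dataset(small_config)
        b = generate_dataset(small_config)
        pd.testing.assert_frame_equal(a.corpus.statuses, b.corpus.statuses)
        pd.testing.assert_frame_equal(a.truth.users, b.truth.users)

    def test_affect_link_positive(self, rng):
        cfg = GenConfig(
            n_users=400,
            mean_statuses=40,
            affect_effect=0.1,
            affect_noise=0.01,
            n_topics=20,
            n_informative_topics=2,
            n_categories=10,
            n_pos_words=40,
            n_neg_words=40,
            n_filler_words=300,
            seed=11,
        )
        data = generate_dataset(cfg)
        from swbtext.affect import affect_feature_frame

        tok = data.corpus.tokenize()
        aff = affect_feature_frame(tok, data.lexicon)
        truth = data.truth.users.set_index("user_id")
        r = stats.pearsonr(
            aff["mean_sentiment"], truth.loc[aff.index, "latent_swl"]
        ).statistic
        assert r > 0.3

    def test_cesd_negatively_correlated(self, small_data):
        users = small_data.truth.users.dropna(subset=["cesd"])
        r = stats.pearsonr(users["swl_report"], users["cesd"]).statistic
        assert r < 0

    def test_informative_topics_exist_in_table(self, small_data):
        tids = set(small_data.table.topic_ids)
        assert set(small_data.truth.informative_topics) <= tids


@pytest.fixture(scope="module")
def midsize_data():
    """~1000 retained users at otherwise default conditions."""
    return generate_dataset(GenConfig(n_users=1250, seed=42))


class TestPopulationStructure:
    def test_most_users_more_positive_than_negative(self, midsize_data):
        from swbtext.affect import affect_feature_frame

        tok = midsize_data.corpus.tokenize()
        aff = affect_feature_frame(tok, midsize_data.lexicon)
        assert len(aff) > 900
        assert (aff["pos_freq"] > aff["neg_freq"]).mean() > 0.75

    def test_affect_swl_correlation_signs(self, midsize_data):
        from swbtext.affect import affect_feature_frame

        tok = midsize_data.corpus.tokenize()
        aff = affect_feature_frame(tok, midsize_data.lexicon)
        truth = midsize_data.truth.users.set_index("user_id")
        swl = truth.loc[aff.index, "swl_report"]
        assert stats.pearsonr(aff["mean_sentiment"], swl).statistic > 0
        assert stats.pearsonr(aff["neg_freq"], swl).statistic < 0

    def test_swl_mean_near_configured_population_mean(self, midsize_data):
        assert midsize_data.truth.users["latent_swl"].mean() == pytest.approx(
            4.2, abs=0.15
        )


class TestRoundTrip:
    def test_write_then_read_preserves_corpus(self, small_data, tmp_path):
        paths = write_corpus(
            small_data.corpus,
            small_data.truth,
            tmp_path / "out",
            lexicon=small_data.lexicon,
            table=small_data.table,
            categories=small_data.categories,
            activities=small_data.activities,
        )
        corpus, outcomes = read_corpus(tmp_path / "out")
        pd.testing.assert_frame_equal(
            corpus.statuses, small_data.corpus.statuses
        )
        assert len(outcomes) == len(small_data.truth.users)
        from swbtext.lexicons import TopicTable, ValenceLexicon

        assert ValenceLexicon.from_csv(paths["lexicon"]).valence == small_data.lexicon.valence
        back = TopicTable.from_csv(paths["topics"])
        assert back.topics.keys() == small_data.table.topics.keys()
        for t in back.topics:
            assert [w for w, _ in back.topics[t]] == [
                w for w, _ in small_data.table.topics[t]
            ]

    def test_empty_corpus_writes_valid_files(self, tmp_path):
        from swbtext.corpus import UserCorpus
        from swbtext.synthetic import GroundTruth

        empty = UserCorpus(pd.DataFrame(columns=["user_id", "text"]).astype(str))
        truth = GroundTruth(
            users=pd.DataFrame(
                columns=["user_id", "latent_swl", "swl_report", "cesd", "p_positive"]
            ),
            informative_topics=(),
        )
        write_corpus(empty, truth, tmp_path / "empty")
        corpus, outcomes = read_corpus(tmp_path / "empty")
        assert len(corpus) == 0 and len(outcomes) == 0

    def test_byte_identical_reruns(self, small_config, tmp_path):
        a = generate_dataset(small_config)
        b = generate_dataset(small_config)
        write_corpus(a.corpus, a.truth, tmp_path / "a")
        write_corpus(b.corpus, b.truth, tmp_path / "b")
        assert (tmp_path / "a" / "statuses.tsv").read_bytes() == (
            tmp_path / "b" / "statuses.tsv"
        ).read_bytes()
        assert (tmp_path / "a" / "outcomes.csv").read_bytes() == (
            tmp_path / "b" / "outcomes.csv"
        ).read_bytes()


def test_sample_document_hits_table_words(small_data):
    doc = sample_document(small_data.table, seed=0)
    listed = sum(
        cnt for w, cnt in doc.counts.items() if small_data.table.word_topics(w)
    )
    assert listed > 0
    assert doc.total_words >= 20
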