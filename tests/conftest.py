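import numpy as np
import pytest

from swbtext import GenConfig, TopicTable, ValenceLexicon
from swbtext.synthetic import generate_dataset


@pytest.fixture(scope="session")
def tiny_lexicon():
    return ValenceLexicon(
        {"love": 1, "good": 1, "happyface": 1, "bad": -1, "sadface": -1}
    )


@pytest.fixture(scope="session")
def winter_table():
    """Truncated-table fixture around the winter-traffic example: one word
    exclusive to a topic (p=1), one word shared across six topics."""
    topics = {
        1: (("driveway", 1.0), ("ice", 0.049), ("snow", 0.30)),
    }
    for tid in range(2, 7):
        topics[tid] = ((f"w{tid}", 1.0), ("ice", 0.05))
    return TopicTable(topics)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale generator settings for fast unit tests."""
    return GenConfig(
        n_users=260,
        mean_statuses=45.0,
        n_topics=40,
        n_informative_topics=5,
        n_categories=16,
        n_pos_words=60,
        n_neg_words=60,
        n_filler_words=400,
        cesd_fraction=0.6,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_tok(small_data):
    return small_data.corpus.tokenize()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
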