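import numpy as np
import pytest

from lexepi import (
    SimulationConfig,
    generate_counties,
    generate_lexicon,
    relative_frequencies,
    score_topics,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        n_counties=80,
        n_topics=8,
        vocab_size=300,
        words_per_county=2_000,
        predictive_topics={2: 0.5},
        mediator_topics={5: (0.6, 0.5)},
        control_effects={"unemployment": -0.2},
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(lexicon, corpus, covariates, outcome, truth) at test scale."""
    lexicon = generate_lexicon(small_config)
    corpus, covariates, outcome, truth = generate_counties(small_config, lexicon)
    return lexicon, corpus, covariates, outcome, truth


@pytest.fixture(scope="session")
def small_scores(small_dataset):
    lexicon, corpus, *_ = small_dataset
    return score_topics(relative_frequencies(corpus), lexicon)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
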