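"""Synthetic county corpora with planted structure.

Generates an LDA-style topic-word lexicon, county token counts drawn
from topic mixtures, socio-demographic covariates, and an outcome built
from known control effects, direct topic effects, and mediator paths, so
every pipeline stage can be tested against recorded ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .language_features import CountyCorpus, TopicLexicon

__all__ = ["SimulationConfig", "GroundTruth", "generate_lexicon", "generate_counties"]


@dataclass(frozen=True, kw_only=True)
class SimulationConfig:
    seed: int
    n_counties: int = 200
    n_topics: int = 50
    vocab_size: int = 2000
    words_per_county: int = 5_000
    min_words: int = 0
    # Dirichlet concentration for topic->word distributions (sparse topics)
    topic_word_concentration: float = 0.1
    # topic index -> standardized direct effect on the outcome
    predictive_topics: dict[int, float] = field(default_factory=dict)
    # topic index -> (a, b): SES->topic shift and topic->outcome effect
    mediator_topics: dict[int, tuple[float, float]] = field(default_factory=dict)
    # covariate name -> standardized effect on the outcome
    control_effects: dict[str, float] = field(default_factory=dict)
    outcome_noise_sd: float = 1.0
    # outcome is an affine map of the latent predictor to this scale
    outcome_mean: float = 25.0
    outcome_scale_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.n_counties < 2 or self.n_topics < 1 or self.vocab_size < 2:
            raise ValueError("counts must be positive (>=2 counties, >=2 words)")
        if self.words_per_county <= 0:
            raise ValueError("words_per_county must be positive")
        if self.words_per_county < self.min_words:
            raise ValueError(
                "words_per_county below min_words: generated counties would "
                "not pass the word-count filter"
            )
        effect_topics = set(self.predictive_topics) | set(self.mediator_topics)
        if not effect_topics <= set(range(self.n_topics)):
            raise ValueError("effect-bearing topic indices must lie in [0, n_topics)")
        if self.outcome_noise_sd < 0:
            raise ValueError("outcome_noise_sd must be non-negative")

    @classmethod
    def paper_scale(cls, seed: int, **overrides) -> "SimulationConfig":
        """Preset at the scale of the original study (slow)."""
        defaults = dict(
            n_counties=1384, n_topics=2000, vocab_size=20_000,
            words_per_county=40_000, min_words=40_000,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)

    def topic_id(self, k: int) -> str:
        return f"topic_{k:04d}"


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters and realized latent state, exactly as used."""

    ses: np.ndarray                      # latent socioeconomic factor
    topic_mixtures: np.ndarray           # county x topic usage
    predictive_topics: dict[int, float]
    mediator_topics: dict[int, tuple[float, float]]
    control_effects: dict[str, float]
    latent_outcome: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "ses": self.ses.tolist(),
            "topic_mixtures": self.topic_mixtures.tolist(),
            "predictive_topics": {str(k): v for k, v in self.predictive_topics.items()},
            "mediator_topics": {
                str(k): list(v) for k, v in self.mediator_topics.items()
            },
            "control_effects": dict(self.control_effects),
            "latent_outcome": self.latent_outcome.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _topic_word_distributions(config: SimulationConfig) -> np.ndarray:
    """K x V Dirichlet rows, one word distribution per topic.

    Drawn from a dedicated seeded stream so both the lexicon and the
    corpus generator reproduce the same distributions independently.
    """
    rng = np.random.default_rng([config.seed, 0])
    alpha = np.full(config.vocab_size, config.topic_word_concentration)
    return rng.dirichlet(alpha, size=config.n_topics)


def _word_id(w: int) -> str:
    return f"w{w:05d}"


def generate_lexicon(config: SimulationConfig) -> TopicLexicon:
    """P(topic | word) obtained by normalizing the topic->word Dirichlet
    draws across topics under a uniform topic prior; fully normalized."""
    phi = _topic_word_distributions(config)
    col_mass = phi.sum(axis=0)
    # every word receives positive mass from some topic almost surely,
    # but guard against underflow
    col_mass[col_mass == 0] = 1.0
    post = phi / col_mass  # K x V, columns sum to 1
    topic_ids = tuple(config.topic_id(k) for k in range(config.n_topics))
    entries: dict[str, dict[str, float]] = {}
    for w in range(config.vocab_size):
        entries[_word_id(w)] = {
            topic_ids[k]: float(post[k, w]) for k in range(config.n_topics)
            if post[k, w] > 0
        }
    return TopicLexicon(entries, topic_ids)


def _softmax(eta: np.ndarray) -> np.ndarray:
    e = np.exp(eta - eta.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def generate_counties(
    config: SimulationConfig, lexicon: TopicLexicon
) -> tuple[CountyCorpus, pd.DataFrame, pd.Series, GroundTruth]:
    """Generate (corpus, covariates, outcome, ground truth).

    A latent SES factor drives log income and graduation rates (so the
    pipeline's ses_index recovers it) and shifts mediator topics' mixture
    weights by their planted `a` path. Token counts are multinomial draws
    from each county's mixture composed with the topic->word
    distributions. The outcome combines control effects, direct topic
    effects, mediator `b` paths, and Gaussian noise, then is mapped
    affinely to a percentage-like scale.
    """
    if tuple(lexicon.topic_ids) != tuple(
        config.topic_id(k) for k in range(config.n_topics)
    ):
        raise ValueError("lexicon topics do not match the simulation config")
    rng = np.random.default_rng([config.seed, 1])
    N, K = config.n_counties, config.n_topics
    phi = _topic_word_distributions(config)

    ses = rng.standard_normal(N)

    # county topic mixtures: noisy base logits plus planted SES shifts
    eta = rng.normal(0.0, 0.5, size=(N, K))
    for k, (a, _b) in config.mediator_topics.items():
        eta[:, k] += a * ses
    theta = _softmax(eta)

    counts: dict[str, dict[str, int]] = {}
    county_ids = [f"c{i:04d}" for i in range(N)]
    word_probs = theta @ phi  # N x V
    for i, county in enumerate(county_ids):
        draw = rng.multinomial(config.words_per_county, word_probs[i])
        nz = np.flatnonzero(draw)
        counts[county] = {_word_id(w): int(draw[w]) for w in nz}
    corpus = CountyCorpus(counts)

    covariates = _generate_covariates(rng, ses, county_ids)

    linear = np.zeros(N)
    for name, coef in config.control_effects.items():
        if name not in covariates.columns:
            raise ValueError(f"control effect references unknown covariate {name!r}")
        linear += coef * _zscore(covariates[name].to_numpy())
    for k, effect in config.predictive_topics.items():
        linear += effect * _zscore(theta[:, k])
    for k, (_a, b) in config.mediator_topics.items():
        linear += b * _zscore(theta[:, k])
    linear += config.outcome_noise_sd * rng.standard_normal(N)

    outcome_values = config.outcome_mean + config.outcome_scale_sd * _zscore(linear)
    outcome = pd.Series(
        np.clip(outcome_values, 0.0, 100.0), index=county_ids, name="outcome"
    )
    outcome.index.name = "county_id"

    truth = GroundTruth(
        ses=ses,
        topic_mixtures=theta,
        predictive_topics=dict(config.predictive_topics),
        mediator_topics=dict(config.mediator_topics),
        control_effects=dict(config.control_effects),
        latent_outcome=linear,
    )
    return corpus, covariates, outcome, truth


def _generate_covariates(
    rng: np.random.Generator, ses: np.ndarray, county_ids: list[str]
) -> pd.DataFrame:
    """Covariates on census-like scales, income/education driven by SES."""
    N = len(ses)
    noise = lambda s: rng.normal(0.0, s, size=N)  # noqa: E731
    df = pd.DataFrame(index=pd.Index(county_ids, name="county_id"))
    df["log_income"] = 10.5 + 0.35 * ses + noise(0.12)
    df["hs_grad"] = np.clip(85.0 + 4.0 * ses + noise(1.5), 0, 100)
    df["college_grad"] = np.clip(28.0 + 5.0 * ses + noise(2.5), 0, 100)
    df["unemployment"] = np.clip(7.0 - 1.2 * ses + noise(0.9), 0, 100)
    df["pct_female"] = np.clip(50.0 + noise(1.2), 0, 100)
    df["pct_african_american"] = np.clip(9.0 - 1.5 * ses + np.abs(noise(6.0)), 0, 100)
    df["pct_hispanic"] = np.clip(8.0 + np.abs(noise(5.0)), 0, 100)
    df["pct_foreign_born"] = np.clip(4.0 + 1.0 * ses + np.abs(noise(3.0)), 0, 100)
    df["pct_married"] = np.clip(52.0 + 1.5 * ses + noise(3.0), 0, 100)
    age = rng.dirichlet([15.0, 20.0, 40.0, 20.0], size=N) * 100.0
    df["age_1_14"] = age[:, 0]
    df["age_15_29"] = age[:, 1]
    df["age_30_60"] = age[:, 2]
    df["age_60_plus"] = age[:, 3]
    return df
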