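"""Lexicon-based topic scoring of county-aggregated text.

Pipeline: tokenize raw text, aggregate token counts per county, drop
counties below a minimum word count, convert counts to within-county
relative frequencies, and project onto a topic lexicon::

    score(county, topic) = sum_tok  P(topic | tok) * P(tok | county)

Out-of-lexicon tokens contribute zero topic mass; rows are not
renormalized unless requested.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EMOTICONS",
    "TopicLexicon",
    "CountyCorpus",
    "TopicScores",
    "tokenize",
    "aggregate_counts",
    "filter_min_words",
    "relative_frequencies",
    "score_topics",
    "load_lexicon",
    "write_lexicon",
    "load_corpus_csv",
    "load_corpus_text",
    "write_scores",
    "load_scores",
]

# Frozen emoticon inventory: matched verbatim, never lowercased.
# Longest-first ordering so ":))" prefers ":)" + ")" over ambiguity
# and ":-)" is not split at the hyphen.
EMOTICONS: tuple[str, ...] = (
    ":-)", ":-(", ":-D", ":-P", ":-p", ";-)", ":')", ":'(",
    ":)", ":(", ":D", ":P", ":p", ";)", ":/", ":|", ":o", ":O",
    "=)", "=(", "=D", "<3", "</3", "^_^", "-_-", "o_O", "O_o",
    "xD", "XD", "D:",
)

_EMOTICON_RE = "|".join(re.escape(e) for e in sorted(EMOTICONS, key=len, reverse=True))

_TOKEN_RE = re.compile(
    r"(?P<url>https?://\S+|www\.\S+)"
    rf"|(?P<emoticon>{_EMOTICON_RE})"
    r"|(?P<mention>@\w+)"
    r"|(?P<hashtag>#\w+)"
    r"|(?P<word>\w+(?:'\w+)*)"
    r"|(?P<punct>\S)",
    re.UNICODE,
)


def tokenize(text: str) -> list[str]:
    """Split ``text`` into social-media-aware tokens.

    Hashtags, @-mentions, URLs, and emoticons from :data:`EMOTICONS` are
    kept as single tokens. Alphabetic tokens, mention/hashtag bodies are
    lowercased; emoticons and URLs are preserved verbatim. Punctuation
    characters are retained as individual tokens.
    """
    tokens: list[str] = []
    for m in _TOKEN_RE.finditer(text):
        kind = m.lastgroup
        tok = m.group()
        if kind in ("word", "mention", "hashtag"):
            tok = tok.lower()
        tokens.append(tok)
    return tokens


@dataclass(frozen=True)
class TopicLexicon:
    """Term -> topic weight table holding P(topic | term).

    ``entries[term][topic]`` is a non-negative weight; for any term the
    weights over topics sum to at most 1 (equality when the lexicon is
    fully normalized).
    """

    entries: Mapping[str, Mapping[str, float]]
    topic_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.topic_ids:
            raise ValueError("lexicon must define at least one topic")
        if len(set(self.topic_ids)) != len(self.topic_ids):
            raise ValueError("topic ids must be unique")
        known = set(self.topic_ids)
        for term, weights in self.entries.items():
            total = 0.0
            for topic, w in weights.items():
                if topic not in known:
                    raise ValueError(f"term {term!r} references unknown topic {topic!r}")
                if w < 0:
                    raise ValueError(f"negative weight {w} for term {term!r}, topic {topic!r}")
                total += w
            if total > 1 + 1e-9:
                raise ValueError(
                    f"weights for term {term!r} sum to {total} > 1; not a probability"
                )

    @property
    def vocab_size(self) -> int:
        return len(self.entries)

    def is_normalized(self, tol: float = 1e-9) -> bool:
        """True when every term's topic weights sum to 1 within ``tol``."""
        return all(
            abs(sum(w.values()) - 1.0) <= tol for w in self.entries.values()
        )


@dataclass(frozen=True)
class CountyCorpus:
    """Sparse per-county token counts."""

    counts: Mapping[str, Mapping[str, int]]

    def __post_init__(self) -> None:
        for county, toks in self.counts.items():
            for tok, n in toks.items():
                if n < 0 or n != int(n):
                    raise ValueError(
                        f"count for county {county!r}, token {tok!r} must be a "
                        f"non-negative integer, got {n}"
                    )

    @property
    def county_ids(self) -> list[str]:
        return list(self.counts)

    @property
    def total_words(self) -> dict[str, int]:
        return {c: sum(toks.values()) for c, toks in self.counts.items()}


@dataclass(frozen=True)
class TopicScores:
    """County x topic matrix of P(topic | county)."""

    matrix: np.ndarray
    county_ids: tuple[str, ...]
    topic_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.shape != (len(self.county_ids), len(self.topic_ids)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(self.county_ids)} counties x {len(self.topic_ids)} topics"
            )
        if (mat < 0).any():
            raise ValueError("topic scores must be non-negative")
        object.__setattr__(self, "matrix", mat)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.county_ids), columns=list(self.topic_ids)
        ).rename_axis("county_id")


def aggregate_counts(documents: Iterable[tuple[str, str]]) -> CountyCorpus:
    """Tokenize documents and sum token counts at the county level."""
    counts: dict[str, Counter] = {}
    for county_id, text in documents:
        if not county_id:
            raise ValueError("county id must be a non-empty string")
        counts.setdefault(county_id, Counter()).update(tokenize(text))
    return CountyCorpus({c: dict(t) for c, t in counts.items()})


def filter_min_words(corpus: CountyCorpus, threshold: int = 40_000) -> CountyCorpus:
    """Retain counties whose total token count is at least ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    totals = corpus.total_words
    return CountyCorpus(
        {c: toks for c, toks in corpus.counts.items() if totals[c] >= threshold}
    )


def relative_frequencies(corpus: CountyCorpus) -> dict[str, dict[str, float]]:
    """Per-county token probabilities P(tok | county)."""
    totals = corpus.total_words
    freqs: dict[str, dict[str, float]] = {}
    for county, toks in corpus.counts.items():
        total = totals[county]
        if total == 0:
            raise ZeroDivisionError(
                f"county {county!r} has zero words; filter it out before scoring"
            )
        freqs[county] = {tok: n / total for tok, n in toks.items() if n > 0}
    return freqs


def score_topics(
    freqs: Mapping[str, Mapping[str, float]],
    lexicon: TopicLexicon,
    renormalize: bool = False,
) -> TopicScores:
    """Project county token frequencies onto lexicon topics.

    ``score[c][k] = sum_tok P(k | tok) * P(tok | c)`` with out-of-lexicon
    tokens contributing zero. With ``renormalize=True`` each nonzero row
    is rescaled to sum to 1 (off by default: the scoring sum runs over
    lexicon tokens only).
    """
    county_ids = tuple(freqs)
    topic_index = {t: j for j, t in enumerate(lexicon.topic_ids)}
    term_index = {term: i for i, term in enumerate(lexicon.entries)}
    # dense term x topic weight matrix; the per-county pass then reduces
    # to an indexed vector-matrix product over in-lexicon tokens
    W = np.zeros((len(term_index), len(topic_index)))
    for term, weights in lexicon.entries.items():
        i = term_index[term]
        for topic, w in weights.items():
            W[i, topic_index[topic]] = w
    matrix = np.zeros((len(county_ids), len(topic_index)))
    for i, county in enumerate(county_ids):
        idx: list[int] = []
        vals: list[float] = []
        for tok, p in freqs[county].items():
            j = term_index.get(tok)
            if j is not None:
                idx.append(j)
                vals.append(p)
        if idx:
            matrix[i] = np.asarray(vals) @ W[idx]
    if renormalize:
        sums = matrix.sum(axis=1, keepdims=True)
        nonzero = sums[:, 0] > 0
        matrix[nonzero] /= sums[nonzero]
    return TopicScores(matrix, county_ids, lexicon.topic_ids)


# ---------------------------------------------------------------------------
# I/O: lexicon CSV (term,topic,weight), corpus CSV (county_id,term,count),
# corpus text (county_id<TAB>text), scores CSV (county_id + topic columns).

def load_lexicon(path) -> TopicLexicon:
    df = pd.read_csv(path, dtype={"term": str, "topic": str})
    required = {"term", "topic", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lexicon file missing columns: {sorted(missing)}")
    weights = pd.to_numeric(df["weight"], errors="raise")
    if df.duplicated(subset=["term", "topic"]).any():
        dupes = df[df.duplicated(subset=["term", "topic"])]
        raise ValueError(
            f"duplicate (term, topic) rows in lexicon: {dupes.iloc[0].term!r}"
        )
    entries: dict[str, dict[str, float]] = {}
    for term, topic, w in zip(df["term"], df["topic"], weights):
        entries.setdefault(term, {})[topic] = float(w)
    topic_ids = tuple(dict.fromkeys(df["topic"]))
    return TopicLexicon(entries, topic_ids)


def write_lexicon(lexicon: TopicLexicon, path) -> None:
    rows = [
        {"term": term, "topic": topic, "weight": repr(float(w))}
        for term, weights in lexicon.entries.items()
        for topic, w in weights.items()
    ]
    pd.DataFrame(rows, columns=["term", "topic", "weight"]).to_csv(path, index=False)


def load_corpus_csv(path) -> CountyCorpus:
    df = pd.read_csv(path, dtype={"county_id": str, "term": str})
    required = {"county_id", "term", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"corpus file missing columns: {sorted(missing)}")
    counts: dict[str, dict[str, int]] = {}
    for county, term, n in zip(df["county_id"], df["term"], df["count"]):
        by_tok = counts.setdefault(county, {})
        by_tok[term] = by_tok.get(term, 0) + int(n)
    return CountyCorpus(counts)


def write_corpus_csv(corpus: CountyCorpus, path) -> None:
    rows = [
        {"county_id": county, "term": tok, "count": n}
        for county, toks in corpus.counts.items()
        for tok, n in toks.items()
    ]
    pd.DataFrame(rows, columns=["county_id", "term", "count"]).to_csv(path, index=False)


def load_corpus_text(path) -> CountyCorpus:
    """Read ``county_id<TAB>text`` lines and aggregate token counts."""
    docs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            county, _, text = line.partition("\t")
            docs.append((county, text))
    return aggregate_counts(docs)


def write_scores(scores: TopicScores, path) -> None:
    scores.to_frame().to_csv(path)


def load_scores(path) -> TopicScores:
    df = pd.read_csv(path, index_col="county_id")
    df.index = df.index.astype(str)
    return TopicScores(
        df.to_numpy(dtype=float), tuple(df.index), tuple(str(c) for c in df.columns)
    )
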