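"""Differential language analysis.

Each topic is regressed against the outcome in its own standardized OLS
model, optionally controlling for covariates; the topic coefficient, its
standard error and two-sided p-value are reported, with Benjamini-Hochberg
correction applied across all non-degenerate topics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .language_features import TopicLexicon, TopicScores

__all__ = ["DLAEntry", "dla_correlate", "bh_adjust", "top_topics"]


@dataclass(frozen=True)
class DLAEntry:
    topic_id: str
    coefficient: float
    std_error: float
    p_value: float
    p_adjusted: float
    significant: bool
    covariate_names: tuple[str, ...] = ()
    degenerate: bool = False


def bh_adjust(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted, reject)`` where ``adjusted[i]`` is
    ``min_{j >= rank(i)} m * p_(j) / j`` capped at 1 and ``reject[i]``
    is ``adjusted[i] <= q``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be a 1-d vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted, adjusted <= q


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant column cannot be standardized")
    return (X - X.mean(axis=0)) / sd


def dla_correlate(
    scores: TopicScores,
    outcome,
    covariates: pd.DataFrame | np.ndarray | None = None,
    q: float = 0.05,
) -> list[DLAEntry]:
    """One standardized OLS per topic: ``outcome ~ topic (+ covariates)``.

    All variables are standardized internally, so without covariates the
    topic coefficient equals Pearson r(topic, outcome). Constant topics
    are flagged degenerate and excluded from the BH family.
    """
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    if n != len(scores.county_ids):
        raise ValueError("outcome length does not match score rows")
    cov_names: tuple[str, ...] = ()
    Z = None
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            cov_names = tuple(covariates.columns)
            Z = covariates.to_numpy(dtype=float)
        else:
            Z = np.asarray(covariates, dtype=float)
            if Z.ndim == 1:
                Z = Z[:, None]
            cov_names = tuple(f"cov{i}" for i in range(Z.shape[1]))
        Z = _standardize_columns(Z)
    n_cov = 0 if Z is None else Z.shape[1]
    if n < n_cov + 3:
        raise ValueError("too few counties for the requested covariate set")

    from scipy import stats

    yz = _standardize_columns(y[:, None])[:, 0]
    results: list[tuple[str, float, float, float] | tuple[str, None]] = []
    for j, topic in enumerate(scores.topic_ids):
        col = scores.matrix[:, j]
        if col.std(ddof=1) == 0:
            results.append((topic, None))
            continue
        tz = (col - col.mean()) / col.std(ddof=1)
        X = np.column_stack([np.ones(n), tz] if Z is None else [np.ones(n), tz, Z])
        beta, _, rank, _ = np.linalg.lstsq(X, yz, rcond=None)
        resid = yz - X @ beta
        df = n - X.shape[1]
        sigma2 = resid @ resid / df
        cov_beta = sigma2 * np.linalg.pinv(X.T @ X)
        se = float(np.sqrt(cov_beta[1, 1]))
        t = beta[1] / se
        p = float(2 * stats.t.sf(abs(t), df))
        results.append((topic, float(beta[1]), se, p))

    tested = [r for r in results if len(r) == 4]
    adjusted, reject = bh_adjust(np.array([r[3] for r in tested]), q) if tested else (
        np.array([]), np.array([], dtype=bool),
    )
    adj_map = {r[0]: (a, bool(rj)) for r, a, rj in zip(tested, adjusted, reject)}

    entries: list[DLAEntry] = []
    for r in results:
        topic = r[0]
        if len(r) == 2:
            entries.append(
                DLAEntry(topic, float("nan"), float("nan"), float("nan"),
                         float("nan"), False, cov_names, degenerate=True)
            )
        else:
            p_adj, sig = adj_map[topic]
            entries.append(
                DLAEntry(topic, r[1], r[2], r[3], float(p_adj), sig, cov_names)
            )
    return entries


def top_topics(
    entries: Sequence[DLAEntry],
    lexicon: TopicLexicon,
    k_topics: int,
    k_words: int = 15,
) -> dict[str, list[dict]]:
    """Ranked summary of significant topics with their top-weighted words.

    Significant topics are split by coefficient sign and sorted by
    |coefficient| descending; each carries its ``k_words`` highest-weight
    lexicon terms (ties broken lexicographically by term).
    """
    report: dict[str, list[dict]] = {"positive": [], "negative": []}
    significant = [e for e in entries if e.significant and not e.degenerate]
    for sign, key in (("positive", 1), ("negative", -1)):
        group = [e for e in significant if np.sign(e.coefficient) == key]
        group.sort(key=lambda e: -abs(e.coefficient))
        for e in group[:k_topics]:
            words = [
                (term, weights[e.topic_id])
                for term, weights in lexicon.entries.items()
                if e.topic_id in weights
            ]
            words.sort(key=lambda tw: (-tw[1], tw[0]))
            report[sign].append(
                {
                    "topic": e.topic_id,
                    "coefficient": e.coefficient,
                    "p_adjusted": e.p_adjusted,
                    "top_words": words[:k_words],
                }
            )
    return report


def entries_to_frame(entries: Sequence[DLAEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "topic": [e.topic_id for e in entries],
            "coef": [e.coefficient for e in entries],
            "se": [e.std_error for e in entries],
            "p": [e.p_value for e in entries],
            "p_bh": [e.p_adjusted for e in entries],
            "significant": [e.significant for e in entries],
        }
    )
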