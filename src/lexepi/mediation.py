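"""Mass mediation screening over topic features.

For each topic m, three standardized OLS regressions estimate the paths
of the x -> m -> y mediation triangle::

    y = c x  + b1 + e1      (total effect)
    m = a x  + b2 + e2      (x -> mediator)
    y = c'x + b m + b3 + e3 (direct + mediator effects)

Mediation size is c - c' (equal to a*b for nested OLS with a single
mediator); significance uses the Sobel normal-theory test, with BH
correction across all screened topics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import standardize
from .dla import bh_adjust
from .language_features import TopicScores
from .prediction import ols_fit

__all__ = ["MediationEntry", "mediate", "mass_mediation", "sobel"]

# |r(topic, x)| above this is treated as collinear and skipped in the
# mass screen (path b undefined).
_COLLINEARITY_R = 0.999


@dataclass(frozen=True)
class MediationEntry:
    topic_id: str
    c: float            # total effect x -> y
    a: float            # x -> mediator
    se_a: float
    b: float            # mediator -> y given x
    se_b: float
    c_prime: float      # direct effect
    mediation: float    # c - c'
    sobel_z: float
    p_value: float
    p_adjusted: float = float("nan")
    significant: bool = False


def sobel(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Sobel z = a*b / sqrt(b^2 se_a^2 + a^2 se_b^2), two-sided normal p."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    denom = np.sqrt(b * b * se_a * se_a + a * a * se_b * se_b)
    if denom == 0:
        return 0.0, 1.0
    z = a * b / denom
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def mediate(x, m, y, topic_id: str = "") -> MediationEntry:
    """Single-mediator three-regression analysis on standardized variables."""
    xz = standardize(x)
    mz = standardize(m)
    yz = standardize(y)
    n = len(xz)
    if not (len(mz) == len(yz) == n):
        raise ValueError("x, m, y must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    r_xm = float(np.corrcoef(xz, mz)[0, 1])
    if abs(r_xm) > _COLLINEARITY_R:
        raise ValueError(
            f"mediator {topic_id!r} is collinear with x (|r|={abs(r_xm):.4f}); "
            "path b is undefined"
        )
    total = ols_fit(xz[:, None], yz)
    c = float(total.coefficients[0])
    to_mediator = ols_fit(xz[:, None], mz)
    a, se_a = float(to_mediator.coefficients[0]), float(to_mediator.std_errors[0])
    direct = ols_fit(np.column_stack([xz, mz]), yz)
    c_prime = float(direct.coefficients[0])
    b, se_b = float(direct.coefficients[1]), float(direct.std_errors[1])
    z, p = sobel(a, se_a, b, se_b)
    return MediationEntry(
        topic_id, c, a, se_a, b, se_b, c_prime, c - c_prime, z, p
    )


def mass_mediation(
    ses,
    scores: TopicScores,
    outcome,
    q: float = 0.05,
) -> list[MediationEntry]:
    """Screen every topic as a candidate mediator of ses -> outcome.

    Degenerate topics (zero variance or collinear with ses) are skipped
    with a warning. BH runs over the Sobel p-values of all screened
    topics; results are ordered by descending mediation size within the
    positive-b group, then within the negative-b group.
    """
    x = np.asarray(ses, dtype=float)
    y = np.asarray(outcome, dtype=float)
    entries: list[MediationEntry] = []
    for j, topic in enumerate(scores.topic_ids):
        col = scores.matrix[:, j]
        if col.std(ddof=1) == 0:
            warnings.warn(f"topic {topic!r} is constant; skipped", stacklevel=2)
            continue
        try:
            entries.append(mediate(x, col, y, topic_id=topic))
        except ValueError as exc:
            warnings.warn(f"topic {topic!r} skipped: {exc}", stacklevel=2)
    if not entries:
        return []
    adjusted, reject = bh_adjust(np.array([e.p_value for e in entries]), q)
    entries = [
        MediationEntry(
            e.topic_id, e.c, e.a, e.se_a, e.b, e.se_b, e.c_prime,
            e.mediation, e.sobel_z, e.p_value, float(p_adj), bool(rej),
        )
        for e, p_adj, rej in zip(entries, adjusted, reject)
    ]
    positive = sorted((e for e in entries if e.b >= 0), key=lambda e: -e.mediation)
    negative = sorted((e for e in entries if e.b < 0), key=lambda e: -e.mediation)
    return positive + negative


def entries_to_frame(entries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "topic": [e.topic_id for e in entries],
            "a": [e.a for e in entries],
            "se_a": [e.se_a for e in entries],
            "b": [e.b for e in entries],
            "se_b": [e.se_b for e in entries],
            "c": [e.c for e in entries],
            "c_prime": [e.c_prime for e in entries],
            "mediation": [e.mediation for e in entries],
            "sobel_z": [e.sobel_z for e in entries],
            "p": [e.p_value for e in entries],
            "p_bh": [e.p_adjusted for e in entries],
            "significant": [e.significant for e in entries],
        }
    )
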