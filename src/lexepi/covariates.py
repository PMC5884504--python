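"""Socio-demographic design matrices, the composite socioeconomic index,
and the cross-correlation summary table."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dla import bh_adjust

__all__ = [
    "DEMOGRAPHIC_COLUMNS",
    "SOCIOECONOMIC_COLUMNS",
    "AGE_BIN_COLUMNS",
    "standardize",
    "ses_index",
    "add_ses_index",
    "cross_correlations",
    "collapse_age_bins",
    "restrict_counties",
    "load_covariates",
    "load_outcome",
]

DEMOGRAPHIC_COLUMNS = (
    "pct_female",
    "pct_african_american",
    "pct_hispanic",
    "pct_foreign_born",
    "pct_married",
)
SOCIOECONOMIC_COLUMNS = (
    "log_income",
    "hs_grad",
    "college_grad",
    "unemployment",
)
# Census age distribution collapsed to four bins by summation.
AGE_BIN_COLUMNS = ("age_1_14", "age_15_29", "age_30_60", "age_60_plus")

CONTROL_COLUMNS = DEMOGRAPHIC_COLUMNS + SOCIOECONOMIC_COLUMNS + AGE_BIN_COLUMNS

# Default design for control-only / combined models: one age bin is left
# out (the four sum to 100, exactly collinear with the intercept) and the
# SES index is excluded (a linear combination of its member columns).
DEFAULT_CONTROL_COLUMNS = (
    DEMOGRAPHIC_COLUMNS + SOCIOECONOMIC_COLUMNS + AGE_BIN_COLUMNS[:-1]
)


def standardize(values) -> np.ndarray:
    """z-score with sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d vector")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant vector (zero variance)")
    return (x - x.mean()) / sd


def ses_index(log_income, hs_grad) -> np.ndarray:
    """Average of standardized log income and standardized high-school
    graduation rate."""
    z_inc = standardize(log_income)
    z_hs = standardize(hs_grad)
    if len(z_inc) != len(z_hs):
        raise ValueError("log_income and hs_grad must have equal length")
    return (z_inc + z_hs) / 2.0


def add_ses_index(covariates: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``covariates`` with a ``ses_index`` column."""
    out = covariates.copy()
    out["ses_index"] = ses_index(out["log_income"], out["hs_grad"])
    return out


def collapse_age_bins(covariates: pd.DataFrame, bin_map: dict[str, list[str]]) -> pd.DataFrame:
    """Sum fine-grained age-percentage columns into named coarse bins.

    ``bin_map`` maps each output column (e.g. ``age_15_29``) to the input
    columns it aggregates; input columns are dropped from the result.
    """
    out = covariates.copy()
    consumed: set[str] = set()
    for coarse, fine_cols in bin_map.items():
        missing = [c for c in fine_cols if c not in out.columns]
        if missing:
            raise ValueError(f"age bin {coarse!r} references missing columns {missing}")
        out[coarse] = out[fine_cols].sum(axis=1)
        consumed.update(fine_cols)
    return out.drop(columns=sorted(consumed - set(bin_map)))


def restrict_counties(*tables: pd.DataFrame, log=None) -> list[pd.DataFrame]:
    """Successively intersect tables on their county index, logging the
    count after each restriction."""
    if not tables:
        return []
    idx = tables[0].index
    if log:
        log(f"county restriction: start with {len(idx)}")
    for t in tables[1:]:
        idx = idx.intersection(t.index)
        if log:
            log(f"county restriction: {len(idx)} after intersecting")
    idx = idx.sort_values()
    return [t.loc[idx] for t in tables]


def cross_correlations(table: pd.DataFrame, q: float = 0.05):
    """Pairwise Pearson correlations with BH-corrected two-sided p-values.

    Returns ``(r, p_bh)`` DataFrames. ``r`` is symmetric with unit
    diagonal; p-values come from the t distribution of Pearson r and BH
    is applied across the upper triangle (diagonal excluded). Diagonal
    and lower-triangle p entries mirror the upper triangle.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 counties for correlations")
    for col in table.columns:
        if table[col].std(ddof=1) == 0:
            raise ValueError(f"column {col!r} is constant; cannot correlate")
    cols = list(table.columns)
    m = len(cols)
    r = np.eye(m)
    p_raw = np.zeros((m, m))
    pairs = []
    for i in range(m):
        for j in range(i + 1, m):
            res = stats.pearsonr(table[cols[i]], table[cols[j]])
            r[i, j] = r[j, i] = res.statistic
            pairs.append((i, j, res.pvalue))
    adjusted, _ = bh_adjust(np.array([p for _, _, p in pairs]), q)
    for (i, j, _), p_adj in zip(pairs, adjusted):
        p_raw[i, j] = p_raw[j, i] = p_adj
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p_raw, index=cols, columns=cols),
    )


def load_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"county_id": str}).set_index("county_id")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in covariate columns {bad}")
    return df


def load_outcome(path) -> pd.Series:
    df = pd.read_csv(path, dtype={"county_id": str}).set_index("county_id")
    if "outcome" not in df.columns:
        raise ValueError("outcome file must have columns county_id,outcome")
    s = df["outcome"].astype(float)
    if s.isna().any():
        raise ValueError("missing outcome values")
    return s
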