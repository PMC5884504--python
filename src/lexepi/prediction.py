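"""Cross-validated prediction of a county outcome from topic features.

Language models use a train-fold-only pipeline of variance/correlation
feature screening, PCA, and ridge regression; control-only models use
OLS. The combined model regresses controls on the outcome by OLS and
fits the language pipeline to the residuals, summing the two paths for
held-out predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LinearFit",
    "PipelineConfig",
    "ModelEvaluation",
    "ols_fit",
    "ridge_fit",
    "screen_features",
    "pca_reduce",
    "crossval_predict",
    "evaluate",
    "compare_models",
    "assign_folds",
]


@dataclass(frozen=True)
class LinearFit:
    coefficients: np.ndarray
    intercept: float
    residuals: np.ndarray
    std_errors: np.ndarray | None = None  # OLS only

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients + self.intercept


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs for the screen -> PCA -> ridge language pipeline and CV."""

    ridge_lambda: float = 1000.0
    variance_floor: float = 0.0
    screen_alpha: float = 60.0
    pca_variance_fraction: float = 0.99
    n_folds: int = 10
    seed: int = 42

    def __post_init__(self) -> None:
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be non-negative")
        if not (0 < self.pca_variance_fraction <= 1):
            raise ValueError("pca_variance_fraction must be in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass(frozen=True)
class ModelEvaluation:
    predictions: np.ndarray
    observed: np.ndarray
    fold_ids: np.ndarray
    pooled_r: float
    mae: float
    per_fold_r: tuple[float, ...]

    @property
    def abs_errors(self) -> np.ndarray:
        return np.abs(self.predictions - self.observed)


def ols_fit(X, y) -> LinearFit:
    """Ordinary least squares with intercept and classical standard errors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more rows ({n}) than features plus intercept ({p + 1})")
    D = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(D)
    if rank < p + 1:
        sds = X.std(axis=0)
        const = [str(j) for j in np.flatnonzero(sds == 0)]
        detail = f" (constant columns: {const})" if const else ""
        raise ValueError(f"design matrix is rank deficient{detail}")
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    sigma2 = resid @ resid / (n - p - 1)
    cov = sigma2 * np.linalg.inv(D.T @ D)
    se = np.sqrt(np.diag(cov))
    return LinearFit(beta[1:], float(beta[0]), resid, se[1:])


def ridge_fit(X, y, ridge_lambda: float) -> LinearFit:
    """Ridge regression ``beta = (X'X + lambda I)^-1 X'y`` on standardized
    columns, intercept unpenalized (handled by centering). Coefficients
    are returned on the original feature scale."""
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be non-negative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant column passed to ridge_fit")
    Z = (X - mu) / sd
    y_mean = y.mean()
    yc = y - y_mean
    p = Z.shape[1]
    beta_z = np.linalg.solve(Z.T @ Z + ridge_lambda * np.eye(p), Z.T @ yc)
    coef = beta_z / sd
    intercept = y_mean - mu @ coef
    resid = y - (X @ coef + intercept)
    return LinearFit(coef, float(intercept), resid)


def screen_features(X, y, variance_floor: float, alpha: float) -> np.ndarray:
    """Two-stage univariate screen: drop low-variance columns, then keep
    column j iff its Pearson p-value with y satisfies ``p <= alpha / m``
    where m is the number of columns surviving the variance screen.

    ``alpha`` defaults to a deliberately permissive 60 in
    :class:`PipelineConfig`, making this a weak Bonferroni-style sieve.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    variances = X.var(axis=0, ddof=1)
    # constants are always dropped; otherwise keep variance >= floor
    survivors = np.flatnonzero((variances > 0) & (variances >= variance_floor))
    if survivors.size == 0:
        raise ValueError("variance screen removed every feature")
    m = survivors.size
    threshold = alpha / m
    kept = [
        j for j in survivors
        if stats.pearsonr(X[:, j], y).pvalue <= threshold
    ]
    if not kept:
        raise ValueError("correlation screen removed every feature")
    return np.array(kept)


def pca_reduce(X_train, X_apply, variance_fraction: float):
    """PCA fit on ``X_train`` (centered internally), retaining the
    smallest component count whose cumulative explained variance ratio
    reaches ``variance_fraction``; ``X_apply`` is projected with the
    train rotation and centering. Returns (train scores, apply scores,
    rotation matrix)."""
    if not (0 < variance_fraction <= 1):
        raise ValueError("variance_fraction must be in (0, 1]")
    X_train = np.asarray(X_train, dtype=float)
    X_apply = np.asarray(X_apply, dtype=float)
    if X_train.shape[0] < 2:
        raise ValueError("PCA needs at least 2 training samples")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=None, svd_solver="full")
    T_full = pca.fit_transform(X_train)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    k = min(k, len(ratios))
    rotation = pca.components_[:k].T
    T_train = T_full[:, :k]
    T_apply = (X_apply - pca.mean_) @ rotation
    return T_train, T_apply, rotation


def assign_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Deterministic seeded partition of n units into k folds with sizes
    differing by at most one."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        fold_ids[chunk] = f
    return fold_ids


def _fit_language_path(X_train, y_train, X_test, config: PipelineConfig):
    """Screen -> standardize -> PCA -> ridge on the training fold; returns
    held-out predictions for X_test."""
    kept = screen_features(X_train, y_train, config.variance_floor, config.screen_alpha)
    Xt, Xs = X_train[:, kept], X_test[:, kept]
    mu = Xt.mean(axis=0)
    sd = Xt.std(axis=0, ddof=1)
    Zt, Zs = (Xt - mu) / sd, (Xs - mu) / sd
    Tt, Ts, _ = pca_reduce(Zt, Zs, config.pca_variance_fraction)
    max_comp = min(Tt.shape[1], Xt.shape[0] - 1)
    Tt, Ts = Tt[:, :max_comp], Ts[:, :max_comp]
    fit = ridge_fit(Tt, y_train, config.ridge_lambda)
    return fit.predict(Ts)


def crossval_predict(
    X,
    y,
    config: PipelineConfig,
    controls=None,
) -> ModelEvaluation:
    """k-fold cross-validated prediction.

    Three modes: language-only (``X`` given), controls-only (``X`` is
    None), or combined (both given: per training fold the controls are
    fit by OLS and the language pipeline models the control residuals;
    held-out prediction is the sum of the two paths). All screening,
    standardization, and PCA statistics come from the training fold only.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None and controls is None:
        raise ValueError("provide topic features, controls, or both")
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.shape[0] != n:
            raise ValueError("feature rows do not match outcome length")
    if controls is not None:
        controls = np.asarray(controls, dtype=float)
        if controls.ndim == 1:
            controls = controls[:, None]
        if controls.shape[0] != n:
            raise ValueError("control rows do not match outcome length")
    k = config.n_folds
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} units for {k}-fold CV")
    fold_ids = assign_folds(n, k, config.seed)
    predictions = np.empty(n)
    for f in range(k):
        test = fold_ids == f
        train = ~test
        if test.sum() < 2:
            raise ValueError(f"fold {f} has fewer than 2 counties")
        y_tr = y[train]
        pred = np.zeros(test.sum())
        residual_target = y_tr
        if controls is not None:
            ctrl_fit = ols_fit(controls[train], y_tr)
            pred += ctrl_fit.predict(controls[test])
            residual_target = ctrl_fit.residuals
        if X is not None:
            pred += _fit_language_path(X[train], residual_target, X[test], config)
        predictions[test] = pred
    pooled_r, mae = evaluate(predictions, y)
    per_fold = []
    for f in range(k):
        mask = fold_ids == f
        if np.std(predictions[mask]) > 0 and np.std(y[mask]) > 0:
            per_fold.append(float(stats.pearsonr(predictions[mask], y[mask]).statistic))
        else:
            per_fold.append(float("nan"))
    return ModelEvaluation(predictions, y, fold_ids, pooled_r, mae, tuple(per_fold))


def evaluate(predictions, observed) -> tuple[float, float]:
    """Pearson r and mean absolute error between predictions and truth."""
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if len(pred) != len(obs) or len(pred) < 3:
        raise ValueError("need equal-length vectors of at least 3")
    if np.std(pred) == 0 or np.std(obs) == 0:
        raise ValueError("cannot correlate a constant vector")
    r = float(stats.pearsonr(pred, obs).statistic)
    mae = float(np.mean(np.abs(pred - obs)))
    return r, mae


def compare_models(errors_a, errors_b) -> tuple[float, float]:
    """Paired t-test on per-county model errors (n-1 degrees of freedom)."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t-test undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
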