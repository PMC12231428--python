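"""Connectome-based prediction: correlation-filtered regularised regression.

Within each training fold, features (EC entries) are correlated with the
behavioural score and the strongest positively and negatively correlated
fractions are kept; a ridge- or LASSO-regularised linear model is then fit
on the standardized selected features and evaluated as the Pearson
correlation between predicted and observed scores on the held-out fold.
Fold correlations are averaged within a repeat, and the whole 10-fold scheme
is repeated with fresh random partitions.

Selection, standardization and fitting all use training-fold data only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.model_selection import KFold

from .errors import ConfigError, DegenerateInputError, NumericalError

__all__ = [
    "SelectionConfig",
    "CVConfig",
    "PredictionResult",
    "select_features",
    "fit_linear",
    "crossval_predict",
    "repeat_prediction",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Correlation-based feature selection settings.

    ``fraction`` is the per-direction fraction: the top ``floor(fraction*P)``
    most positively correlated features and the same number of most
    negatively correlated features are kept (``2*floor(fraction*P)`` total).
    """

    fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 0.5:
            raise ConfigError("fraction must be in (0, 0.5)")


@dataclass(frozen=True)
class CVConfig:
    """Repeated k-fold cross-validation settings."""

    n_folds: int = 10
    n_repeats: int = 100
    model: str = "ridge"
    penalty: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if self.model not in ("ridge", "lasso"):
            raise ConfigError("model must be 'ridge' or 'lasso'")
        if self.penalty < 0:
            raise ConfigError("penalty must be non-negative")


@dataclass
class PredictionResult:
    """Fold-averaged prediction correlations across repeats for one family."""

    per_repeat_r: np.ndarray
    family: str
    selection: SelectionConfig
    cv: CVConfig

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.per_repeat_r))


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of ``x`` with ``y``.

    Zero-variance columns get correlation 0 (they carry no information and
    must never be selected ahead of informative ones).
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    x_ss = np.einsum("ij,ij->j", xc, xc)
    denom = np.sqrt(x_ss * y_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / denom
    return np.where(denom > 0, r, 0.0)


def select_features(features: np.ndarray, scores: np.ndarray, fraction: float) -> np.ndarray:
    """Indices of the ``k`` most positive plus ``k`` most negative correlations.

    ``k = floor(fraction * P)``; ties are broken in favour of the lower
    feature index within each direction.  Raises when the target is constant,
    when ``k`` is zero, or when ``2k >= P``.
    """
    features = np.asarray(features, dtype=float)
    scores = np.asarray(scores, dtype=float)
    p = features.shape[1]
    if scores.std() == 0:
        raise DegenerateInputError("score vector is constant; correlations undefined")
    k = int(np.floor(fraction * p))
    if k < 1:
        raise ConfigError(f"fraction {fraction} selects zero features out of {p}")
    if 2 * k >= p:
        raise ConfigError(f"2*floor(fraction*P) = {2 * k} must be < P = {p}")
    corr = _pearson_columns(features, scores)
    order_desc = np.lexsort((np.arange(p), -corr))
    order_asc = np.lexsort((np.arange(p), corr))
    top = order_desc[:k]
    top_set = np.zeros(p, dtype=bool)
    top_set[top] = True
    bottom = np.array([i for i in order_asc if not top_set[i]][:k], dtype=int)
    return np.sort(np.concatenate([top, bottom]))


def fit_linear(
    x: np.ndarray, y: np.ndarray, model: str = "ridge", penalty: float = 1.0
) -> tuple[np.ndarray, float]:
    """Fit a regularised linear model; returns ``(weights, intercept)``.

    Ridge minimises ``||y - Xw - b||^2 + penalty * ||w||^2``; LASSO minimises
    ``(1/2n) ||y - Xw - b||^2 + penalty * ||w||_1`` (coordinate descent).
    The intercept is never penalised.  Features are assumed standardized by
    the caller.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise NumericalError("non-finite values in regression inputs")
    if model == "ridge":
        est = Ridge(alpha=penalty) if penalty > 0 else LinearRegression()
    elif model == "lasso":
        est = (
            Lasso(alpha=penalty, max_iter=50_000, tol=1e-6)
            if penalty > 0
            else LinearRegression()
        )
    else:
        raise ConfigError("model must be 'ridge' or 'lasso'")
    est.fit(x, y)
    return np.asarray(est.coef_, dtype=float), float(est.intercept_)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; 0.0 when either vector is constant (no linear association)."""
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(stats.pearsonr(a, b).statistic)


def crossval_predict(
    features: np.ndarray,
    scores: np.ndarray,
    sel: SelectionConfig,
    cv: CVConfig,
    seed: int,
) -> float:
    """One repeat: fold-averaged correlation between predicted and true scores.

    For each fold: select features on the training subjects, z-score the
    selected columns by training statistics, fit the regularised model,
    predict the held-out subjects and record Pearson r; returns the mean of
    the fold r values.
    """
    features = np.asarray(features, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n = features.shape[0]
    if scores.shape[0] != n:
        raise ConfigError("features and scores are not row-aligned")
    if n // cv.n_folds < 3:
        raise ConfigError(
            f"{cv.n_folds}-fold CV on {n} subjects leaves test folds with fewer "
            "than 3 subjects; Pearson r needs at least 3 points"
        )
    splitter = KFold(n_splits=cv.n_folds, shuffle=True, random_state=int(seed) % 2**31)
    fold_rs = []
    for train_idx, test_idx in splitter.split(features):
        x_tr, y_tr = features[train_idx], scores[train_idx]
        keep = select_features(x_tr, y_tr, sel.fraction)
        mu = x_tr[:, keep].mean(axis=0)
        sd = x_tr[:, keep].std(axis=0)
        sd[sd == 0] = 1.0
        z_tr = (x_tr[:, keep] - mu) / sd
        z_te = (features[test_idx][:, keep] - mu) / sd
        w, b = fit_linear(z_tr, y_tr, model=cv.model, penalty=cv.penalty)
        pred = z_te @ w + b
        fold_rs.append(_safe_pearson(pred, scores[test_idx]))
    return float(np.mean(fold_rs))


def _repeat_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-repeat seeds (all below 2**31)."""
    return np.random.SeedSequence(master_seed).generate_state(n) % np.uint32(2**31)


def repeat_prediction(
    features: np.ndarray,
    scores: np.ndarray,
    sel: SelectionConfig,
    cv: CVConfig,
    family: str = "WB",
) -> PredictionResult:
    """Repeat the cross-validated prediction with fresh random partitions.

    Per-repeat fold partitions use seeds derived deterministically from
    ``cv.seed``; the summary statistic is the mean over repeats of the
    fold-averaged correlations.
    """
    seeds = _repeat_seeds(cv.seed, cv.n_repeats)
    per_repeat = np.array(
        [crossval_predict(features, scores, sel, cv, int(s)) for s in seeds]
    )
    return PredictionResult(per_repeat_r=per_repeat, family=family, selection=sel, cv=cv)
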