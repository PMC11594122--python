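"""Cross-validated regression of tract outcome rates on visual features.

Two model families mirror common practice for area-level outcome
modelling on high-dimensional image embeddings:

* a Gaussian-identity linear model ("GLM"): with D >> n the ordinary
  least-squares problem is underdetermined, so the default solution is
  the minimum-norm pseudoinverse fit, with optional ridge shrinkage;
* a seeded bootstrap random-forest regressor, which also supplies
  impurity-based feature importances.

Evaluation uses a seeded 80/20 holdout and k-fold cross-validation with
per-fold MSE, R^2 and adjusted R^2, pooled out-of-fold predictions, a
percentage-normalized feature-importance ranking with per-feature
Pearson correlations, and a signed-error table (actual - predicted,
in percentage points) with absolute-error threshold subsets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.linalg import matrix_rank
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import KFold, train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "FoldMetrics",
    "CVSummary",
    "ImportanceRecord",
    "fit_linear",
    "fit_forest",
    "compute_metrics",
    "holdout_evaluate",
    "kfold_cv",
    "summarize_folds",
    "feature_importance",
    "error_analysis",
]

ADJ_R2_UNDEFINED = float("nan")


@dataclass
class FoldMetrics:
    fold_index: int
    mse: float
    r2: float
    adj_r2: float
    n_test: int


@dataclass
class CVSummary:
    folds: list[FoldMetrics]
    mean_mse: float
    mean_r2: float
    mean_adj_r2: float
    oof_predictions: np.ndarray  # one out-of-fold prediction per sample
    models: list = field(default_factory=list)
    y: Optional[np.ndarray] = None

    @property
    def oof_r2(self) -> float:
        """R^2 of the pooled out-of-fold predictions.

        Pooling uses every sample's single held-out prediction, so this
        is the stabler recovery statistic; per-fold R^2 values (and
        their mean) are noisier because each fold's total sum of
        squares rests on n/k samples.
        """
        ss_res = float(np.sum((self.y - self.oof_predictions) ** 2))
        ss_tot = float(np.sum((self.y - np.mean(self.y)) ** 2))
        return 1.0 - ss_res / ss_tot

    @property
    def oof_mse(self) -> float:
        return float(np.mean((self.y - self.oof_predictions) ** 2))

    def to_frame(self) -> pd.DataFrame:
        """Fold table at display precision (MSE to 2 decimals, R^2 to 3)."""
        rows = [
            (m.fold_index, round(m.mse, 2), round(m.r2, 3), round(m.adj_r2, 3))
            for m in self.folds
        ]
        rows.append(
            ("Mean", round(self.mean_mse, 2), round(self.mean_r2, 3), round(self.mean_adj_r2, 3))
        )
        return pd.DataFrame(rows, columns=["fold", "mse", "r2", "adj_r2"])


@dataclass
class ImportanceRecord:
    feature_index: int
    importance_pct: float
    correlation: float


def _check_finite(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("design matrix and outcomes must be finite")
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    return X, y


def fit_linear(X: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    """Least-squares linear model; minimum-norm when D >= n, ridge when ridge>0."""
    X, y = _check_finite(X, y)
    if ridge < 0:
        raise ValueError("ridge penalty must be non-negative")
    model = Ridge(alpha=ridge) if ridge > 0 else LinearRegression()
    model.fit(X, y)
    return model


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
    max_features: float | str = "sqrt",
):
    """Seeded bootstrap regression forest with impurity importances.

    ``max_features="sqrt"`` is the standard choice when the feature
    dimension far exceeds the sample count: with D >> n, scanning every
    feature at every split buys little decorrelation and dominates the
    run time.
    """
    X, y = _check_finite(X, y)
    model = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, max_features=max_features, n_jobs=1
    )
    model.fit(X, y)
    return model


def _make_model(model_kind: str, seed: int, ridge: float, n_trees: int):
    if model_kind == "glm":
        return lambda X, y: fit_linear(X, y, ridge=ridge)
    if model_kind == "rf":
        return lambda X, y: fit_forest(X, y, n_trees=n_trees, seed=seed)
    raise ValueError(f"unknown model kind {model_kind!r}; expected 'glm' or 'rf'")


def compute_metrics(
    actual: np.ndarray, predicted: np.ndarray, p_eff: int
) -> tuple[float, float, float]:
    """(MSE, R^2, adjusted R^2) of a prediction vector.

    adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p_eff - 1); when
    n <= p_eff + 1 the adjustment is undefined and NaN is reported (and
    logged) rather than a misleading number.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    n = len(actual)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if p_eff < 1:
        raise ValueError("p_eff must be >= 1")
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("actual values have zero variance; R^2 undefined")
    ss_res = float(np.sum((actual - predicted) ** 2))
    mse = ss_res / n
    r2 = 1.0 - ss_res / ss_tot
    if n <= p_eff + 1:
        logger.info("adjusted R^2 undefined at n=%d, p_eff=%d; reporting NaN", n, p_eff)
        adj = ADJ_R2_UNDEFINED
    else:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_eff - 1)
    return mse, r2, adj


def effective_p(X_train: np.ndarray, n_test: int) -> int:
    """Effective predictor count for the adjusted-R^2 penalty.

    The rank of the training design matrix, capped so the adjustment
    denominator stays positive on the test set.
    """
    rank = int(matrix_rank(X_train))
    return max(1, min(rank, n_test - 2))


def holdout_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    model_kind: str = "glm",
    split_fraction: float = 0.8,
    seed: int = 0,
    ridge: float = 0.0,
    n_trees: int = 100,
) -> FoldMetrics:
    """Train on a seeded random split_fraction share, report test metrics."""
    X, y = _check_finite(X, y)
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie in (0, 1)")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split_fraction, random_state=seed, shuffle=True
    )
    if len(y_te) < 2:
        raise ValueError("test partition smaller than 2 samples")
    model = _make_model(model_kind, seed, ridge, n_trees)(X_tr, y_tr)
    mse, r2, adj = compute_metrics(y_te, model.predict(X_te), effective_p(X_tr, len(y_te)))
    return FoldMetrics(fold_index=1, mse=mse, r2=r2, adj_r2=adj, n_test=len(y_te))


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    model_kind: str = "glm",
    seed: int = 0,
    ridge: float = 0.0,
    n_trees: int = 100,
    keep_models: bool = False,
) -> CVSummary:
    """Seeded shuffled k-fold cross-validation with pooled out-of-fold predictions.

    Fold sizes differ by at most one and each sample is tested exactly
    once; per-fold metrics use the rank of that fold's training matrix
    as the adjusted-R^2 predictor count.
    """
    X, y = _check_finite(X, y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(y):
        raise ValueError(f"k={k} exceeds the {len(y)} available samples")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[FoldMetrics] = []
    oof = np.full(len(y), np.nan)
    models = []
    for fold_index, (tr, te) in enumerate(splitter.split(X), start=1):
        model = _make_model(model_kind, seed, ridge, n_trees)(X[tr], y[tr])
        pred = model.predict(X[te])
        oof[te] = pred
        if len(te) >= 2 and np.var(y[te]) > 0:
            mse, r2, adj = compute_metrics(y[te], pred, effective_p(X[tr], len(te)))
        else:
            # tiny or constant test folds (e.g. leave-one-out): R^2 undefined
            mse = float(np.mean((y[te] - pred) ** 2))
            r2 = adj = ADJ_R2_UNDEFINED
            logger.info("fold %d: R^2 undefined on %d test samples", fold_index, len(te))
        folds.append(FoldMetrics(fold_index, mse, r2, adj, n_test=len(te)))
        if keep_models:
            models.append(model)
    mean_mse, mean_r2, mean_adj = summarize_folds(folds)
    return CVSummary(
        folds=folds,
        mean_mse=mean_mse,
        mean_r2=mean_r2,
        mean_adj_r2=mean_adj,
        oof_predictions=oof,
        models=models,
        y=y,
    )


def summarize_folds(folds: Sequence[FoldMetrics]) -> tuple[float, float, float]:
    """Arithmetic mean of the MSE, R^2 and adjusted-R^2 columns."""
    if not folds:
        raise ValueError("no folds to summarize")
    return (
        float(np.mean([f.mse for f in folds])),
        float(np.mean([f.r2 for f in folds])),
        float(np.mean([f.adj_r2 for f in folds])),
    )


def feature_importance(
    models: Sequence, X: np.ndarray, y: np.ndarray, against: str = "actual",
    oof_predictions: Optional[np.ndarray] = None,
) -> list[ImportanceRecord]:
    """Percentage-normalized impurity importances with Pearson correlations.

    Importances are averaged over the cross-validation fold models and
    rescaled to sum to 100. The correlation column is Pearson r between
    each feature and the actual outcome (``against="actual"``) or the
    out-of-fold predictions (``against="predicted"``); constant features
    get correlation 0 with a log note. Records are sorted by importance,
    descending.
    """
    if not models:
        raise ValueError("need at least one fitted forest model")
    imp = np.mean([m.feature_importances_ for m in models], axis=0)
    total = imp.sum()
    if total <= 0:
        raise ValueError("all importances are zero")
    imp_pct = imp / total * 100.0
    if against == "actual":
        target = np.asarray(y, dtype=float)
    elif against == "predicted":
        if oof_predictions is None:
            raise ValueError("against='predicted' requires oof_predictions")
        target = np.asarray(oof_predictions, dtype=float)
    else:
        raise ValueError("against must be 'actual' or 'predicted'")
    X = np.asarray(X, dtype=float)
    sds = X.std(axis=0)
    corr = np.zeros(X.shape[1])
    ok = sds > 1e-12 * (1.0 + np.abs(X).max(axis=0))  # constant up to roundoff
    if target.std() > 0 and ok.any():
        centered = X[:, ok] - X[:, ok].mean(axis=0)
        tc = target - target.mean()
        corr[ok] = (centered.T @ tc) / (
            np.sqrt((centered**2).sum(axis=0)) * math.sqrt((tc**2).sum())
        )
    if (~ok).any():
        logger.info("constant features %s: correlation set to 0", np.flatnonzero(~ok)[:10])
    records = [
        ImportanceRecord(int(i), float(imp_pct[i]), float(corr[i]))
        for i in range(X.shape[1])
    ]
    records.sort(key=lambda r: -r.importance_pct)
    return records


def error_analysis(
    ids: Sequence[str],
    actual: np.ndarray,
    predicted: np.ndarray,
    thresholds: Sequence[float] = (4.0, 2.5),
) -> tuple[pd.DataFrame, dict[float, pd.DataFrame]]:
    """Signed-error table and absolute-error threshold subsets.

    signed_error = actual - predicted (percentage points; positive means
    the model under-predicted). The full table is ranked by signed error
    descending; for each threshold the subset with |signed_error| >=
    threshold is returned (the per-tract "RMSE" of a single out-of-fold
    prediction is its absolute error).
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if not (len(ids) == len(actual) == len(predicted)):
        raise ValueError("ids, actual and predicted must be aligned")
    table = pd.DataFrame(
        {
            "tract_id": list(ids),
            "actual": actual,
            "predicted": predicted,
            "signed_error": actual - predicted,
        }
    ).sort_values("signed_error", ascending=False, kind="mergesort", ignore_index=True)
    subsets = {
        float(th): table[table["signed_error"].abs() >= th].reset_index(drop=True)
        for th in thresholds
    }
    return table, subsets
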