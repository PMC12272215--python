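"""Ridge age regression with subject-grouped Monte-Carlo cross-validation.

Features are z-scored with training-set statistics, the ridge
regularization strength is selected by closed-form generalized
leave-one-out (LOO) on the training fold over a 100-point log-uniform
grid spanning 1e-5..1e10, and performance is evaluated on held-out
subjects with R^2 and MAE against a dummy predictor that always outputs
the training median age.  Subjects are split atomically: all sessions
of a subject land on the same side of every split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.model_selection import GroupShuffleSplit

from .features import (
    CovarianceSet,
    TangentReference,
    assemble_features,
    fit_tangent_reference,
)

#: the regularization grid: 100 values log-uniform between 1e-5 and 1e10
DEFAULT_ALPHA_GRID = np.logspace(-5, 10, 100)


def r2_score(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination: 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.size < 2:
        raise ValueError("R^2 needs at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 is undefined for constant targets")
    return 1.0 - float(np.sum((y - y_pred) ** 2)) / ss_tot


def mae_score(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute error in years."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.size == 0:
        raise ValueError("y and y_pred must be non-empty and equal-length")
    return float(np.mean(np.abs(y - y_pred)))


def dummy_baseline(train_ages: np.ndarray, test_ages: np.ndarray) -> tuple[float, float]:
    """Scores of the constant predictor emitting the training median age."""
    train_ages = np.asarray(train_ages, dtype=float)
    if train_ages.size == 0:
        raise ValueError("empty training ages")
    pred = np.full(np.asarray(test_ages).shape, np.median(train_ages))
    return r2_score(test_ages, pred), mae_score(test_ages, pred)


# ---------------------------------------------------------------------------
# scaling and ridge


def zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Training mean and SD per column; zero-variance columns pass through.

    Constant columns get scale 1 (values unchanged after centring) and
    trigger a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two training rows to fit the scaler")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    constant = std == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance feature(s) passed through unscaled"
        )
        std = np.where(constant, 1.0, std)
    return mean, std


@dataclass
class ModelBundle:
    """A fitted scaler + ridge model with its selection diagnostics."""

    mean_: np.ndarray
    scale_: np.ndarray
    coef_: np.ndarray
    intercept_: float
    alpha_: float
    alpha_grid: np.ndarray
    loo_mse_: np.ndarray
    feature_index: list | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return Xs @ self.coef_ + self.intercept_


def ridge_loo_errors(
    X: np.ndarray, y: np.ndarray, alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID
) -> np.ndarray:
    """Closed-form leave-one-out squared errors per alpha (no refit loop).

    For ridge with an unpenalized intercept, centring the design makes
    the intercept column orthogonal to the features, so the hat matrix
    is H = 11^T/n + U diag(s^2/(s^2+a)) U^T with X_c = U S V^T, and the
    exact LOO residual of row i is (y_i - yhat_i) / (1 - H_ii).

    Returns mean squared LOO error per alpha.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least three rows for generalized LOO")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    u, s, _ = linalg.svd(Xc, full_matrices=False)
    uty = u.T @ yc
    s2 = s**2
    out = np.empty(len(alpha_grid))
    for k, alpha in enumerate(alpha_grid):
        d = s2 / (s2 + alpha)
        fitted = u @ (d * uty)
        h = 1.0 / n + np.einsum("ij,j,ij->i", u, d, u)
        resid = (yc - fitted) / (1.0 - h)
        out[k] = float(np.mean(resid**2))
    return out


def ridge_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID,
    feature_index: list | None = None,
) -> ModelBundle:
    """Z-score, select alpha by generalized LOO, refit on all rows."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size == 0:
        raise ValueError("alpha grid is empty")
    mean, scale = zscore_fit(X)
    Xs = (X - mean) / scale
    loo = ridge_loo_errors(Xs, y, alpha_grid)
    alpha = float(alpha_grid[int(np.argmin(loo))])
    coef, intercept = _solve_ridge(Xs, y, alpha)
    return ModelBundle(
        mean_=mean,
        scale_=scale,
        coef_=coef,
        intercept_=intercept,
        alpha_=alpha,
        alpha_grid=alpha_grid,
        loo_mse_=loo,
        feature_index=feature_index,
    )


def _solve_ridge(X: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Ridge with unpenalized intercept via SVD of the centred design."""
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    u, s, vt = linalg.svd(Xc, full_matrices=False)
    d = s / (s**2 + alpha)
    coef = vt.T @ (d * (u.T @ (y - y_mean)))
    intercept = float(y_mean - x_mean @ coef)
    return coef, intercept


# ---------------------------------------------------------------------------
# dataset-level feature extraction (fit on train, apply to test)


class FeatureExtractor:
    """Fits tangent references and imputation means on training recordings.

    ``cov_sets`` entries are single :class:`CovarianceSet` objects for
    meditation or stage -> CovarianceSet-or-None mappings for sleep.
    Missing-stage NaN blocks are imputed with training-set column means.
    """

    def __init__(self, variant: str, modality: str):
        self.variant = variant
        self.modality = modality
        self.reference: TangentReference | None = None
        self.impute_: np.ndarray | None = None
        self.index: list | None = None

    def _flatten(self, cov_sets) -> list[CovarianceSet]:
        if self.modality == "meditation":
            return list(cov_sets)
        flat: list[CovarianceSet] = []
        for mapping in cov_sets:
            flat.extend(cs for cs in mapping.values() if cs is not None)
        return flat

    def fit(self, cov_sets: Sequence, fitted_on: str = "train") -> "FeatureExtractor":
        if self.variant != "spectral":
            self.reference = fit_tangent_reference(
                self._flatten(cov_sets),
                use_cross=self.variant == "cross-spectro-spatial",
                fitted_on=fitted_on,
            )
        X = self._raw_matrix(cov_sets)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            col_means = np.nanmean(X, axis=0)
        self.impute_ = np.where(np.isfinite(col_means), col_means, 0.0)
        return self

    def _raw_matrix(self, cov_sets: Sequence) -> np.ndarray:
        rows = []
        for cs in cov_sets:
            fv = assemble_features(cs, self.variant, self.modality, self.reference)
            if self.index is None:
                self.index = fv.index
            rows.append(fv.values)
        return np.vstack(rows)

    def transform(self, cov_sets: Sequence) -> np.ndarray:
        if self.impute_ is None:
            raise RuntimeError("FeatureExtractor must be fitted before transform")
        X = self._raw_matrix(cov_sets)
        nan_mask = ~np.isfinite(X)
        if nan_mask.any():
            X[nan_mask] = np.broadcast_to(self.impute_, X.shape)[nan_mask]
        return X

    def fit_transform(self, cov_sets: Sequence, fitted_on: str = "train") -> np.ndarray:
        return self.fit(cov_sets, fitted_on).transform(cov_sets)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class EvalResult:
    """Per-split scores, pooled predictions, and optional fitted artifacts."""

    per_split: pd.DataFrame
    predictions: pd.DataFrame
    artifacts: list[dict] = field(default_factory=list)

    def summary(self) -> dict[str, float]:
        return {
            "median_r2": float(self.per_split["r2"].median()),
            "median_mae": float(self.per_split["mae"].median()),
            "median_dummy_r2": float(self.per_split["dummy_r2"].median()),
            "median_dummy_mae": float(self.per_split["dummy_mae"].median()),
        }


def monte_carlo_cv(
    data,
    ages: np.ndarray,
    subjects: Sequence[str],
    *,
    variant: str | None = None,
    modality: str | None = None,
    n_splits: int = 100,
    test_frac: float = 0.1,
    seed: int = 0,
    alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID,
    keep_models: bool = False,
    session_ids: Sequence[str] | None = None,
) -> EvalResult:
    """Subject-grouped shuffle-split evaluation (default 100 x 10% test).

    ``data`` is either a precomputed feature matrix (rows = recordings)
    or a list of per-recording covariance structures, in which case
    ``variant`` and ``modality`` select the extractor that is re-fitted
    on each training fold (tangent references and imputation means never
    see test subjects).
    """
    ages = np.asarray(ages, dtype=float)
    subjects = np.asarray(subjects)
    n = len(ages)
    if np.unique(subjects).size < 10:
        raise ValueError("need at least 10 distinct subjects for grouped CV")
    precomputed = isinstance(data, np.ndarray)
    if not precomputed and (variant is None or modality is None):
        raise ValueError("variant and modality are required for covariance input")

    splitter = GroupShuffleSplit(n_splits=n_splits, test_size=test_frac, random_state=seed)
    rows, preds, artifacts = [], [], []
    for split_id, (tr, te) in enumerate(splitter.split(np.zeros(n), groups=subjects)):
        if precomputed:
            X_train, X_test = data[tr], data[te]
            index = None
        else:
            extractor = FeatureExtractor(variant, modality)
            X_train = extractor.fit_transform([data[i] for i in tr])
            X_test = extractor.transform([data[i] for i in te])
            index = extractor.index
        bundle = ridge_fit(X_train, ages[tr], alpha_grid, feature_index=index)
        y_pred = bundle.predict(X_test)
        r2 = r2_score(ages[te], y_pred)
        mae = mae_score(ages[te], y_pred)
        dummy_r2, dummy_mae = dummy_baseline(ages[tr], ages[te])
        rows.append(
            {
                "split": split_id,
                "r2": r2,
                "mae": mae,
                "dummy_r2": dummy_r2,
                "dummy_mae": dummy_mae,
                "n_test": len(te),
                "test_subjects": tuple(sorted(set(subjects[te]))),
            }
        )
        pred_df = pd.DataFrame(
            {
                "split": split_id,
                "subject_id": subjects[te],
                "y": ages[te],
                "y_pred": y_pred,
            }
        )
        if session_ids is not None:
            pred_df.insert(2, "session_id", np.asarray(session_ids)[te])
        preds.append(pred_df)
        if keep_models:
            artifacts.append(
                {"split": split_id, "bundle": bundle, "X_test": X_test,
                 "y_test": ages[te], "test_rows": te}
            )
    return EvalResult(
        per_split=pd.DataFrame(rows),
        predictions=pd.concat(preds, ignore_index=True),
        artifacts=artifacts,
    )
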