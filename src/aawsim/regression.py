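"""Composition-only regression of binding profiles.

The model is linear in amino-acid composition: ``s = X w + eps`` where
``X`` is the (n_pep, 20) composition matrix and ``w`` the 20-vector of
amino-acid-associated weights (AAWS).  ``w`` is estimated by partial least
squares (PLS) regression; predictive performance is quantified by
cross-validated Q^2,

    Q^2 = 1 - sum((s_hat_leftout - s_leftout)^2) / sum(s_leftout^2),

pooled over the left-out folds (10-fold by default).  Q^2 = 1 means perfect
prediction, Q^2 <= 0 no better than predicting zero (the global mean, since
profiles are centred).

Measured intensities can first be cleared of the polyclonal
secondary-antibody signal by regressing log(I) on log(I_secondary) and
keeping the centred, unit-variance residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .binding import BindingProfile


@dataclass(frozen=True)
class AAWSEstimate:
    """A fitted 20-vector of amino-acid-associated weights.

    ``w`` follows the canonical alphabet order; ``intercept`` is the fitted
    centring offset; ``residuals`` are s - (X w + intercept) on the training
    data; ``n_components`` the number of PLS components actually used.
    """

    w: np.ndarray
    intercept: float
    residuals: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (20,):
            raise ValueError("w must be a 20-vector")
        object.__setattr__(self, "w", w)
        object.__setattr__(
            self, "residuals", np.asarray(self.residuals, dtype=float)
        )


@dataclass(frozen=True)
class CorrectionModel:
    """Fitted secondary-antibody correction log(I) = b0 + b1 log(I_sec) + eps."""

    intercept: float
    slope: float
    residuals: np.ndarray


@dataclass(frozen=True)
class CvResult:
    """Cross-validation outcome: pooled Q^2, the fold id of every peptide and
    the per-fold prediction error sums (PRESS)."""

    q2: float
    fold_assignments: np.ndarray
    per_fold_press: list[float]


def _coef_path(X: np.ndarray, y: np.ndarray, max_components: int):
    """PLS coefficient vectors for 1..max_components components from one fit.

    NIPALS components are nested, so a single decomposition yields the whole
    path: with x-weights W, x-loadings P and y-loadings Q, the k-component
    coefficient vector on centred (unscaled) data is

        B_k = W_k (P_k^T W_k)^{-1} Q_k^T.

    The path is truncated once a component degenerates (the centred
    composition matrix has rank 19, not 20, because every row sums to the
    peptide length, so a 20th component has nothing left to extract).

    Returns (coefs, intercepts): coefs[k-1] is the coefficient vector for k
    components, intercepts[k-1] the matching offset.
    """
    max_components = min(max_components, X.shape[1], X.shape[0] - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=max_components, scale=False)
        pls.fit(X, y)
    W = pls.x_weights_              # (n_features, K)
    P = pls.x_loadings_             # (n_features, K)
    Q = pls.y_loadings_             # (1, K)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    x_scale = max(float(np.abs(X - x_mean).max()), 1.0)
    coefs, intercepts = [], []
    for k in range(1, W.shape[1] + 1):
        M = P[:, :k].T @ W[:, :k]
        try:
            B = W[:, :k] @ np.linalg.solve(M, Q[:, :k].T)
        except np.linalg.LinAlgError:
            break
        w = B.ravel()
        # degenerate extra component: exploding or non-finite coefficients
        if not np.all(np.isfinite(w)) or np.abs(w).max() * x_scale > 1e8 * (
            1.0 + np.abs(y).max()
        ):
            break
        coefs.append(w)
        intercepts.append(float(y_mean - x_mean @ w))
    if not coefs:
        raise ValueError("PLS decomposition failed: no usable components")
    return coefs, intercepts


def select_n_components(
    s: np.ndarray,
    X: np.ndarray,
    max_components: int = 20,
    folds: int = 5,
    seed: int = 0,
) -> int:
    """Choose the number of PLS components by seeded k-fold cross-validation,
    minimizing the pooled squared prediction error over 1..max_components."""
    X = np.asarray(X, dtype=float)
    s = np.asarray(s, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    n_eval = min(max_components, X.shape[1])
    press = np.zeros(n_eval)
    counted = np.full(n_eval, True)
    for train, test in kf.split(X):
        coefs, intercepts = _coef_path(X[train], s[train], n_eval)
        for k in range(n_eval):
            if k < len(coefs):
                pred = X[test] @ coefs[k] + intercepts[k]
                press[k] += float(((pred - s[test]) ** 2).sum())
            else:
                counted[k] = False
    press[~counted] = np.inf
    return int(np.argmin(press)) + 1


def fit_aaws(
    s: BindingProfile | np.ndarray,
    X: np.ndarray,
    n_components: int | None = None,
    seed: int = 0,
) -> AAWSEstimate:
    """Fit the composition-only model s = X w + eps by PLS regression.

    Parameters
    ----------
    s : BindingProfile or array
        Normalized profile (mean 0, unit variance).
    X : array, shape (n_pep, 20)
        Composition matrix, rows aligned with s.
    n_components : int, optional
        Fixed number of PLS components (1..20).  If None, the number is
        chosen per fit by internal 5-fold cross-validation, which with only
        20 predictors is cheap and reproducible.
    seed : int
        Seed for the internal component-selection folds (ignored when
        n_components is fixed).

    Notes
    -----
    At 20 components on a full-column-rank X the PLS solution coincides with
    ordinary least squares.
    """
    y = s.values if isinstance(s, BindingProfile) else np.asarray(s, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 20:
        raise ValueError("X must be an (n_pep, 20) composition matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X row count does not match profile length")
    if np.ptp(y) == 0:
        raise ValueError("constant profile cannot be fitted")
    if not np.any(X):
        raise ValueError("zero composition matrix cannot be fitted")
    if n_components is None:
        n_components = select_n_components(y, X, seed=seed)
    if not 1 <= n_components <= 20:
        raise ValueError("n_components must be in 1..20")
    coefs, intercepts = _coef_path(X, y, n_components)
    k = min(n_components, len(coefs))
    w, b = coefs[k - 1], intercepts[k - 1]
    residuals = y - (X @ w + b)
    return AAWSEstimate(w=w, intercept=b, residuals=residuals, n_components=k)


def predict_signal(X: np.ndarray, est: AAWSEstimate) -> np.ndarray:
    """Predict a profile from composition alone: s_hat = X w + intercept."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != est.w.shape[0]:
        raise ValueError("X column count does not match weight vector")
    return X @ est.w + est.intercept


def q2_score(s_leftout: np.ndarray, s_hat: np.ndarray) -> float:
    """Predictive performance Q^2 = 1 - PRESS / sum(s_leftout^2).

    The denominator is the raw sum of squares of the left-out values (the
    profile is globally centred, so this approximates its total variance).
    """
    s_leftout = np.asarray(s_leftout, dtype=float)
    s_hat = np.asarray(s_hat, dtype=float)
    if s_leftout.shape != s_hat.shape:
        raise ValueError("shape mismatch between predictions and observations")
    denom = float((s_leftout**2).sum())
    if denom == 0:
        raise ValueError("left-out values are all zero; Q^2 undefined")
    return 1.0 - float(((s_hat - s_leftout) ** 2).sum()) / denom


def q2_cross_validation(
    s: BindingProfile | np.ndarray,
    X: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    n_components: int | None = None,
    fold_assignments: np.ndarray | None = None,
) -> CvResult:
    """Cross-validated predictive performance of the composition-only model.

    The peptides are partitioned at random (seeded) into ``folds`` groups
    (or according to an explicit ``fold_assignments`` vector of fold ids);
    for each group the model is fitted on the remainder and predicts the
    group.  Q^2 pools all left-out predictions into one global score.
    """
    y = s.values if isinstance(s, BindingProfile) else np.asarray(s, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.shape[0]
    if fold_assignments is not None:
        fold_assignments = np.asarray(fold_assignments, dtype=int)
        if fold_assignments.shape != (n,):
            raise ValueError("fold_assignments must give one fold id per peptide")
        splits = [
            (np.flatnonzero(fold_assignments != f), np.flatnonzero(fold_assignments == f))
            for f in np.unique(fold_assignments)
        ]
    else:
        if folds < 2:
            raise ValueError("folds must be >= 2")
        if n // folds < 2:
            raise ValueError("each fold needs at least 2 peptides")
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(kf.split(X))
    if any(len(test) < 2 for _, test in splits):
        raise ValueError("each fold needs at least 2 peptides")
    assignments = np.empty(n, dtype=int)
    press: list[float] = []
    pred = np.empty(n)
    for fold_id, (train, test) in enumerate(splits):
        assignments[test] = fold_id
        est = fit_aaws(y[train], X[train], n_components=n_components, seed=seed)
        pred[test] = predict_signal(X[test], est)
        press.append(float(((pred[test] - y[test]) ** 2).sum()))
    return CvResult(
        q2=q2_score(y, pred), fold_assignments=assignments, per_fold_press=press
    )


def secondary_correction(
    log_intensity: np.ndarray, log_secondary: np.ndarray
) -> tuple[BindingProfile, CorrectionModel]:
    """Remove the polyclonal secondary-antibody signal from log intensities.

    Fits log(I) = b0 + b1 * log(I_secondary) + eps by least squares (with a
    single predictor, PLS and ordinary least squares coincide) and returns
    the residuals centred to mean 0 and scaled to unit variance, ready for
    the composition regression.
    """
    y = np.asarray(log_intensity, dtype=float)
    x = np.asarray(log_secondary, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("log_intensity and log_secondary must be equal-length vectors")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("constant secondary channel: slope unidentifiable")
    b1, b0 = np.polyfit(x, y, 1)
    resid = y - (b0 + b1 * x)
    sd = resid.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("degenerate profile: secondary channel explains all signal")
    corrected = BindingProfile(
        values=(resid - resid.mean()) / sd, stage="normalized"
    )
    return corrected, CorrectionModel(
        intercept=float(b0), slope=float(b1), residuals=resid
    )
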