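"""Stacking of the mean-block and sd-block TVC predictions.

Three combiners are provided, in increasing sophistication: elementwise
averaging; a linear partial-least-squares meta-model on (X_mean, X_sd); and a
degree-4 polynomial meta-model

    Y = b0 + sum_{d=1..4} (b_m,d X_mean^d + b_s,d X_sd^d)

fit by NIPALS partial-least-squares component extraction on the standardized
power basis (coefficients are reported back in raw units).  Meta-training
inputs should be out-of-fold base predictions, never in-sample fits — the
:func:`oof_predictions` helper produces them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

META_KINDS = ("pls_linear", "poly4_nipals")


@dataclass
class StackedPredictions:
    """Aligned base predictions (and targets, when training a meta-model)."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x_mean = np.asarray(self.x_mean, float).ravel()
        self.x_sd = np.asarray(self.x_sd, float).ravel()
        if self.x_mean.shape != self.x_sd.shape:
            raise ValueError("base prediction vectors must be aligned")
        if self.y is not None:
            self.y = np.asarray(self.y, float).ravel()
            if self.y.shape != self.x_mean.shape:
                raise ValueError("targets must align with base predictions")
        for name in ("x_mean", "x_sd"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")


def average_combine(x_mean, x_sd) -> np.ndarray:
    """Elementwise average of the two base predictions."""
    sp = StackedPredictions(x_mean, x_sd)
    return (sp.x_mean + sp.x_sd) / 2.0


def _poly_basis(x_mean: np.ndarray, x_sd: np.ndarray, degree: int) -> np.ndarray:
    """Power basis [Xm, Xs, Xm^2, Xs^2, ...] up to ``degree`` (no intercept)."""
    cols = []
    for d in range(1, degree + 1):
        cols.append(x_mean**d)
        cols.append(x_sd**d)
    return np.column_stack(cols)


class MetaPLSRegressor(RegressorMixin, BaseEstimator):
    """Stacking meta-model fit by NIPALS partial least squares.

    ``kind='pls_linear'`` regresses on (X_mean, X_sd); ``kind='poly4_nipals'``
    on the degree-4 power basis of each base prediction.  The basis is
    z-scored before component extraction (the powers are strongly collinear);
    ``n_components=None`` picks the component count by inner k-fold
    cross-validation up to ``max_components``.

    Attributes
    ----------
    coefficients_ : ndarray
        Raw-unit coefficients, intercept first then basis terms in order
        (Xm, Xs, Xm^2, Xs^2, ...) — 3 values for pls_linear, 9 for poly4.
    n_components_ : int
    """

    def __init__(self, kind: str = "poly4_nipals", n_components: int | None = None,
                 max_components: int = 4, cv: int = 5, seed: int = 0):
        self.kind = kind
        self.n_components = n_components
        self.max_components = max_components
        self.cv = cv
        self.seed = seed

    @property
    def _degree(self) -> int:
        return 4 if self.kind == "poly4_nipals" else 1

    def _basis(self, x_mean, x_sd) -> np.ndarray:
        return _poly_basis(np.asarray(x_mean, float).ravel(),
                           np.asarray(x_sd, float).ravel(), self._degree)

    def fit(self, X, y):
        """Fit on stacked base predictions ``X`` of shape (n, 2) and targets."""
        if self.kind not in META_KINDS:
            raise ValueError(f"kind must be one of {META_KINDS}")
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float).ravel()
        B = self._basis(X[:, 0], X[:, 1])
        n, p = B.shape
        if self.kind == "poly4_nipals" and n < p + 2:
            raise ValueError(
                f"poly4 meta-model needs at least {p + 2} rows, got {n}"
            )
        self.basis_mean_ = B.mean(axis=0)
        sd = B.std(axis=0)
        if np.any(sd == 0):
            raise ValueError(
                "degenerate polynomial basis (too few distinct base-prediction "
                "values); provide more data"
            )
        self.basis_scale_ = sd
        Z = (B - self.basis_mean_) / self.basis_scale_

        cap = min(self.max_components, p, n - 1)
        if self.n_components is not None:
            ncomp = min(self.n_components, p, n - 1)
        else:
            ncomp = self._select_components(Z, y, cap)
        pls = PLSRegression(n_components=ncomp, scale=False).fit(Z, y)
        self._pls = pls
        self.n_components_ = ncomp
        coef_z = np.ravel(pls.coef_)
        beta = coef_z / self.basis_scale_
        intercept = float(y.mean() - beta @ self.basis_mean_)
        self.coefficients_ = np.concatenate([[intercept], beta])
        return self

    def _select_components(self, Z, y, cap: int) -> int:
        n = len(y)
        folds = KFold(min(self.cv, n), shuffle=True, random_state=self.seed)
        best, best_rmse = 1, np.inf
        for k in range(1, cap + 1):
            errs = []
            for tr, te in folds.split(Z):
                if len(tr) <= k:
                    continue
                model = PLSRegression(n_components=k, scale=False).fit(Z[tr], y[tr])
                errs.append(np.mean((np.ravel(model.predict(Z[te])) - y[te]) ** 2))
            rmse = float(np.sqrt(np.mean(errs))) if errs else np.inf
            if rmse < best_rmse - 1e-12:
                best, best_rmse = k, rmse
        return best

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        Z = (self._basis(X[:, 0], X[:, 1]) - self.basis_mean_) / self.basis_scale_
        return np.ravel(self._pls.predict(Z))

    def to_json(self, path) -> None:
        payload = {"kind": self.kind, "n_components": self.n_components_,
                   "coefficients": self.coefficients_.tolist()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def fit_meta(sp: StackedPredictions, kind: str = "poly4_nipals",
             **kwargs) -> MetaPLSRegressor:
    """Fit a meta-model on (out-of-fold) base predictions with targets."""
    if sp.y is None:
        raise ValueError("StackedPredictions must carry targets to fit a meta-model")
    X = np.column_stack([sp.x_mean, sp.x_sd])
    return MetaPLSRegressor(kind=kind, **kwargs).fit(X, sp.y)


def predict_meta(meta, x_mean, x_sd) -> np.ndarray:
    """Evaluate a meta-model, or an explicit raw coefficient vector.

    A coefficient vector is intercept first, then (Xm, Xs) pairs of
    increasing degree: length 9 evaluates the degree-4 polynomial
    Y = b0 + sum_d (b_m,d Xm^d + b_s,d Xs^d).
    """
    x_mean = np.asarray(x_mean, float).ravel()
    x_sd = np.asarray(x_sd, float).ravel()
    if not (np.all(np.isfinite(x_mean)) and np.all(np.isfinite(x_sd))):
        raise ValueError("non-finite base predictions")
    if isinstance(meta, MetaPLSRegressor):
        return meta.predict(np.column_stack([x_mean, x_sd]))
    coeffs = np.asarray(meta, float).ravel()
    if (len(coeffs) - 1) % 2 != 0:
        raise ValueError("coefficient vector must be intercept + (Xm, Xs) pairs")
    degree = (len(coeffs) - 1) // 2
    out = np.full_like(x_mean, coeffs[0])
    for d in range(1, degree + 1):
        out = out + coeffs[2 * d - 1] * x_mean**d + coeffs[2 * d] * x_sd**d
    return out


def oof_predictions(X, y, base_estimator, n_splits: int = 5, seed: int = 0,
                    fit_params: dict | None = None) -> np.ndarray:
    """Out-of-fold predictions of one base model (for leakage-free stacking)."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    preds = np.full(len(y), np.nan)
    folds = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for tr, te in folds.split(X):
        model = clone(base_estimator)
        model.fit(X[tr], y[tr])
        preds[te] = np.asarray(model.predict(X[te])).ravel()
    return preds
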