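"""Clustering-initialized asymmetric-Gaussian TSK neuro-fuzzy regressor.

The network has the classic five-layer TSK layout: an input layer, a
membership layer of asymmetric Gaussian functions (one center c_ij with
separate left/right spreads), a product rule layer R_i = prod_j A_ij(x_j), a
normalization layer Rbar_i = R_i / sum_j R_j, and an affine consequent layer
O = sum_i Rbar_i (w_i . x + w_i0).  The number of rules equals the number of
clusters found by the two-stage clustering initializer and never changes
during training.

During the forward pass each membership uses the *total* spread
b_ij = sigma_left + sigma_right:

    A_ij(x) = exp(-(x - c_ij)^2 / (2 b_ij^2)),

and records which side of the center the input fell on.  Training is hybrid,
ANFIS-style: recursive least squares (RLS) on the consequent weights over the
regressor vector (Rbar_1 [x, 1], ..., Rbar_c [x, 1]), and per-sample gradient
descent on the premise — centers by the chain rule, and the total spread's
gradient step producing sigma_new of which only the recorded side is set to
sigma_new / 2 (the other side is left unchanged).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .clustering import FuzzyPartition, TwoStageClusterer

SPREAD_FLOOR_FRAC = 1e-3


class TrainingDivergedError(RuntimeError):
    """Epoch RMSE became non-finite; try a smaller learning rate."""


@dataclass
class AsymmetricMF:
    """One asymmetric Gaussian membership function.

    ``side_index`` records the side ("left"/"right") the last evaluated input
    fell on; it steers the side-specific spread update during learning.
    """

    center: float
    sigma_left: float
    sigma_right: float
    side_index: str | None = None

    def __post_init__(self) -> None:
        if self.sigma_left <= 0 or self.sigma_right <= 0:
            raise ValueError("spreads must be positive")

    @property
    def sigma_total(self) -> float:
        return self.sigma_left + self.sigma_right


def membership(mf: AsymmetricMF, x: float) -> float:
    """Membership degree exp(-(x-c)^2 / (2 (sl+sr)^2)); records the side."""
    if not np.isfinite(x):
        raise ValueError("input must be finite")
    mf.side_index = "left" if x < mf.center else "right"
    b = mf.sigma_total
    return float(np.exp(-((x - mf.center) ** 2) / (2.0 * b * b)))


def _forward(X, centers, b, consequents):
    """Vectorized forward pass.

    Returns (R, Rbar, F, O) with shapes (n,c), (n,c), (n,c), (n,).
    All-underflow rows fall back to uniform normalized strengths.
    """
    X = np.atleast_2d(X)
    A = np.exp(-((X[:, None, :] - centers[None, :, :]) ** 2) / (2.0 * b[None] ** 2))
    R = A.prod(axis=2)                       # (n, c)
    S = R.sum(axis=1, keepdims=True)
    c = centers.shape[0]
    underflow = (S[:, 0] == 0.0)
    S_safe = np.where(S == 0.0, 1.0, S)
    Rbar = R / S_safe
    if underflow.any():
        Rbar[underflow] = 1.0 / c
    F = X @ consequents[:, :-1].T + consequents[:, -1]   # (n, c)
    O = (Rbar * F).sum(axis=1)
    return R, Rbar, F, O, int(underflow.sum())


def premise_gradients(x, y, centers, b, consequents):
    """Gradients of E = 0.5 (O - y)^2 w.r.t. centers and total spreads.

    The left/right indicator of the asymmetric membership is locally constant
    (zero derivative almost everywhere), so only the shared Gaussian body is
    differentiated.  Returns (grad_c, grad_b), each (c, q).
    """
    x = np.asarray(x, float)
    R, Rbar, F, O, _ = _forward(x[None, :], centers, b, consequents)
    R, Rbar, F, O = R[0], Rbar[0], F[0], float(O[0])
    e = O - y
    S = R.sum()
    if S == 0.0:          # uniform fallback region: premise gradient undefined, skip
        z = np.zeros_like(centers)
        return z, z.copy()
    dE_dR = e * (F - O) / S                       # (c,)
    diff = x[None, :] - centers                   # (c, q)
    grad_c = dE_dR[:, None] * R[:, None] * diff / b**2
    grad_b = dE_dR[:, None] * R[:, None] * diff**2 / b**3
    return grad_c, grad_b


class CAGFINNRegressor(RegressorMixin, BaseEstimator):
    """TSK neuro-fuzzy regressor with asymmetric Gaussian memberships.

    Parameters
    ----------
    radius_frac, lvq_rate, fuzzifier
        Settings of the two-stage clustering initializer (rule count is
        self-determined by the prototype stage).
    max_epochs, learning_rate, tol
        Hybrid-training controls; ``learning_rate`` is the premise
        gradient-descent step (inputs are standardized internally by
        default, so the default step is scale-free).
    rls_forgetting, rls_init_cov, rls_reset_per_epoch
        Recursive-least-squares settings for the consequent weights.
    standardize
        Z-score the inputs internally (fitted parameters are kept in the
        standardized space; prediction maps through automatically).

    Attributes
    ----------
    centers_, sigma_left_, sigma_right_ : (c, q) arrays
    consequents_ : (c, q+1) array, bias last
    n_rules_ : int
    training_log_ : list of per-epoch RMSE
    underflow_count_ : rule-strength underflow events during training
    """

    def __init__(self, radius_frac: float = 0.35, lvq_rate: float = 0.05,
                 fuzzifier: float = 2.0, max_epochs: int = 500,
                 learning_rate: float = 0.01, rls_forgetting: float = 1.0,
                 rls_init_cov: float = 1e4, tol: float = 1e-6,
                 rls_reset_per_epoch: bool = True, standardize: bool = True,
                 seed: int = 0):
        self.radius_frac = radius_frac
        self.lvq_rate = lvq_rate
        self.fuzzifier = fuzzifier
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.rls_forgetting = rls_forgetting
        self.rls_init_cov = rls_init_cov
        self.tol = tol
        self.rls_reset_per_epoch = rls_reset_per_epoch
        self.standardize = standardize
        self.seed = seed

    # -- helpers -----------------------------------------------------------
    def _to_internal(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean_) / self.x_scale_

    def fit(self, X, y, init: FuzzyPartition | None = None):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float).ravel()
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        n, q = X.shape
        if not 0.0 < self.rls_forgetting <= 1.0:
            raise ValueError("rls_forgetting must be in (0, 1]")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")

        if self.standardize:
            self.x_mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.x_scale_ = np.where(scale > 0, scale, 1.0)
        else:
            self.x_mean_ = np.zeros(q)
            self.x_scale_ = np.ones(q)
        Xi = self._to_internal(X)

        if init is None:
            clusterer = TwoStageClusterer(
                radius_frac=self.radius_frac, lvq_rate=self.lvq_rate,
                m=self.fuzzifier, seed=self.seed,
            ).fit(Xi, y)
            part = clusterer.partition_
            centers = part.centers.copy()
            sigma_init = part.sigma_init.copy()
        else:
            centers = (np.atleast_2d(init.centers) - self.x_mean_) / self.x_scale_
            sigma_init = np.atleast_2d(init.sigma_init) / self.x_scale_

        c = centers.shape[0]
        sigma_left = sigma_init / 2.0
        sigma_right = sigma_init / 2.0
        W = np.zeros((c, q + 1))

        coord_range = np.ptp(Xi, axis=0)
        b_floor = SPREAD_FLOOR_FRAC * np.where(coord_range > 0, coord_range, 1.0)

        lam = self.rls_forgetting
        dim = c * (q + 1)
        P = self.rls_init_cov * np.eye(dim)
        w_vec = W.ravel().copy()
        underflow_total = 0
        log: list[float] = []
        prev_rmse = np.inf

        for _ in range(self.max_epochs):
            if self.rls_reset_per_epoch:
                P = self.rls_init_cov * np.eye(dim)
            for k in range(n):
                x = Xi[k]
                b = sigma_left + sigma_right
                _, Rbar, _, _, uf = _forward(x[None, :], centers, b, W)
                underflow_total += uf
                phi = (Rbar[0][:, None] * np.append(x, 1.0)[None, :]).ravel()
                # RLS consequent update
                Pphi = P @ phi
                gain = Pphi / (lam + phi @ Pphi)
                w_vec = w_vec + gain * (y[k] - phi @ w_vec)
                P = (P - np.outer(gain, Pphi)) / lam
                W = w_vec.reshape(c, q + 1)
                # premise gradient-descent update (side recorded pre-update)
                if self.learning_rate > 0:
                    grad_c, grad_b = premise_gradients(x, y[k], centers, b, W)
                    left_side = x[None, :] < centers
                    centers = centers - self.learning_rate * grad_c
                    b_new = np.maximum(b - self.learning_rate * grad_b,
                                       b_floor[None, :])
                    half = b_new / 2.0
                    sigma_left = np.where(left_side, half, sigma_left)
                    sigma_right = np.where(~left_side, half, sigma_right)

            b = sigma_left + sigma_right
            _, _, _, O, _ = _forward(Xi, centers, b, W)
            rmse = float(np.sqrt(np.mean((O - y) ** 2)))
            if not np.isfinite(rmse):
                raise TrainingDivergedError(
                    "epoch RMSE is non-finite; reduce learning_rate"
                )
            log.append(rmse)
            if prev_rmse - rmse < self.tol and len(log) > 1:
                break
            prev_rmse = rmse

        self.centers_ = centers
        self.sigma_left_ = sigma_left
        self.sigma_right_ = sigma_right
        self.consequents_ = W
        self.n_rules_ = c
        self.n_features_in_ = q
        self.training_log_ = log
        self.underflow_count_ = underflow_total
        return self

    @classmethod
    def from_parameters(cls, centers, sigma_left, sigma_right, consequents,
                        x_mean=None, x_scale=None) -> "CAGFINNRegressor":
        """Build a ready-to-predict model from explicit parameters."""
        model = cls(standardize=False)
        model.centers_ = np.atleast_2d(np.asarray(centers, float))
        model.sigma_left_ = np.atleast_2d(np.asarray(sigma_left, float))
        model.sigma_right_ = np.atleast_2d(np.asarray(sigma_right, float))
        model.consequents_ = np.atleast_2d(np.asarray(consequents, float))
        c, q = model.centers_.shape
        if model.consequents_.shape != (c, q + 1):
            raise ValueError("consequents must have shape (c, q+1)")
        model.n_rules_ = c
        model.n_features_in_ = q
        model.x_mean_ = np.zeros(q) if x_mean is None else np.asarray(x_mean, float)
        model.x_scale_ = np.ones(q) if x_scale is None else np.asarray(x_scale, float)
        model.training_log_ = []
        model.underflow_count_ = 0
        return model

    def fire_rules(self, x):
        """Rule strengths and normalized strengths at one input point."""
        x = np.asarray(x, float).ravel()
        if x.shape != (self.n_features_in_,):
            raise ValueError("input dimension mismatch")
        xi = (x - self.x_mean_) / self.x_scale_
        b = self.sigma_left_ + self.sigma_right_
        R, Rbar, _, _, _ = _forward(xi[None, :], self.centers_, b, self.consequents_)
        return R[0], Rbar[0]

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("input dimension mismatch")
        Xi = self._to_internal(X)
        b = self.sigma_left_ + self.sigma_right_
        _, _, _, O, _ = _forward(Xi, self.centers_, b, self.consequents_)
        return O

    # -- persistence -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": self.get_params(),
            "centers": self.centers_.tolist(),
            "sigma_left": self.sigma_left_.tolist(),
            "sigma_right": self.sigma_right_.tolist(),
            "consequents": self.consequents_.tolist(),
            "x_mean": self.x_mean_.tolist(),
            "x_scale": self.x_scale_.tolist(),
            "training_log": self.training_log_,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "CAGFINNRegressor":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls.from_parameters(
            payload["centers"], payload["sigma_left"], payload["sigma_right"],
            payload["consequents"], payload["x_mean"], payload["x_scale"],
        )
        model.set_params(**payload["params"])
        model.training_log_ = payload.get("training_log", [])
        return model
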