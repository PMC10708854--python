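"""Two-stage clustering used to initialize the neuro-fuzzy rule base.

Stage one is a supervised, LVQ-flavoured incremental prototype allocation in
the standardized joint (input, target) space: a sample farther than
``radius_frac`` x (bounding-box diagonal of the standardized data) from every
existing prototype spawns a new prototype; otherwise the nearest prototype is
nudged toward it.  This self-determines the number of clusters — and hence
the number of fuzzy rules — with supervision entering through the target
coordinate.  Stage two refines the prototype input-coordinates with classic
fuzzy c-means (FCM).  Initial membership-function spreads are the
membership-weighted second moments around each refined center, square-rooted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

SPREAD_FLOOR_FRAC = 1e-3  # floor on spreads, as a fraction of coordinate range


class DegenerateClusterError(RuntimeError):
    pass


@dataclass
class FuzzyPartition:
    """Result of the two-stage clustering.

    ``centers`` is (c, q); ``U`` the (c, n) fuzzy membership matrix whose
    columns sum to one; ``sigma_init`` the (c, q) initial spreads.
    """

    centers: np.ndarray
    U: np.ndarray
    sigma_init: np.ndarray
    fuzzifier: float = 2.0

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, float))
        self.U = np.atleast_2d(np.asarray(self.U, float))
        self.sigma_init = np.atleast_2d(np.asarray(self.sigma_init, float))
        if self.centers.shape[0] < 1:
            raise ValueError("at least one cluster is required")
        col_sums = self.U.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValueError("columns of U must sum to 1")

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


# ---------------------------------------------------------------------------
# Stage 1: supervised prototype allocation
# ---------------------------------------------------------------------------

def supervised_prototype_stage(
    X,
    y,
    radius_frac: float = 0.35,
    lvq_rate: float = 0.05,
    seed: int | None = None,
    shuffle: bool = False,
):
    """Allocate prototypes incrementally in the standardized joint space.

    Returns the (c, q) prototype input-coordinates mapped back to original
    units (the target coordinate is dropped).  Deterministic for a fixed
    presentation order; ``seed`` only controls the optional shuffle.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, q = X.shape
    if n == 0:
        raise ValueError("at least one sample is required")
    if not 0.0 < radius_frac <= 1.0:
        raise ValueError("radius_frac must be in (0, 1]")

    Z = np.column_stack([X, y])
    mean = Z.mean(axis=0)
    scale = Z.std(axis=0)
    scale[scale == 0] = 1.0
    Zs = (Z - mean) / scale

    span = Zs.max(axis=0) - Zs.min(axis=0)
    diameter = float(np.sqrt(np.sum(span**2)))
    radius = radius_frac * diameter if diameter > 0 else radius_frac

    order = np.arange(n)
    if shuffle:
        order = np.random.default_rng(seed).permutation(n)

    prototypes = [Zs[order[0]].copy()]
    for idx in order[1:]:
        z = Zs[idx]
        d = np.array([np.linalg.norm(z - p) for p in prototypes])
        j = int(np.argmin(d))
        if d[j] > radius:
            prototypes.append(z.copy())
        else:
            prototypes[j] += lvq_rate * (z - prototypes[j])
    P = np.array(prototypes)
    centers_joint = P * scale + mean
    return centers_joint[:, :q]


# ---------------------------------------------------------------------------
# Stage 2: fuzzy c-means
# ---------------------------------------------------------------------------

class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Classic fuzzy c-means with user-supplied initial centers.

    Alternates membership and center updates of the standard FCM objective
    J_m = sum_ik u_ik^m d_ik^2 until the center shift falls below ``tol``.

    Attributes (after fit): ``cluster_centers_``, ``membership_`` (c, n),
    ``objective_history_``, ``n_iter_``, ``converged_``.
    """

    def __init__(self, centers_init=None, m: float = 2.0, tol: float = 1e-6,
                 max_iter: int = 300):
        self.centers_init = centers_init
        self.m = m
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
        # u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1)); points on a center get
        # crisp membership there (limit convention).
        d = np.linalg.norm(X[None, :, :] - centers[:, None, :], axis=2)  # (c, n)
        U = np.empty_like(d)
        zero = d < 1e-12
        any_zero = zero.any(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            power = d ** (-2.0 / (m - 1.0))
            U = power / power.sum(axis=0, keepdims=True)
        if any_zero.any():
            for k in np.flatnonzero(any_zero):
                col = np.zeros(len(centers))
                hits = np.flatnonzero(zero[:, k])
                col[hits] = 1.0 / len(hits)
                U[:, k] = col
        return U

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, float))
        if self.m <= 1.0:
            raise ValueError("fuzzifier m must be > 1")
        centers = np.atleast_2d(np.asarray(self.centers_init, float)).copy()
        c, n = centers.shape[0], X.shape[0]
        if c > n:
            raise ValueError("more clusters than samples")
        # collapse-protection: re-perturb coincident initial centers
        for i in range(c):
            for j in range(i):
                if np.allclose(centers[i], centers[j]):
                    warnings.warn("duplicate initial centers; perturbing")
                    jitter = 1e-6 * (np.ptp(X, axis=0) + 1.0)
                    centers[i] = centers[i] + jitter

        history = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            U = self._memberships(X, centers, self.m)
            Um = U**self.m
            new_centers = (Um @ X) / Um.sum(axis=1, keepdims=True)
            d = np.linalg.norm(X[None, :, :] - new_centers[:, None, :], axis=2)
            history.append(float(np.sum(Um * d**2)))
            shift = float(np.max(np.abs(new_centers - centers)))
            centers = new_centers
            if shift < self.tol:
                converged = True
                break
        self.cluster_centers_ = centers
        self.membership_ = self._memberships(X, centers, self.m)
        self.objective_history_ = history
        self.n_iter_ = it
        self.converged_ = converged
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        U = self._memberships(X, self.cluster_centers_, self.m)
        return np.argmax(U, axis=0)


def fcm_refine(X, centers_init, m: float = 2.0, tol: float = 1e-6,
               max_iter: int = 300) -> FuzzyPartition:
    """Refine initial centers with FCM and package the partition (with spreads)."""
    fcm = FuzzyCMeans(centers_init=centers_init, m=m, tol=tol, max_iter=max_iter).fit(X)
    if not fcm.converged_:
        warnings.warn("FCM did not converge within max_iter")
    sigma = init_spreads(X, fcm.cluster_centers_, fcm.membership_)
    return FuzzyPartition(
        centers=fcm.cluster_centers_, U=fcm.membership_, sigma_init=sigma, fuzzifier=m
    )


def init_spreads(X, centers, U) -> np.ndarray:
    """Membership-weighted second moment around each center, square-rooted.

    sigma_ij = sqrt( sum_k u_ik (x_kj - c_ij)^2 / sum_k u_ik ), floored at
    1e-3 x the coordinate-wise data range (so degenerate clusters cannot
    produce zero spreads downstream).
    """
    X = np.atleast_2d(np.asarray(X, float))
    centers = np.atleast_2d(np.asarray(centers, float))
    U = np.atleast_2d(np.asarray(U, float))
    totals = U.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.flatnonzero(totals <= 0)[0])
        raise DegenerateClusterError(f"cluster {bad} has zero total membership")
    diff2 = (X[None, :, :] - centers[:, None, :]) ** 2   # (c, n, q)
    sigma = np.sqrt((U[:, :, None] * diff2).sum(axis=1) / totals[:, None])
    coord_range = np.ptp(X, axis=0)
    floor = SPREAD_FLOOR_FRAC * np.where(coord_range > 0, coord_range, 1.0)
    return np.maximum(sigma, floor[None, :])


# ---------------------------------------------------------------------------
# Combined estimator
# ---------------------------------------------------------------------------

class TwoStageClusterer(ClusterMixin, BaseEstimator):
    """Supervised prototype allocation followed by FCM refinement.

    The emergent number of clusters equals the number of fuzzy rules of the
    downstream TSK network.  ``n_clusters_override`` forces a cluster count
    (k-means++-style subsampling of the stage-1 prototypes) — intended for
    tests only, the method's contract is self-determination.

    After fit: ``partition_`` (:class:`FuzzyPartition`), ``n_clusters_``.
    """

    def __init__(self, radius_frac: float = 0.35, lvq_rate: float = 0.05,
                 m: float = 2.0, tol: float = 1e-6, max_iter: int = 300,
                 seed: int | None = None, shuffle: bool = False,
                 n_clusters_override: int | None = None):
        self.radius_frac = radius_frac
        self.lvq_rate = lvq_rate
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed
        self.shuffle = shuffle
        self.n_clusters_override = n_clusters_override

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float).ravel()
        centers = supervised_prototype_stage(
            X, y, radius_frac=self.radius_frac, lvq_rate=self.lvq_rate,
            seed=self.seed, shuffle=self.shuffle,
        )
        if self.n_clusters_override is not None:
            k = self.n_clusters_override
            if k < len(centers):
                idx = np.linspace(0, len(centers) - 1, k).round().astype(int)
                centers = centers[np.unique(idx)]
        if len(centers) == 1 and X.shape[0] == 1:
            sigma = init_spreads(X, centers, np.ones((1, 1)))
            self.partition_ = FuzzyPartition(
                centers=centers, U=np.ones((1, X.shape[0])), sigma_init=sigma,
                fuzzifier=self.m,
            )
        else:
            self.partition_ = fcm_refine(
                X, centers, m=self.m, tol=self.tol, max_iter=self.max_iter
            )
        self.n_clusters_ = self.partition_.n_clusters
        self.labels_ = np.argmax(self.partition_.U, axis=0)
        return self
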