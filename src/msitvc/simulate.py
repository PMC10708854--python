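"""Synthetic multispectral meat-spoilage data.

The study data this package targets — beef fillets stored aerobically at
0/4/8/12/16 degC for up to 434 h, total viable counts (TVC) spanning roughly
3.0-9.9 log10 cfu cm^-2, with an 18-band multispectral signature per sample —
are not publicly deposited.  This module emulates their statistical structure
so every downstream stage (feature selection, neuro-fuzzy regression,
stacking, evaluation) is testable end to end:

* TVC trajectories follow the Baranyi-Roberts primary growth model with a
  Ratkowsky square-root secondary model for the temperature dependence of the
  maximum specific growth rate.
* Reflectance features are affinely coupled to TVC band by band (optionally
  with a quadratic term) plus additive Gaussian noise; a subset of bands gets
  zero slope so that feature selection has irrelevant bands to reject.

A separate generator draws data from a known Takagi-Sugeno-Kang (TSK) fuzzy
system, used for parameter-recovery tests of the neuro-fuzzy regressor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SpectralDataset
from .wavebands import N_BANDS, feature_columns

MAX_STORAGE_H = 434.0  # longest storage time in the emulated design

LN10 = np.log(10.0)


@dataclass
class GrowthParams:
    """Baranyi-Roberts growth parameters in log10 cfu cm^-2 units.

    ``mu_ref`` is the maximum specific growth rate (log10 units / h) at the
    reference temperature ``T_ref``; rates at other temperatures follow the
    Ratkowsky square-root model ``sqrt(mu) = b (T - T_min)``.  ``b_sqrt`` may
    be given explicitly; otherwise it is derived from ``mu_ref`` at ``T_ref``.
    ``h0`` is the dimensionless lag parameter (work to be done before
    exponential growth; h0 = 0 means no lag).
    """

    y0: float = 3.0
    ymax: float = 9.9
    mu_ref: float = 0.038
    h0: float = 1.5
    T_min: float = -5.0
    T_ref: float = 8.0
    b_sqrt: float | None = None

    def __post_init__(self) -> None:
        if not self.y0 < self.ymax:
            raise ValueError("y0 must be below ymax")
        if self.mu_ref <= 0:
            raise ValueError("mu_ref must be positive")
        if self.h0 < 0:
            raise ValueError("h0 must be non-negative")

    @property
    def sqrt_slope(self) -> float:
        if self.b_sqrt is not None:
            return self.b_sqrt
        return float(np.sqrt(self.mu_ref) / (self.T_ref - self.T_min))

    def mu(self, T: float) -> float:
        """Maximum specific growth rate (log10 units / h) at temperature T."""
        if T <= self.T_min:
            raise ValueError(f"temperature {T} degC is at or below T_min={self.T_min}")
        return float((self.sqrt_slope * (T - self.T_min)) ** 2)


def baranyi_tvc(t, T: float, gp: GrowthParams):
    """Baranyi-Roberts TVC at storage time ``t`` (hours) and temperature ``T``.

    y(t) = y0 + mu*A(t) - log10(1 + (10^(mu*A(t)) - 1) / 10^(ymax - y0)),
    A(t) = t + (1/nu) * ln(e^(-nu t) + e^(-h0) - e^(-nu t - h0)),

    with ``mu`` the log10-scale rate and ``nu = mu * ln(10)`` its natural-log
    counterpart.  y(0) = y0 exactly, y is non-decreasing and approaches
    ``ymax`` as t grows.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("storage time must be non-negative")
    mu = gp.mu(T)
    nu = mu * LN10
    # adjustment function A(t); ln term rewritten as e^-h0 + e^-nu*t (1 - e^-h0)
    lag = np.log(np.exp(-gp.h0) + np.exp(-nu * t) * (1.0 - np.exp(-gp.h0)))
    A = t + lag / nu
    u = mu * A                      # log10-scale unconstrained increment
    delta = gp.ymax - gp.y0
    # log10(1 + (10^u - 1) 10^-delta) = log10(10^(u-delta) + 1 - 10^-delta), stable
    a = u - delta
    c = 1.0 - 10.0 ** (-delta)
    m = np.maximum(a, 0.0)
    damp = m + np.log10(10.0 ** (a - m) + c * 10.0 ** (-m))
    y = gp.y0 + u - damp
    return y if y.ndim else float(y)


def time_to_level(level: float, T: float, gp: GrowthParams, t_hi: float = 1e6) -> float:
    """Storage time at which the growth curve first reaches ``level`` (bisection)."""
    if not gp.y0 <= level < gp.ymax:
        raise ValueError("level must lie in [y0, ymax)")
    lo, hi = 0.0, 1.0
    while baranyi_tvc(hi, T, gp) < level:
        hi *= 2.0
        if hi > t_hi:
            return t_hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if baranyi_tvc(mid, T, gp) < level:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _default_slopes_mean() -> np.ndarray:
    # visible bands (1-12) informative, near-infrared bands (13-18) irrelevant
    return np.array(
        [2.5, 2.2, 1.8, 1.6, 3.0, 1.9, 2.8, 2.4, 3.2, 2.0, 3.4, 3.6,
         0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
    )


def _default_slopes_sd() -> np.ndarray:
    return np.array(
        [0.0, 0.0, 0.0, 0.9, 0.8, 0.7, 0.6, 1.0, 0.5, 0.4, 0.6, 0.8,
         0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
    )


@dataclass
class SpectralResponseParams:
    """Coupling of the 18-band signature to TVC.

    Each feature block (mean reflectance; pixel-intensity sd) is generated as
    ``baseline[j] + slope[j] * tvc + quad[j] * tvc**2 + N(0, noise_sd)``.
    Bands with zero slope are irrelevant by construction.
    """

    baseline_mean: np.ndarray = field(
        default_factory=lambda: np.linspace(20.0, 60.0, N_BANDS)
    )
    slope_mean: np.ndarray = field(default_factory=_default_slopes_mean)
    baseline_sd: np.ndarray = field(
        default_factory=lambda: np.linspace(4.0, 10.0, N_BANDS)
    )
    slope_sd: np.ndarray = field(default_factory=_default_slopes_sd)
    quad_mean: np.ndarray = field(default_factory=lambda: np.zeros(N_BANDS))
    quad_sd: np.ndarray = field(default_factory=lambda: np.zeros(N_BANDS))
    noise_sd_mean: float = 2.0
    noise_sd_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_mean", "slope_mean", "baseline_sd", "slope_sd",
                     "quad_mean", "quad_sd"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (N_BANDS,):
                raise ValueError(f"{name} must have length {N_BANDS}")
            setattr(self, name, vec)
        if self.noise_sd_mean < 0 or self.noise_sd_sd < 0:
            raise ValueError("noise scales must be non-negative")


DEFAULT_TEMPS = (0.0, 4.0, 8.0, 12.0, 16.0)


def generate_dataset(
    n_per_temp: int = 17,
    temps=DEFAULT_TEMPS,
    sampling_hours=None,
    gp: GrowthParams | None = None,
    sp: SpectralResponseParams | None = None,
    seed: int | None = None,
) -> SpectralDataset:
    """Simulate a spoilage storage experiment.

    For each temperature, ``n_per_temp`` sampling times are taken (by default
    evenly spaced from 0 to the time the curve nears its asymptote, capped at
    434 h), TVC is evaluated on the growth curve, and the 36-feature spectral
    signature is drawn from the coupling model.  Identical parameters and seed
    give an identical dataset.
    """
    if n_per_temp < 1:
        raise ValueError("n_per_temp must be at least 1")
    temps = list(temps)
    if not temps:
        raise ValueError("temps must be non-empty")
    gp = gp or GrowthParams()
    sp = sp or SpectralResponseParams()
    seed = sp.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    rows = []
    for T in temps:
        if sampling_hours is None:
            t_end = min(MAX_STORAGE_H, time_to_level(gp.ymax - 0.05, T, gp))
            times = np.linspace(0.0, t_end, n_per_temp)
        else:
            times = np.asarray(sampling_hours, dtype=float)
        tvc = np.atleast_1d(baranyi_tvc(times, T, gp))
        for k, (t, y) in enumerate(zip(times, tvc)):
            mean_feats = (
                sp.baseline_mean + sp.slope_mean * y + sp.quad_mean * y**2
                + rng.normal(0.0, sp.noise_sd_mean, N_BANDS)
            )
            sd_feats = (
                sp.baseline_sd + sp.slope_sd * y + sp.quad_sd * y**2
                + rng.normal(0.0, sp.noise_sd_sd, N_BANDS)
            )
            row = {
                "sample_id": f"T{T:g}_{k:02d}",
                "temperature_C": T,
                "storage_time_h": float(t),
                "tvc": float(y),
            }
            row.update(dict(zip(feature_columns("mean"), mean_feats)))
            row.update(dict(zip(feature_columns("sd"), sd_feats)))
            rows.append(row)
    columns = (
        ["sample_id", "temperature_C", "storage_time_h"]
        + feature_columns("mean") + feature_columns("sd") + ["tvc"]
    )
    frame = pd.DataFrame(rows)[columns]
    return SpectralDataset(frame)


# ---------------------------------------------------------------------------
# Ground-truth TSK system generator
# ---------------------------------------------------------------------------

def tsk_forward(X: np.ndarray, rules) -> np.ndarray:
    """Reference forward pass of a Gaussian TSK system (straight loops).

    ``rules`` is a list of ``(center, spread, weights)`` with ``center`` and
    ``spread`` of length q and ``weights`` of length q+1 (affine consequent,
    bias last).  ``spread`` is the total spread b of the Gaussian
    ``exp(-(x - c)^2 / (2 b^2))``; rule strengths are products over inputs,
    normalized to sum to one.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    q = X.shape[1]
    out = np.empty(len(X))
    for k, x in enumerate(X):
        strengths = []
        consequents = []
        for center, spread, weights in rules:
            center = np.asarray(center, float)
            spread = np.asarray(spread, float)
            weights = np.asarray(weights, float)
            if center.shape != (q,) or spread.shape != (q,) or weights.shape != (q + 1,):
                raise ValueError("rule dimensions inconsistent with input dimension")
            memb = np.exp(-((x - center) ** 2) / (2.0 * spread**2))
            strengths.append(float(np.prod(memb)))
            consequents.append(float(weights[:q] @ x + weights[q]))
        total = sum(strengths)
        if total == 0.0:
            norm = [1.0 / len(rules)] * len(rules)
        else:
            norm = [s / total for s in strengths]
        out[k] = sum(r * f for r, f in zip(norm, consequents))
    return out


def generate_tsk_dataset(n: int, rules, noise_sd: float = 0.0, seed: int = 0):
    """Draw ``n`` samples from a known TSK system plus Gaussian noise.

    Inputs are uniform over the box spanned by the rule centers +/- 2 spreads.
    Returns ``(X, y)``; reproducible under ``seed``.
    """
    if not rules:
        raise ValueError("at least one rule is required")
    centers = np.array([np.asarray(r[0], float) for r in rules])
    spreads = np.array([np.asarray(r[1], float) for r in rules])
    if centers.shape != spreads.shape:
        raise ValueError("rule centers and spreads have inconsistent shapes")
    rng = np.random.default_rng(seed)
    lo = (centers - 2.0 * spreads).min(axis=0)
    hi = (centers + 2.0 * spreads).max(axis=0)
    X = rng.uniform(lo, hi, size=(n, centers.shape[1]))
    y = tsk_forward(X, rules)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    return X, y
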