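"""Food-microbiology and chemometric validation metrics plus protocols.

The suite covers the indices conventionally reported for microbial-growth
prediction models: the multiplicative bias factor Bf = 10^(mean log10(yhat/y))
and accuracy factor Af = 10^(mean |log10(yhat/y)|) (both 1 at perfect
agreement), the standardized mean difference theta and Cohen's d effect size,
and the chemometric ratios RPD (sd/RMSE), RER (range/RMSE) and RPIQ
(interquartile range/RMSE), alongside RMSE, MAE, MAPE%, APE and SEP%.

Validation protocols: leave-one-out cross-validation and a temperature-
stratified hold-out split.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np

from .dataset import SpectralDataset

INF_SENTINEL = float("inf")


@dataclass
class MetricsReport:
    """All validation indices for one prediction vector.

    ``r_squared`` is the squared Pearson correlation between observed and
    predicted (set ``r2_definition='explained'`` in :func:`compute_metrics`
    for 1 - SSE/SST).  ``bf``/``af`` are NaN when any observation is
    non-positive (log-ratio undefined); ``rpd``/``rer``/``rpiq`` are +inf when
    RMSE is zero, with ``zero_rmse`` flagged.
    """

    n: int
    rmse: float
    mae: float
    mape_pct: float
    ape: float
    sep_pct: float
    rpd: float
    rer: float
    rpiq: float
    bf: float
    af: float
    theta: float
    cohens_d: float
    r_squared: float
    zero_rmse: bool = False
    log_ratio_defined: bool = True
    quartile_method: str = "linear"   # type-7 linear interpolation
    r2_definition: str = "squared_correlation"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compute_metrics(
    y, y_pred, r2_definition: str = "squared_correlation"
) -> MetricsReport:
    """Compute the full metrics report for observed ``y`` and predicted ``y_pred``."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.ndim != 1:
        raise ValueError("y and y_pred must be 1-d arrays of equal length")
    n = len(y)
    if n < 2:
        raise ValueError("at least two observations are required")

    err = y - y_pred
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))

    log_ok = bool(np.all(y > 0) and np.all(y_pred > 0))
    if log_ok:
        log_ratio = np.log10(y_pred / y)
        bf = float(10.0 ** np.mean(log_ratio))
        af = float(10.0 ** np.mean(np.abs(log_ratio)))
    else:
        bf = af = float("nan")

    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(err) / y
    mape_pct = float(100.0 * np.mean(rel))
    ape = float(100.0 * np.sum(rel))
    ybar = float(np.mean(y))
    sep_pct = float(100.0 * rmse / ybar)

    sd_y = float(np.std(y, ddof=1))
    sd_pred = float(np.std(y_pred, ddof=1))
    q1, q3 = np.percentile(y, [25, 75])  # type-7 linear interpolation
    iqr = float(q3 - q1)
    rng = float(np.max(y) - np.min(y))
    zero_rmse = rmse == 0.0
    rpd = sd_y / rmse if not zero_rmse else INF_SENTINEL
    rer = rng / rmse if not zero_rmse else INF_SENTINEL
    rpiq = iqr / rmse if not zero_rmse else INF_SENTINEL

    mean_diff = ybar - float(np.mean(y_pred))
    theta = mean_diff / sd_y if sd_y > 0 else float("nan")
    pooled = math.sqrt(((n - 1) * sd_y**2 + (n - 1) * sd_pred**2) / (2 * n - 2))
    cohens_d = mean_diff / pooled if pooled > 0 else float("nan")

    if r2_definition == "squared_correlation":
        sy, sp_ = np.std(y), np.std(y_pred)
        if sy == 0 or sp_ == 0:
            r_squared = float("nan")
        else:
            r_squared = float(np.corrcoef(y, y_pred)[0, 1] ** 2)
    elif r2_definition == "explained":
        sst = float(np.sum((y - ybar) ** 2))
        r_squared = 1.0 - float(np.sum(err**2)) / sst if sst > 0 else float("nan")
    else:
        raise ValueError("r2_definition must be 'squared_correlation' or 'explained'")

    return MetricsReport(
        n=n, rmse=rmse, mae=mae, mape_pct=mape_pct, ape=ape, sep_pct=sep_pct,
        rpd=rpd, rer=rer, rpiq=rpiq, bf=bf, af=af, theta=theta,
        cohens_d=cohens_d, r_squared=r_squared, zero_rmse=zero_rmse,
        log_ratio_defined=log_ok, r2_definition=r2_definition,
    )


def loocv(X, y, model_factory, seed: int = 0):
    """Leave-one-out cross-validation.

    ``model_factory()`` must return a fresh unfitted estimator with
    ``fit(X, y)`` and ``predict(X)``.  Returns ``(predictions, report,
    failures)`` where ``predictions`` are the n out-of-fold predictions and
    ``failures`` lists indices of folds whose training raised (their
    prediction is NaN and they are excluded from the report).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least three samples")
    preds = np.full(n, np.nan)
    failures: list[int] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = model_factory()
        try:
            model.fit(X[mask], y[mask])
            preds[i] = float(np.asarray(model.predict(X[i:i + 1])).ravel()[0])
        except Exception:
            failures.append(i)
    ok = ~np.isnan(preds)
    report = compute_metrics(y[ok], preds[ok]) if ok.sum() >= 2 else None
    return preds, report, failures


def holdout_split(ds: SpectralDataset, test_frac: float = 0.1, seed: int = 0):
    """Temperature-stratified train/test split.

    The test size is ``round(n * test_frac)`` (at least 1); test samples are
    allocated across temperature groups proportionally (largest-remainder
    rounding) and drawn with the seeded generator, so the split is
    reproducible.  Returns ``(train, test)`` datasets.
    """
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must be in (0, 1)")
    n = ds.n_samples
    n_test = max(1, int(round(n * test_frac)))
    if n_test >= n:
        raise ValueError("test fraction leaves no training samples")
    rng = np.random.default_rng(seed)

    temps = ds.frame["temperature_C"].to_numpy()
    groups = [np.flatnonzero(temps == t) for t in np.unique(temps)]
    quotas = np.array([len(g) * n_test / n for g in groups])
    counts = np.floor(quotas).astype(int)
    remainder = n_test - counts.sum()
    order = np.argsort(-(quotas - counts))
    for j in order[:remainder]:
        counts[j] += 1
    test_idx: list[int] = []
    for g, c in zip(groups, counts):
        c = min(c, len(g))
        test_idx.extend(rng.choice(g, size=c, replace=False))
    test_idx = np.sort(np.array(test_idx, dtype=int))
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    if mask.sum() == 0:
        raise ValueError("empty test set")
    return ds.select(~mask), ds.select(mask)
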