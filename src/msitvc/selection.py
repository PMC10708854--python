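"""Wavelength selection: pluggable rankers, majority-vote fusion, PCA baseline.

Seven established feature-selection families are wrapped as rankers that each
emit a one-method :class:`~msitvc.dataset.RankingTable` (distinct ranks 1..m
over the bands the method retains): a Boruta-style shadow-feature random
forest, recursive feature elimination, a genetic search, forward stepwise-AIC
regression, LASSO, LMG relative importance, and a PLSR-coefficient filter.
Their rankings are fused by majority voting: a band is selected iff at least
``threshold`` methods retained it, ordered by (votes desc, mean rank asc,
band index asc).  The fusion core and the PLSR filter are the bespoke pieces;
the rankers lean on scikit-learn / statsmodels fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import RFE
from sklearn.linear_model import LassoCV, LinearRegression
from sklearn.model_selection import KFold, cross_val_score

from .dataset import RankingTable, SpectralDataset

# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

@dataclass
class FusionResult:
    """Majority-voting fusion of per-method rankings."""

    selected: list[int]
    votes: dict[int, int]
    mean_rank: dict[int, float]
    threshold: int

    def to_dict(self) -> dict:
        return asdict(self)


def fuse_rankings(rt: RankingTable, threshold="majority") -> FusionResult:
    """Fuse per-method rankings by vote counting.

    ``threshold="majority"`` resolves to the strict majority floor(K/2)+1 of
    the K methods.  A band is selected iff it appears in at least
    ``threshold`` methods' retained sets; the selection is ordered by
    (votes desc, mean rank asc, band index asc).
    """
    K = rt.n_methods
    if K < 1:
        raise ValueError("ranking table must contain at least one method")
    if threshold == "majority":
        threshold = K // 2 + 1
    threshold = int(threshold)
    if not 1 <= threshold <= K:
        raise ValueError(f"threshold must be in 1..{K}, got {threshold}")

    votes: dict[int, int] = {}
    rank_sums: dict[int, int] = {}
    for br in rt.ranks.values():
        for band, rank in br.items():
            votes[band] = votes.get(band, 0) + 1
            rank_sums[band] = rank_sums.get(band, 0) + rank
    mean_rank = {b: rank_sums[b] / votes[b] for b in votes}
    selected = sorted(
        (b for b, v in votes.items() if v >= threshold),
        key=lambda b: (-votes[b], mean_rank[b], b),
    )
    return FusionResult(selected=selected, votes=dict(sorted(votes.items())),
                        mean_rank={b: mean_rank[b] for b in sorted(mean_rank)},
                        threshold=threshold)


# ---------------------------------------------------------------------------
# Rankers (each returns {band_index: rank})
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _scores_to_ranks(scores: dict[int, float]) -> dict[int, int]:
    """Higher score -> better (lower) rank; ties broken by band index."""
    order = sorted(scores, key=lambda b: (-scores[b], b))
    return {b: r for r, b in enumerate(order, start=1)}


def _rank_boruta(X, y, seed, n_iter: int = 20, alpha: float = 0.05, **_):
    """Shadow-feature random-forest relevance screening (Boruta-style).

    Each iteration appends a shuffled copy of every column, fits a random
    forest, and scores a 'hit' for features more important than the best
    shadow; features with significantly more hits than a fair coin
    (one-sided binomial test at ``alpha``) are confirmed and ranked by mean
    importance.
    """
    rng = np.random.default_rng(seed)
    n, q = X.shape
    hits = np.zeros(q, dtype=int)
    imp_sum = np.zeros(q)
    for it in range(n_iter):
        shadow = X.copy()
        for j in range(q):
            shadow[:, j] = rng.permutation(shadow[:, j])
        Xa = np.hstack([X, shadow])
        rf = RandomForestRegressor(n_estimators=100,
                                   random_state=int(rng.integers(2**31)))
        rf.fit(Xa, y)
        imp = rf.feature_importances_
        thresh = imp[q:].max()
        hits += imp[:q] > thresh
        imp_sum += imp[:q]
    # one-sided binomial: confirmed if P(hits >= observed | p=0.5) < alpha
    pvals = stats.binom.sf(hits - 1, n_iter, 0.5)
    confirmed = np.flatnonzero(pvals < alpha)
    scores = {int(j) + 1: float(imp_sum[j]) for j in confirmed}
    return _scores_to_ranks(scores)


def _rank_rfe(X, y, seed, top_k: int = 8, **_):
    """Recursive feature elimination with a random-forest base model."""
    rf = RandomForestRegressor(n_estimators=100, random_state=seed)
    rfe = RFE(rf, n_features_to_select=1, step=1).fit(X, y)
    full = rfe.ranking_                     # 1 = eliminated last = best
    keep = min(top_k, X.shape[1])
    return {int(j) + 1: int(full[j]) for j in range(X.shape[1]) if full[j] <= keep}


def _rank_ga(X, y, seed, pop_size: int = 24, n_generations: int = 15,
             p_crossover: float = 0.8, p_mutation: float = 0.1, cv: int = 3, **_):
    """Genetic search over band subsets.

    Chromosomes are binary masks; fitness is negative cross-validated RMSE of
    a linear model on the masked bands.  Crossover/mutation probabilities
    default to 0.8/0.1.  The best mask's bands are ranked by their selection
    frequency in the final population (then by |correlation| with the target).
    """
    rng = np.random.default_rng(seed)
    n, q = X.shape

    def fitness(mask: np.ndarray) -> float:
        if mask.sum() == 0:
            return -np.inf
        folds = KFold(cv, shuffle=True, random_state=seed)
        scores = cross_val_score(LinearRegression(), X[:, mask], y,
                                 scoring="neg_root_mean_squared_error", cv=folds)
        return float(scores.mean())

    pop = rng.random((pop_size, q)) < 0.5
    pop[pop.sum(axis=1) == 0, 0] = True
    fits = np.array([fitness(m) for m in pop])
    for _ in range(n_generations):
        new = []
        elite = pop[np.argmax(fits)].copy()
        new.append(elite)
        while len(new) < pop_size:
            # tournament selection of two parents
            cand = rng.integers(0, pop_size, size=(2, 2))
            pa = pop[cand[0][np.argmax(fits[cand[0]])]].copy()
            pb = pop[cand[1][np.argmax(fits[cand[1]])]].copy()
            if rng.random() < p_crossover:
                cut = int(rng.integers(1, q))
                pa = np.concatenate([pa[:cut], pb[cut:]])
            flips = rng.random(q) < p_mutation
            pa = pa ^ flips
            if pa.sum() == 0:
                pa[rng.integers(q)] = True
            new.append(pa)
        pop = np.array(new)
        fits = np.array([fitness(m) for m in pop])
    best = pop[np.argmax(fits)]
    freq = pop.mean(axis=0)
    corr = np.array([abs(np.corrcoef(X[:, j], y)[0, 1]) if X[:, j].std() > 0 else 0.0
                     for j in range(q)])
    scores = {int(j) + 1: (float(freq[j]), float(corr[j]))
              for j in np.flatnonzero(best)}
    order = sorted(scores, key=lambda b: (-scores[b][0], -scores[b][1], b))
    return {b: r for r, b in enumerate(order, start=1)}


def _rank_stepwise(X, y, seed=None, max_features: int | None = None, **_):
    """Forward stepwise selection by AIC with backward elimination checks."""
    import statsmodels.api as sm

    n, q = X.shape
    limit = max_features or q
    selected: list[int] = []
    remaining = list(range(q))

    def aic(cols: list[int]) -> float:
        design = sm.add_constant(X[:, cols]) if cols else np.ones((n, 1))
        return float(sm.OLS(y, design).fit().aic)

    current = aic([])
    while remaining and len(selected) < limit:
        trials = [(aic(selected + [j]), j) for j in remaining]
        best_aic, best_j = min(trials)
        if best_aic >= current:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        current = best_aic
        # backward pass: drop any earlier entrant that no longer helps
        improved = True
        while improved and len(selected) > 1:
            improved = False
            for j in selected[:-1]:
                reduced = [s for s in selected if s != j]
                a = aic(reduced)
                if a < current:
                    selected = reduced
                    remaining.append(j)
                    current = a
                    improved = True
                    break
    return {int(j) + 1: r for r, j in enumerate(selected, start=1)}


def _rank_lasso(X, y, seed, cv: int = 5, **_):
    """LASSO with CV-min lambda; nonzero coefficients ranked by magnitude.

    Full shrinkage (no surviving coefficient) yields an empty ranking rather
    than an error.
    """
    Xs = _standardize(X)
    folds = KFold(cv, shuffle=True, random_state=seed)
    model = LassoCV(cv=folds, random_state=seed, max_iter=50000).fit(Xs, y)
    coefs = model.coef_
    scores = {int(j) + 1: float(abs(coefs[j])) for j in np.flatnonzero(coefs != 0)}
    return _scores_to_ranks(scores)


def _rank_relimp(X, y, seed, n_perm: int = 120, **_):
    """LMG relative importance by seeded permutation averaging.

    Averages each band's incremental R^2 contribution over random orderings;
    bands contributing more than the uniform share of the full-model R^2 are
    retained, ranked by average contribution.
    """
    rng = np.random.default_rng(seed)
    n, q = X.shape
    Xs = _standardize(X)
    yc = y - y.mean()
    sst = float(yc @ yc)

    def r2(cols) -> float:
        if not cols:
            return 0.0
        A = Xs[:, list(cols)]
        resid = yc - A @ np.linalg.lstsq(A, yc, rcond=None)[0]
        return 1.0 - float(resid @ resid) / sst

    contrib = np.zeros(q)
    for _ in range(n_perm):
        order = rng.permutation(q)
        prev = 0.0
        cols: list[int] = []
        for j in order:
            cols.append(int(j))
            cur = r2(cols)
            contrib[j] += cur - prev
            prev = cur
    contrib /= n_perm
    total = contrib.sum()
    cutoff = total / q if total > 0 else 0.0
    scores = {int(j) + 1: float(contrib[j])
              for j in range(q) if contrib[j] > cutoff}
    return _scores_to_ranks(scores)


def _rank_plsr_filter(X, y, seed=None, n_components: int = 4, **_):
    """PLSR-coefficient filter: bands with above-average |coefficient|.

    Fits partial least squares on the standardized bands and retains the
    bands whose absolute regression coefficient exceeds the mean absolute
    coefficient, ranked by magnitude.
    """
    import warnings as _warnings

    Xs = _standardize(X)
    ncomp = min(n_components, Xs.shape[1], Xs.shape[0] - 1)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)  # rank-deficient blocks
        pls = PLSRegression(n_components=ncomp, scale=False).fit(Xs, y)
    coefs = np.abs(np.ravel(pls.coef_))
    cutoff = coefs.mean()
    scores = {int(j) + 1: float(coefs[j])
              for j in np.flatnonzero(coefs > cutoff)}
    return _scores_to_ranks(scores)


RANKERS = {
    "boruta": _rank_boruta,
    "rfe": _rank_rfe,
    "ga": _rank_ga,
    "stepwise": _rank_stepwise,
    "lasso": _rank_lasso,
    "relimp": _rank_relimp,
    "plsr": _rank_plsr_filter,
}


def rank_features(ds: SpectralDataset, method: str, statistic: str = "mean",
                  seed: int = 0, **params) -> RankingTable:
    """Run one registered ranker on a feature block of a dataset."""
    if method not in RANKERS:
        raise ValueError(f"unknown ranker {method!r}; available: {sorted(RANKERS)}")
    if not ds.has_target:
        raise ValueError("dataset has no tvc targets")
    X = ds.features(statistic)
    y = ds.tvc
    ranks = RANKERS[method](X, y, seed=seed, **params)
    return RankingTable(ranks={method: ranks}, statistic=statistic)


def rank_all(ds: SpectralDataset, methods=None, statistic: str = "mean",
             seed: int = 0) -> RankingTable:
    """Run several rankers and merge them into one multi-method table."""
    methods = list(methods or RANKERS)
    merged: dict[str, dict[int, int]] = {}
    for method in methods:
        merged[method] = rank_features(ds, method, statistic=statistic,
                                       seed=seed).ranks[method]
    return RankingTable(ranks=merged, statistic=statistic)


# ---------------------------------------------------------------------------
# PCA baseline
# ---------------------------------------------------------------------------

@dataclass
class PCBaseline:
    loadings: np.ndarray           # (q, k)
    eigenvalues: np.ndarray        # (k,)
    cum_prop: np.ndarray           # (k,)


def pca_baseline(X, k: int):
    """Principal-component baseline on one feature block.

    Returns ``(PCBaseline, scores)`` where ``scores`` is the (n, k) projection.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"k must be in 1..{X.shape[1]}")
    pca = PCA(n_components=k).fit(X)
    scores = pca.transform(X)
    baseline = PCBaseline(
        loadings=pca.components_.T,
        eigenvalues=pca.explained_variance_,
        cum_prop=np.cumsum(pca.explained_variance_ratio_),
    )
    return baseline, scores
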