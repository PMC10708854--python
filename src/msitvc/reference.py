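"""Published per-method waveband rankings for the 84-sample beef-fillet study.

Seven feature-selection methods (Boruta, recursive feature elimination,
stepwise-AIC, LASSO, a genetic search, LMG relative importance and a
PLSR-coefficient filter) were each run on the mean-reflectance and
pixel-intensity-sd feature blocks of that study; the tables below freeze the
reported ranks (rank 1 = most important band for that method).  They serve as
worked-example inputs for the majority-voting fusion: with the default strict
majority of 4-of-7 methods the fusion selects bands {1,2,5,7,8,9,11,12} for
the mean block and {4,5,6,7,8,12} for the sd block.
"""

from __future__ import annotations

from .dataset import RankingTable

#: Mean-reflectance block: method -> {band index: rank}.
MEAN_RANKS: dict[str, dict[int, int]] = {
    "boruta": {1: 6, 2: 7, 5: 8, 8: 5, 9: 3, 10: 4, 11: 2, 12: 1},
    "rfe": {1: 6, 2: 9, 7: 7, 8: 5, 9: 3, 10: 4, 11: 2, 12: 1, 15: 8},
    "stepwise": {1: 4, 2: 3, 5: 6, 7: 2, 9: 5, 12: 1},
    "lasso": {1: 7, 2: 1, 5: 2, 7: 4, 9: 3, 11: 6, 12: 5},
    "ga": {1: 1, 5: 7, 7: 5, 8: 6, 9: 2, 11: 4, 12: 3},
    "relimp": {2: 9, 3: 8, 5: 7, 6: 6, 8: 5, 9: 4, 10: 3, 11: 1, 12: 2},
    "plsr": {1: 3, 4: 5, 5: 1, 6: 4, 7: 2, 8: 6, 13: 8, 15: 7},
}

#: Pixel-intensity-sd block: method -> {band index: rank}.
SD_RANKS: dict[str, dict[int, int]] = {
    "boruta": {2: 7, 4: 3, 5: 5, 6: 4, 8: 1, 11: 6, 12: 2},
    "rfe": {1: 5, 4: 3, 5: 6, 7: 4, 8: 1, 11: 7, 12: 2},
    "stepwise": {2: 6, 4: 4, 5: 3, 6: 2, 7: 5, 8: 1, 11: 7},
    "lasso": {3: 5, 4: 3, 5: 2, 6: 1, 7: 6, 8: 4},
    "ga": {4: 1, 6: 2, 7: 3, 8: 4, 12: 5, 15: 6, 16: 7, 17: 8},
    "relimp": {3: 7, 4: 4, 5: 6, 6: 3, 7: 5, 8: 1, 12: 2, 13: 8},
    "plsr": {4: 1, 5: 3, 7: 7, 8: 2, 10: 5, 12: 8, 15: 4, 18: 6},
}


def mean_ranking_table() -> RankingTable:
    """The published mean-block ranking table."""
    return RankingTable(ranks={m: dict(b) for m, b in MEAN_RANKS.items()}, statistic="mean")


def sd_ranking_table() -> RankingTable:
    """The published sd-block ranking table."""
    return RankingTable(ranks={m: dict(b) for m, b in SD_RANKS.items()}, statistic="sd")
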