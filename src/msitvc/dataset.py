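"""Delimited-text I/O and containers for multispectral TVC datasets.

A dataset row is one meat specimen: identifying metadata (sample id, storage
temperature, storage time), the 18 mean-reflectance and 18 pixel-intensity-sd
features, and the microbiological target TVC in log10 cfu cm^-2 (optional for
prediction-only samples).  Ranking tables hold per-feature-selection-method
waveband ranks, the input of the majority-voting fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .wavebands import N_BANDS, STATISTICS, feature_columns

META_COLUMNS = ["sample_id", "temperature_C", "storage_time_h"]
TARGET_COLUMN = "tvc"


class DatasetFormatError(ValueError):
    """A dataset or ranking file violates the expected layout."""


@dataclass
class SpectralDataset:
    """Tabular multispectral dataset with optional TVC targets.

    Thin wrapper over a :class:`pandas.DataFrame` whose columns are
    ``sample_id, temperature_C, storage_time_h, Mean.01..Mean.18,
    StdDev.01..StdDev.18[, tvc]``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def has_target(self) -> bool:
        return TARGET_COLUMN in self.frame.columns and self.frame[TARGET_COLUMN].notna().all()

    def features(self, statistic: str) -> np.ndarray:
        """(n, 18) feature matrix of one FOS block, in band order."""
        return self.frame[feature_columns(statistic)].to_numpy(dtype=float)

    @property
    def tvc(self) -> np.ndarray:
        if TARGET_COLUMN not in self.frame.columns:
            raise DatasetFormatError("dataset has no tvc column")
        return self.frame[TARGET_COLUMN].to_numpy(dtype=float)

    @property
    def temperatures(self) -> np.ndarray:
        return self.frame["temperature_C"].to_numpy(dtype=float)

    def validate(self) -> None:
        cols = list(self.frame.columns)
        required = META_COLUMNS + feature_columns("mean") + feature_columns("sd")
        for col in required:
            if col not in cols:
                raise DatasetFormatError(f"missing required column {col!r}")
            if cols.count(col) > 1:
                raise DatasetFormatError(f"duplicated column {col!r}")
        ids = self.frame["sample_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise DatasetFormatError(f"duplicate sample_id {dup!r}")
        feats = self.frame[feature_columns("mean") + feature_columns("sd")]
        if feats.isna().any().any():
            raise DatasetFormatError("missing entries in feature columns")
        if TARGET_COLUMN in cols:
            t = self.frame[TARGET_COLUMN]
            if np.isinf(t.to_numpy(dtype=float)).any():
                raise DatasetFormatError("tvc values must be finite")

    def select(self, mask: np.ndarray) -> "SpectralDataset":
        return SpectralDataset(self.frame.iloc[np.asarray(mask)].reset_index(drop=True))

    def __eq__(self, other: object) -> bool:  # float-tolerant row equality
        if not isinstance(other, SpectralDataset):
            return NotImplemented
        if list(self.frame.columns) != list(other.frame.columns):
            return False
        try:
            pd.testing.assert_frame_equal(
                self.frame, other.frame, check_exact=False, rtol=0, atol=1e-9,
                check_dtype=False,
            )
        except AssertionError:
            return False
        return True


def read_dataset(path: str | Path, dialect: str = ",") -> SpectralDataset:
    """Read a dataset CSV/TSV.

    Raises
    ------
    DatasetFormatError
        On a missing/duplicated required column or wrong block width.
    ValueError
        On a non-numeric cell, with the offending row index in the message.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=dialect, dtype={"sample_id": str})
    required = META_COLUMNS + feature_columns("mean") + feature_columns("sd")
    for col in required:
        if col not in frame.columns:
            raise DatasetFormatError(f"{path.name}: missing required column {col!r}")
    numeric = [c for c in frame.columns if c != "sample_id"]
    for col in numeric:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(frame[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna() & frame[col].notna())[0])
            raise ValueError(
                f"{path.name}: non-numeric value in column {col!r} at data row {row}"
            ) from exc
    if TARGET_COLUMN in frame.columns and frame[TARGET_COLUMN].isna().all() and len(frame) == 0:
        pass
    return SpectralDataset(frame)


def write_dataset(ds: SpectralDataset, path: str | Path, dialect: str = ",") -> Path:
    """Write a dataset; missing tvc is an empty cell, never a sentinel."""
    path = Path(path)
    ds.frame.to_csv(path, sep=dialect, index=False, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# Ranking tables
# ---------------------------------------------------------------------------

@dataclass
class RankingTable:
    """Per-method waveband importance ranks (the fusion input).

    ``ranks[method]`` maps band index (1-based) -> rank, rank 1 being the most
    important band for that method.  Within a method the ranks are the
    distinct integers 1..m with no gaps; a band absent from the map was not
    retained by the method.
    """

    ranks: dict[str, dict[int, int]]
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise DatasetFormatError(f"statistic must be one of {STATISTICS}")
        for method, br in self.ranks.items():
            for band in br:
                if not 1 <= band <= N_BANDS:
                    raise DatasetFormatError(
                        f"method {method!r}: band index {band} outside 1..{N_BANDS}"
                    )
            values = sorted(br.values())
            if values and values != list(range(1, len(values) + 1)):
                raise DatasetFormatError(
                    f"method {method!r}: ranks must be 1..m without gaps or "
                    f"duplicates, got {values}"
                )

    @property
    def method_names(self) -> list[str]:
        return list(self.ranks)

    @property
    def n_methods(self) -> int:
        return len(self.ranks)


def read_ranking_table(path: str | Path, statistic: str = "mean") -> RankingTable:
    """Read a long-format ranking CSV with columns ``method,band_index,rank``."""
    frame = pd.read_csv(path)
    for col in ("method", "band_index", "rank"):
        if col not in frame.columns:
            raise DatasetFormatError(f"ranking table missing column {col!r}")
    ranks: dict[str, dict[int, int]] = {}
    for _, row in frame.iterrows():
        method = str(row["method"])
        band = int(row["band_index"])
        rank = int(row["rank"])
        per = ranks.setdefault(method, {})
        if band in per:
            raise DatasetFormatError(f"method {method!r}: duplicate entry for band {band}")
        per[band] = rank
    return RankingTable(ranks=ranks, statistic=statistic)


def write_ranking_table(rt: RankingTable, path: str | Path) -> Path:
    rows = [
        {"method": m, "band_index": b, "rank": r}
        for m, br in rt.ranks.items()
        for b, r in sorted(br.items(), key=lambda kv: kv[1])
    ]
    pd.DataFrame(rows, columns=["method", "band_index", "rank"]).to_csv(path, index=False)
    return Path(path)
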