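"""Waveband coding of the 18-channel multispectral instrument.

The imaging system acquires reflectance at 18 discrete wavelengths between
405 and 970 nm; bands are conventionally coded 1..18 in wavelength order and
each sample carries two first-order-statistics (FOS) features per band: the
mean reflectance of the region of interest and the standard deviation of the
pixel intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Instrument wavelengths in nm, indexed by band code 1..18.
WAVELENGTHS_NM: tuple[int, ...] = (
    405, 435, 450, 470, 505, 525, 570, 590, 630,
    645, 660, 700, 850, 870, 890, 910, 940, 970,
)

N_BANDS = len(WAVELENGTHS_NM)

#: The two first-order-statistics feature blocks.
STATISTICS = ("mean", "sd")


@dataclass(frozen=True)
class Waveband:
    """One spectral channel of the instrument.

    Parameters
    ----------
    index : int
        Band code in 1..18 (wavelength order).
    statistic : str
        Which FOS block the feature belongs to, ``"mean"`` or ``"sd"``.
    """

    index: int
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if not 1 <= self.index <= N_BANDS:
            raise ValueError(f"band index must be in 1..{N_BANDS}, got {self.index}")
        if self.statistic not in STATISTICS:
            raise ValueError(f"statistic must be one of {STATISTICS}")

    @property
    def wavelength_nm(self) -> int:
        return WAVELENGTHS_NM[self.index - 1]

    @property
    def column(self) -> str:
        """Column label, e.g. ``Mean.07`` / ``StdDev.07``."""
        prefix = "Mean" if self.statistic == "mean" else "StdDev"
        return f"{prefix}.{self.index:02d}"


def feature_columns(statistic: str) -> list[str]:
    """Ordered column labels for one FOS block (``Mean.01``..``Mean.18`` etc.)."""
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    prefix = "Mean" if statistic == "mean" else "StdDev"
    return [f"{prefix}.{i:02d}" for i in range(1, N_BANDS + 1)]
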