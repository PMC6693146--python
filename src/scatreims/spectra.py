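"""Core spectral containers.

REIMS acquisitions are time series of centroided scans: burning one faecal
pellet with a diathermy electrode produces a seconds-long burst of ion
current, and every scan recorded during the burst is a list of
(m/z, intensity) centroids. Downstream analysis works on fixed-grid
discretised ("binned") spectra so that samples are comparable as equal-length
feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Mass difference between 13C and 12C, Da.
C13_MASS_SHIFT = 1.00336
#: Natural abundance of 13C (per carbon atom), used in the linear
#: first-isotopologue approximation ratio ~= 0.0107 * n_carbons.
C13_ABUNDANCE = 0.0107

#: [M-H]- of leu-enkephalin, the conventional negative-mode lockmass.
LOCKMASS_LEU_ENKEPHALIN = 554.26
#: Propan-2-ol background ion usable as an alternative lockmass.
LOCKMASS_PROPANOL_BACKGROUND = 325.19


@dataclass
class PeakList:
    """Centroided peaks of one scan or one aggregated burn spectrum."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(self.intensity) and np.any(self.intensity < 0):
            raise ValueError("peak intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def tic(self) -> float:
        """Total ion current (sum of all centroid intensities)."""
        return float(self.intensity.sum())

    def sorted_by_mz(self) -> "PeakList":
        order = np.argsort(self.mz, kind="stable")
        return PeakList(self.mz[order], self.intensity[order])

    @staticmethod
    def empty() -> "PeakList":
        return PeakList(np.empty(0), np.empty(0))


@dataclass
class ScanSeries:
    """Time-ordered centroided scans from one acquisition.

    One acquisition covers one or more pellets burned in sequence; each burn
    appears as a burst of total ion current against a near-zero baseline.
    """

    times: np.ndarray
    scans: list[PeakList]
    polarity: str = "negative"
    mz_range: tuple[float, float] = (50.0, 1200.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.scans):
            raise ValueError("times and scans must have the same length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("scan times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.scans)

    def tic(self) -> np.ndarray:
        """Per-scan total ion current."""
        return np.array([s.tic for s in self.scans])


@dataclass(frozen=True)
class BinGrid:
    """Inclusive fixed m/z grid used to discretise spectra.

    Grid points sit at ``mz_start + k * width`` for k = 0 .. n_points - 1,
    so the 400-1100 m/z window at 0.1 Da width yields a 7001-point vector
    (and 14001 points at 0.05 Da). Centroids are assigned to the nearest
    grid point, with ties going to the lower point.
    """

    mz_start: float = 400.0
    mz_end: float = 1100.0
    width: float = 0.1

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bin width must be positive")
        if self.mz_end <= self.mz_start:
            raise ValueError("mz_end must exceed mz_start")

    @property
    def n_points(self) -> int:
        return int(round((self.mz_end - self.mz_start) / self.width)) + 1

    def centers(self) -> np.ndarray:
        return self.mz_start + np.arange(self.n_points) * self.width

    def labels(self) -> list[str]:
        """Column labels rendered at fixed precision for stable CSV round trips."""
        return [f"{mz:.2f}" for mz in self.centers()]

    def bin_index(self, mz: np.ndarray) -> np.ndarray:
        """Nearest-point bin index; midpoints resolve to the lower index.

        Values outside [mz_start - width/2, mz_end + width/2) map to -1.
        """
        x = (np.asarray(mz, dtype=float) - self.mz_start) / self.width
        idx = np.ceil(x - 0.5).astype(int)
        idx[(idx < 0) | (idx >= self.n_points)] = -1
        return idx


@dataclass
class BinnedSpectrum:
    """Fixed-grid discretised spectrum for one pellet or one individual."""

    grid: BinGrid
    values: np.ndarray
    provenance: list[str] = field(default_factory=list)
    lockmass_used: float | None = None
    normalised: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_points,):
            raise ValueError(
                f"values must have length {self.grid.n_points}, got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("binned intensities must be non-negative")

    @property
    def tic(self) -> float:
        return float(self.values.sum())
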