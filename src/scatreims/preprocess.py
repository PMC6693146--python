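"""Raw scan series -> per-individual discretised feature vectors.

Re-implements the vendor-software preprocessing chain for REIMS burn
spectra: burn-event detection on the total ion chromatogram, per-scan
intensity thresholding and summation into one spectrum per burn,
single-point lockmass recalibration, fixed-grid binning over the
400-1100 m/z analysis window, total-ion normalisation, and averaging of
the pellet spectra belonging to one individual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import (
    BinGrid,
    BinnedSpectrum,
    LOCKMASS_LEU_ENKEPHALIN,
    PeakList,
    ScanSeries,
)

#: Vendor default per-scan intensity threshold, counts.
DEFAULT_INTENSITY_THRESHOLD = 3e5


@dataclass
class BurnEvent:
    """Contiguous run of scans whose TIC rises above the detection baseline."""

    start_index: int
    end_index: int  # inclusive
    tic_peak: float

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("start_index must not exceed end_index")

    @property
    def n_scans(self) -> int:
        return self.end_index - self.start_index + 1


def detect_burn_events(
    series: ScanSeries,
    baseline_fraction: float = 0.1,
    merge_gap: int = 2,
) -> list[BurnEvent]:
    """Segment the TIC trace into burn events.

    A scan belongs to a burn when its TIC exceeds ``baseline_fraction`` of
    the series maximum; contiguous above-threshold scans form one event and
    events separated by fewer than ``merge_gap`` baseline scans are merged
    (hysteresis against single-scan dropouts inside a burn).

    An all-zero TIC trace yields no events; that is a valid empty result,
    not an error.
    """
    if len(series) == 0:
        raise ValueError("scan series is empty")
    if not 0 < baseline_fraction < 1:
        raise ValueError("baseline_fraction must be in (0, 1)")
    tic = series.tic()
    peak = tic.max()
    if peak <= 0:
        return []
    above = tic > baseline_fraction * peak
    events: list[BurnEvent] = []
    idx = np.flatnonzero(above)
    start = prev = int(idx[0])
    for i in idx[1:]:
        if i - prev > merge_gap:
            events.append(_make_event(tic, start, prev))
            start = int(i)
        prev = int(i)
    events.append(_make_event(tic, start, prev))
    return events


def _make_event(tic: np.ndarray, start: int, end: int) -> BurnEvent:
    return BurnEvent(start, end, float(tic[start : end + 1].max()))


def aggregate_burn(
    series: ScanSeries,
    event: BurnEvent,
    threshold: float = DEFAULT_INTENSITY_THRESHOLD,
) -> PeakList:
    """Sum the centroids of a burn's member scans into one spectrum.

    Centroids below ``threshold`` counts are discarded per scan before
    summation; surviving centroids sharing an identical m/z are summed.
    With ``threshold=0`` total intensity is conserved. An empty result is
    allowed (every centroid sub-threshold).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    mzs, ints = [], []
    for scan in series.scans[event.start_index : event.end_index + 1]:
        keep = scan.intensity > threshold
        mzs.append(scan.mz[keep])
        ints.append(scan.intensity[keep])
    mz = np.concatenate(mzs) if mzs else np.empty(0)
    intensity = np.concatenate(ints) if ints else np.empty(0)
    if len(mz) == 0:
        return PeakList.empty()
    uniq, inverse = np.unique(mz, return_inverse=True)
    summed = np.zeros_like(uniq)
    np.add.at(summed, inverse, intensity)
    return PeakList(uniq, summed)


def lockmass_correct(
    peaks: PeakList,
    reference: float = LOCKMASS_LEU_ENKEPHALIN,
    search_window: float = 0.25,
) -> tuple[PeakList, bool]:
    """Single-point multiplicative mass recalibration.

    The most intense centroid within ``reference +/- search_window`` is taken
    as the observed lockmass and every m/z is multiplied by
    ``reference / observed`` so the reference lands exactly on its known
    mass. Multiplicative (gain) correction is used because time-of-flight
    mass error scales with m/z.

    Returns ``(corrected_peaks, corrected_flag)``. When no centroid lies in
    the window the spectrum is passed through unchanged, flagged
    uncorrectable, and a warning is emitted.
    """
    if len(peaks) == 0:
        warnings.warn("lockmass correction skipped: empty spectrum")
        return peaks, False
    in_window = np.abs(peaks.mz - reference) <= search_window
    if not in_window.any():
        warnings.warn(
            f"no lockmass candidate within {search_window} Da of {reference}; "
            "spectrum left uncorrected"
        )
        return peaks, False
    cands = np.flatnonzero(in_window)
    observed = peaks.mz[cands[np.argmax(peaks.intensity[cands])]]
    factor = reference / observed
    return PeakList(peaks.mz * factor, peaks.intensity.copy()), True


def bin_spectrum(
    peaks: PeakList,
    grid: BinGrid,
    provenance: list[str] | None = None,
    lockmass_used: float | None = None,
) -> BinnedSpectrum:
    """Assign each centroid's intensity to the nearest grid point.

    Ties at bin midpoints go to the lower point; centroids outside the
    grid's outer half-bin margins are discarded. An empty peak list yields
    a zero vector of full grid length.
    """
    values = np.zeros(grid.n_points)
    if len(peaks):
        idx = grid.bin_index(peaks.mz)
        keep = idx >= 0
        np.add.at(values, idx[keep], peaks.intensity[keep])
    return BinnedSpectrum(
        grid, values, provenance=list(provenance or []), lockmass_used=lockmass_used
    )


def normalise_spectrum(binned: BinnedSpectrum) -> BinnedSpectrum:
    """Total-ion normalisation: rescale so the vector sums to 1.

    Removes the per-pellet intensity scale (pellet mass, burn efficiency),
    which is why classification is invariant to burning half or a quarter
    of a pellet. An all-zero spectrum cannot be normalised.
    """
    total = binned.values.sum()
    if total <= 0:
        raise ValueError("cannot normalise an all-zero spectrum")
    return BinnedSpectrum(
        binned.grid,
        binned.values / total,
        provenance=list(binned.provenance),
        lockmass_used=binned.lockmass_used,
        normalised=True,
    )


def average_individual(spectra: list[BinnedSpectrum]) -> BinnedSpectrum:
    """Arithmetic per-bin mean of one individual's pellet spectra.

    All spectra must share the same grid; provenance accumulates the
    contributing pellet identifiers.
    """
    if not spectra:
        raise ValueError("need at least one spectrum to average")
    grid = spectra[0].grid
    if any(s.grid != grid for s in spectra):
        raise ValueError("cannot average spectra on different grids")
    values = np.mean([s.values for s in spectra], axis=0)
    provenance = [p for s in spectra for p in s.provenance]
    return BinnedSpectrum(
        grid,
        values,
        provenance=provenance,
        lockmass_used=spectra[0].lockmass_used,
        normalised=all(s.normalised for s in spectra),
    )


def pellet_spectrum(
    series: ScanSeries,
    event: BurnEvent,
    grid: BinGrid,
    threshold: float = DEFAULT_INTENSITY_THRESHOLD,
    lockmass: float | None = LOCKMASS_LEU_ENKEPHALIN,
    lockmass_window: float = 0.25,
    provenance: list[str] | None = None,
) -> BinnedSpectrum:
    """Full chain for one burn: aggregate -> lockmass -> bin -> normalise."""
    peaks = aggregate_burn(series, event, threshold)
    used = None
    if lockmass is not None:
        peaks, ok = lockmass_correct(peaks, lockmass, lockmass_window)
        used = lockmass if ok else None
    binned = bin_spectrum(peaks, grid, provenance=provenance, lockmass_used=used)
    return normalise_spectrum(binned)


def preprocess_dataset(
    series_list: list[ScanSeries],
    grid: BinGrid | None = None,
    threshold: float = DEFAULT_INTENSITY_THRESHOLD,
    lockmass: float | None = LOCKMASS_LEU_ENKEPHALIN,
    lockmass_window: float = 0.25,
    baseline_fraction: float = 0.1,
) -> pd.DataFrame:
    """Reduce acquisitions to one normalised feature vector per individual.

    Each series carries ``meta['sample_id']`` identifying the individual;
    every detected burn in a series is one pellet spectrum, and the pellet
    spectra of one individual are averaged. Returns a DataFrame indexed by
    sample_id with the grid's m/z labels as columns.
    """
    grid = grid or BinGrid()
    by_sample: dict[str, list[BinnedSpectrum]] = {}
    for k, series in enumerate(series_list):
        sample_id = str(series.meta.get("sample_id", f"sample{k}"))
        pellet = str(series.meta.get("pellet_id", f"{sample_id}/run{k}"))
        events = detect_burn_events(series, baseline_fraction)
        for j, event in enumerate(events):
            spec = pellet_spectrum(
                series,
                event,
                grid,
                threshold=threshold,
                lockmass=lockmass,
                lockmass_window=lockmass_window,
                provenance=[f"{pellet}/burn{j}"],
            )
            by_sample.setdefault(sample_id, []).append(spec)
    if not by_sample:
        raise ValueError("no burn events detected in any series")
    rows = {sid: average_individual(specs).values for sid, specs in by_sample.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=grid.labels())
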