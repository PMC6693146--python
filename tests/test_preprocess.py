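"""Vendor-equivalent preprocessing chain: burn detection, thresholded
aggregation, lockmass recalibration, binning, normalisation, averaging."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scatreims import (
    BinGrid,
    PeakList,
    ScanSeries,
    SimulationConfig,
    simulate_dataset,
)
from scatreims.preprocess import (
    aggregate_burn,
    average_individual,
    bin_spectrum,
    detect_burn_events,
    lockmass_correct,
    normalise_spectrum,
    preprocess_dataset,
)
from scatreims.spectra import BinnedSpectrum


def _series(tics, peak_mz=700.0):
    scans = [
        PeakList(np.array([peak_mz]), np.array([t])) if t > 0 else PeakList.empty()
        for t in tics
    ]
    return ScanSeries(times=np.arange(len(tics), dtype=float), scans=scans)


# ---------------------------------------------------------------------------
# burn detection

def test_all_zero_tic_yields_no_events():
    assert detect_burn_events(_series([0.0] * 30)) == []


def test_three_gaussian_bursts_found_at_their_centres():
    """Brute-force oracle: threshold the TIC trace by hand and compare."""
    t = np.arange(60, dtype=float)
    tic = np.zeros(60)
    for centre in (10, 30, 50):
        tic += 1e8 * np.exp(-0.5 * ((t - centre) / 1.2) ** 2)
    series = _series(tic)
    events = detect_burn_events(series, baseline_fraction=0.1)
    assert len(events) == 3
    # oracle: contiguous runs of TIC > 0.1 * max
    above = tic > 0.1 * tic.max()
    runs = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        if not a and start is not None:
            runs.append((start, i - 1))
            start = None
    assert [(e.start_index, e.end_index) for e in events] == runs
    for e, centre in zip(events, (10, 30, 50)):
        tic_e = tic[e.start_index : e.end_index + 1]
        assert e.start_index + int(np.argmax(tic_e)) == centre


def test_events_are_disjoint_and_ordered():
    tic = [0, 0, 5, 9, 5, 0, 0, 0, 0, 7, 10, 6, 0]
    events = detect_burn_events(_series([x * 1e7 for x in tic]))
    assert len(events) == 2
    assert events[0].end_index < events[1].start_index


def test_non_monotone_times_rejected_at_construction():
    with pytest.raises(ValueError, match="strictly increasing"):
        ScanSeries(times=np.array([0.0, 2.0, 1.0]),
                   scans=[PeakList.empty()] * 3)


def test_empty_series_rejected():
    with pytest.raises(ValueError, match="empty"):
        detect_burn_events(ScanSeries(times=np.empty(0), scans=[]))


# ---------------------------------------------------------------------------
# aggregation with intensity threshold

def test_subthreshold_centroids_discarded_before_summation():
    series = ScanSeries(
        times=np.array([0.0]),
        scans=[PeakList(np.array([500.0, 600.0]), np.array([4e5, 1e5]))],
    )
    events = detect_burn_events(series)
    peaks = aggregate_burn(series, events[0], threshold=3e5)
    assert peaks.mz.tolist() == [500.0]
    assert peaks.intensity.tolist() == [4e5]


def test_zero_threshold_conserves_total_intensity():
    series, _ = simulate_dataset(
        SimulationConfig(classes=["A"], seed=3, n_individuals_per_class=1,
                         pellets_per_individual=1)
    )
    (event,) = detect_burn_events(series[0])
    member = series[0].scans[event.start_index : event.end_index + 1]
    total = sum(s.tic for s in member)
    peaks = aggregate_burn(series[0], event, threshold=0.0)
    assert peaks.tic == pytest.approx(total, rel=1e-12)


def test_identical_mz_summed_across_scans():
    series = ScanSeries(
        times=np.array([0.0, 1.0]),
        scans=[PeakList(np.array([500.0]), np.array([4e5]))] * 2,
    )
    (event,) = detect_burn_events(series)
    peaks = aggregate_burn(series, event, threshold=0.0)
    assert peaks.mz.tolist() == [500.0]
    assert peaks.intensity.tolist() == [8e5]


# ---------------------------------------------------------------------------
# lockmass correction

def test_reference_already_on_target_is_identity():
    peaks = PeakList(np.array([500.0, 554.26]), np.array([1e6, 5e6]))
    out, ok = lockmass_correct(peaks, 554.26)
    assert ok
    assert np.allclose(out.mz, peaks.mz, atol=1e-12)


def test_gain_drift_corrected_back_to_truth():
    """TOF gain error: every m/z scaled so the lockmass reads 554.28."""
    factor = 554.28 / 554.26
    peaks = PeakList(np.array([500.0, 554.26]) * factor, np.array([1e6, 5e6]))
    out, ok = lockmass_correct(peaks, 554.26)
    assert ok
    ref = out.mz[np.argmax(out.intensity)]
    assert ref == pytest.approx(554.26, abs=1e-9)
    assert out.mz[0] == pytest.approx(500.0, abs=1e-3)


def test_no_candidate_in_window_flags_uncorrectable():
    peaks = PeakList(np.array([500.0, 700.0]), np.array([1e6, 1e6]))
    with pytest.warns(UserWarning, match="uncorrected"):
        out, ok = lockmass_correct(peaks, 554.26, search_window=0.25)
    assert not ok
    assert np.array_equal(out.mz, peaks.mz)


@given(drift=st.floats(-0.05, 0.05))
def test_lockmass_idempotent(drift):
    factor = (554.26 + drift) / 554.26
    peaks = PeakList(np.array([450.0, 554.26, 900.0]) * factor,
                     np.array([1e6, 5e6, 2e6]))
    once, _ = lockmass_correct(peaks, 554.26)
    twice, _ = lockmass_correct(once, 554.26)
    assert np.allclose(twice.mz, once.mz, rtol=1e-9)


# ---------------------------------------------------------------------------
# binning

@pytest.mark.parametrize(
    "width,n_expected", [(0.1, 7001), (0.05, 14001), (0.2, 3501)]
)
def test_grid_point_count_formula(width, n_expected):
    assert BinGrid(400.0, 1100.0, width).n_points == n_expected


def test_empty_peak_list_bins_to_zero_vector():
    spec = bin_spectrum(PeakList.empty(), BinGrid())
    assert spec.values.shape == (7001,)
    assert not spec.values.any()


def test_nearest_point_assignment_with_ties_to_lower():
    # width 0.5 keeps the midpoint exactly representable in binary floats
    grid = BinGrid(400.0, 402.0, 0.5)
    peaks = PeakList(np.array([400.2, 400.3, 400.25]), np.array([1.0, 1.0, 1.0]))
    spec = bin_spectrum(peaks, grid)
    # 400.2 -> bin 0; 400.3 -> bin 1; exact midpoint 400.25 -> lower bin 0
    assert spec.values[0] == 2.0
    assert spec.values[1] == 1.0


def test_out_of_window_centroids_discarded():
    grid = BinGrid(400.0, 1100.0, 0.1)
    peaks = PeakList(np.array([399.0, 1101.0, 700.0]), np.array([1.0, 1.0, 5.0]))
    spec = bin_spectrum(peaks, grid)
    assert spec.tic == 5.0


@given(
    mz=st.lists(st.floats(400.0, 1100.0), min_size=1, max_size=30),
    scale=st.floats(0.01, 100.0),
)
def test_binning_conserves_in_window_intensity(mz, scale):
    grid = BinGrid(400.0, 1100.0, 0.1)
    intensity = np.full(len(mz), scale)
    spec = bin_spectrum(PeakList(np.array(mz), intensity), grid)
    assert spec.tic == pytest.approx(float(intensity.sum()), rel=1e-12)


# ---------------------------------------------------------------------------
# normalisation and averaging

def test_tic_normalisation_example():
    grid = BinGrid(400.0, 400.2, 0.1)
    spec = BinnedSpectrum(grid, np.array([2.0, 2.0, 6.0]))
    out = normalise_spectrum(spec)
    assert out.values.tolist() == [0.2, 0.2, 0.6]
    assert out.normalised


def test_normalisation_scale_invariant():
    grid = BinGrid(400.0, 400.5, 0.1)
    values = np.array([1.0, 0.0, 3.0, 2.0, 0.0, 4.0])
    a = normalise_spectrum(BinnedSpectrum(grid, values))
    b = normalise_spectrum(BinnedSpectrum(grid, values * 0.25))
    assert np.array_equal(a.values, b.values)


def test_all_zero_vector_cannot_be_normalised():
    with pytest.raises(ValueError, match="all-zero"):
        normalise_spectrum(BinnedSpectrum(BinGrid(), np.zeros(7001)))


def test_average_single_spectrum_is_itself():
    grid = BinGrid(400.0, 400.2, 0.1)
    spec = BinnedSpectrum(grid, np.array([0.1, 0.2, 0.7]))
    assert np.array_equal(average_individual([spec]).values, spec.values)


def test_average_equals_brute_force_per_bin_mean():
    rng = np.random.default_rng(0)
    grid = BinGrid(400.0, 401.0, 0.1)
    specs = [BinnedSpectrum(grid, rng.random(grid.n_points)) for _ in range(3)]
    out = average_individual(specs)
    expected = sum(s.values for s in specs) / 3.0
    assert np.allclose(out.values, expected, rtol=1e-15)


def test_average_rejects_mixed_grids():
    a = BinnedSpectrum(BinGrid(400, 1100, 0.1), np.zeros(7001))
    b = BinnedSpectrum(BinGrid(400, 1100, 0.05), np.zeros(14001))
    with pytest.raises(ValueError, match="grids"):
        average_individual([a, b])


# ---------------------------------------------------------------------------
# full chain

def test_driftfree_data_unchanged_by_lockmass_stage():
    cfg = SimulationConfig(classes=["A"], seed=4, n_individuals_per_class=3,
                           pellets_per_individual=2, calibration_drift=0.0)
    series, _ = simulate_dataset(cfg)
    with_lm = preprocess_dataset(series, lockmass=554.26)
    without = preprocess_dataset(series, lockmass=None)
    assert np.array_equal(with_lm.to_numpy(), without.to_numpy())


def test_drift_recovered_by_lockmass_stage():
    """Lockmass correction of a drifting acquisition reproduces the feature
    vectors obtained after removing the true drift by hand."""
    cfg = SimulationConfig(classes=["A", "B"], seed=6, n_individuals_per_class=4,
                           pellets_per_individual=2, calibration_drift=0.02)
    drifting, _ = simulate_dataset(cfg)
    dedrifted = [
        ScanSeries(
            times=s.times,
            scans=[PeakList(p.mz - s.meta["drift"], p.intensity) for p in s.scans],
            meta=s.meta,
        )
        for s in drifting
    ]
    m_corrected = preprocess_dataset(drifting, lockmass=554.26)
    m_uncorrected = preprocess_dataset(drifting, lockmass=None)
    m_truth = preprocess_dataset(dedrifted, lockmass=None)

    def overlap(m):
        # shared fraction of normalised intensity with the truth, per sample
        return np.minimum(m.to_numpy(), m_truth.to_numpy()).sum(axis=1)

    # single-point gain correction of an additive offset is imperfect far
    # from the reference mass, but must move vectors toward the truth
    assert overlap(m_corrected).mean() > overlap(m_uncorrected).mean()
    assert overlap(m_corrected).mean() > 0.8


def test_preprocess_groups_pellets_by_individual(five_class_matrix):
    assert five_class_matrix.intensities.shape == (100, 7001)
    assert np.allclose(five_class_matrix.X().sum(axis=1), 1.0)
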