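"""Synthetic REIMS scan-series generator with ground-truth labels.

Emulates negative-ion acquisitions of faecal-pellet burns: each pellet
produces a 2-5 s burst of ion current at 1 scan/s, with a lipid-like peak
profile concentrated at 600-900 m/z, monoisotopic + first-13C isotopologue
pairs, a continuously infused lockmass ion, per-individual and per-pellet
log-normal intensity variation, class and covariate effects, chemical
noise, and a constant per-acquisition m/z calibration offset. The generator
gives every downstream stage a dataset with known truth, so the whole
pipeline is testable without instrument data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import C13_ABUNDANCE, C13_MASS_SHIFT, PeakList, ScanSeries

MZ_RANGE = (50.0, 1200.0)


@dataclass
class PeakTemplate:
    """One lipid-like ion species and the factors that modulate it.

    ``carbon_count`` drives the first-13C isotopologue, emitted at
    ``mz_mono + 1.00336`` with intensity ratio ``0.0107 * carbon_count``
    (linear approximation to the binomial isotope envelope).
    ``class_effects`` / ``covariate_effects`` are multiplicative intensity
    factors keyed by class label or ``"covariate=level"`` strings.

    An optional co-regulated satellite peak (``satellite_offset``,
    ``satellite_ratio``) shares the template's biological variation but is
    not a 13C partner — it reproduces ion pairs that correlate strongly
    without showing the isotopic intensity relationship.
    """

    mz_mono: float
    mean_log_intensity: float
    carbon_count: int
    class_effects: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    satellite_offset: float | None = None
    satellite_ratio: float | None = None

    def __post_init__(self) -> None:
        if not MZ_RANGE[0] <= self.mz_mono <= MZ_RANGE[1]:
            raise ValueError(f"mz_mono {self.mz_mono} outside instrument range {MZ_RANGE}")
        if self.carbon_count < 1:
            raise ValueError("carbon_count must be >= 1")
        for factors in (self.class_effects, self.covariate_effects):
            for key, f in factors.items():
                if not math.isfinite(f) or f < 0:
                    raise ValueError(f"effect factor for {key!r} must be finite and >= 0")
        if (self.satellite_offset is None) != (self.satellite_ratio is None):
            raise ValueError("satellite_offset and satellite_ratio must be set together")
        if self.satellite_ratio is not None and self.satellite_ratio <= 0:
            raise ValueError("satellite_ratio must be positive")

    @property
    def isotope_ratio(self) -> float:
        """Expected first-isotopologue / monoisotopic intensity ratio."""
        return C13_ABUNDANCE * self.carbon_count


def default_peak_templates(
    classes: list[str],
    seed: int,
    n_shared: int = 40,
    n_class: int = 20,
    class_effect: float = 4.0,
    covariate_effect: float = 1.3,
    min_separation: float = 2.5,
) -> list[PeakTemplate]:
    """Deterministic default profile: 40 shared + 20 class-affected peaks.

    Monoisotopic masses are drawn in the lipid-dominated 600-900 m/z region
    with a minimum spacing of ``min_separation`` Da so that no two template
    envelopes overlap within an isotope spacing. Carbon counts scale with
    mass (roughly one carbon per 18 Da, typical of glycerophospholipids).
    Class-affected peaks are assigned to classes cyclically with a
    multiplicative factor ``class_effect``; a handful of shared peaks carry
    a mild sex effect.
    """
    rng = np.random.default_rng(seed)
    n_total = n_shared + n_class
    mzs: list[float] = []
    while len(mzs) < n_total:
        cand = float(rng.uniform(600.0, 900.0))
        if all(abs(cand - m) >= min_separation for m in mzs):
            mzs.append(cand)
    templates = []
    for i, mz in enumerate(mzs):
        t = PeakTemplate(
            mz_mono=mz,
            mean_log_intensity=float(rng.uniform(np.log(2e6), np.log(5e7))),
            carbon_count=max(1, int(round(mz / 18.0))),
        )
        if i >= n_shared:
            cls = classes[(i - n_shared) % len(classes)]
            t.class_effects = {cls: class_effect}
        elif i < 6:
            t.covariate_effects = {"sex=F": covariate_effect}
        templates.append(t)
    return templates


@dataclass
class SimulationConfig:
    """Study design and noise model for one synthetic dataset.

    Intensity variation is log-normal at three levels: a per-individual
    random effect (``individual_sd``), a per-pellet effect (``pellet_sd``)
    and independent per-centroid scan noise, all SDs on the natural-log
    scale and applied per peak. Scan noise follows counting statistics:
    the relative SD of a centroid of expected intensity I is
    ``scan_noise_sd * sqrt(scan_noise_ref_intensity / I)`` (capped at 0.8),
    so weak ions — including first isotopologues — are proportionally
    noisier than strong ones, as in real ion-counting detection. The
    log-normal is mean-corrected, so noise leaves expected intensities
    unchanged. ``calibration_drift`` is
    the maximum magnitude of the constant additive m/z offset drawn per
    acquisition; the lockmass stage downstream exists to remove it.
    Chemical noise adds ~``noise_peaks_per_scan`` exponential-intensity
    centroids (mean ``noise_floor`` counts) at uniform m/z in every scan.
    """

    classes: list[str]
    seed: int
    n_individuals_per_class: int = 20
    pellets_per_individual: int = 3
    peaks: list[PeakTemplate] | None = None
    individual_sd: float = 0.4
    pellet_sd: float = 0.2
    scan_noise_sd: float = 0.15
    scan_noise_ref_intensity: float = 1e7
    noise_floor: float = 2e5
    noise_peaks_per_scan: int = 150
    calibration_drift: float = 0.02
    burn_duration_s: float = 4.0
    scan_rate_hz: float = 1.0
    baseline_scans: int = 3
    lockmass_mz: float = 554.26
    lockmass_intensity: float = 5e6
    lockmass_carbon_count: int = 28

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("classes must be a non-empty list")
        if self.n_individuals_per_class < 1 or self.pellets_per_individual < 1:
            raise ValueError("counts must be >= 1")
        for name in ("individual_sd", "pellet_sd", "scan_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 1.0 <= self.burn_duration_s <= 10.0:
            raise ValueError("burn_duration_s must be within [1, 10] s")
        if self.calibration_drift < 0 or self.calibration_drift > 0.05:
            raise ValueError("calibration_drift magnitude must be within [0, 0.05] Da")
        if self.peaks is None:
            self.peaks = default_peak_templates(self.classes, self.seed)
        if not self.peaks:
            raise ValueError("peak template list must be non-empty")


def _covariates(cls: str, index: int) -> dict[str, str]:
    # Balanced deterministic covariate assignment within each class.
    return {
        "sex": "F" if index % 2 == 0 else "M",
        "site": f"site{(index // 2) % 2 + 1}",
        "diet": "chow",
    }


def _template_amplitude(
    t: PeakTemplate, cls: str, covariates: dict[str, str]
) -> float:
    amp = math.exp(t.mean_log_intensity) * t.class_effects.get(cls, 1.0)
    for cov, level in covariates.items():
        amp *= t.covariate_effects.get(f"{cov}={level}", 1.0)
    return amp


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[ScanSeries], pd.DataFrame]:
    """Generate one acquisition per pellet plus a ground-truth table.

    Each acquisition holds ``baseline_scans`` near-empty scans, a truncated
    Gaussian burst of ``burn_duration_s * scan_rate_hz`` burn scans, and
    trailing baseline scans. The ground truth records one row per
    individual (sample_id, individual_id, class and covariates). Identical
    seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    templates = config.peaks
    n_peaks = len(templates)
    n_burn = max(1, int(round(config.burn_duration_s * config.scan_rate_hz)))
    n_scans = config.baseline_scans * 2 + n_burn
    times = np.arange(n_scans) / config.scan_rate_hz
    burn_slice = range(config.baseline_scans, config.baseline_scans + n_burn)
    centre = (n_burn - 1) / 2.0
    sigma = max(n_burn / 4.0, 0.5)
    weights = np.exp(-0.5 * ((np.arange(n_burn) - centre) / sigma) ** 2)

    lock_iso_ratio = C13_ABUNDANCE * config.lockmass_carbon_count

    def noisy(expected: np.ndarray) -> np.ndarray:
        # Mean-corrected log-normal counting noise; relative SD ~ 1/sqrt(I).
        if config.scan_noise_sd <= 0:
            return expected
        sd = np.where(
            expected > 0,
            config.scan_noise_sd
            * np.sqrt(config.scan_noise_ref_intensity / np.maximum(expected, 1e-12)),
            0.0,
        )
        sd = np.minimum(sd, 0.8)
        z = rng.standard_normal(np.shape(expected))
        return expected * np.exp(z * sd - 0.5 * sd * sd)

    series_list: list[ScanSeries] = []
    records = []
    for cls in config.classes:
        for i in range(config.n_individuals_per_class):
            sample_id = f"{cls}_{i:02d}"
            cov = _covariates(cls, i)
            records.append(
                {"sample_id": sample_id, "individual_id": sample_id, "class": cls, **cov}
            )
            base_amp = np.array(
                [_template_amplitude(t, cls, cov) for t in templates]
            )
            ind_mult = np.exp(rng.normal(0.0, config.individual_sd, n_peaks))
            for p in range(config.pellets_per_individual):
                pellet_mult = np.exp(rng.normal(0.0, config.pellet_sd, n_peaks))
                drift = (
                    float(rng.uniform(-config.calibration_drift, config.calibration_drift))
                    if config.calibration_drift > 0
                    else 0.0
                )
                scans = []
                for s in range(n_scans):
                    mz_parts = [np.array([config.lockmass_mz + drift,
                                          config.lockmass_mz + C13_MASS_SHIFT + drift])]
                    int_parts = [
                        noisy(
                            config.lockmass_intensity * np.array([1.0, lock_iso_ratio])
                        )
                    ]
                    if s in burn_slice:
                        w = weights[s - config.baseline_scans]
                        amp = base_amp * ind_mult * pellet_mult * w
                        mono_mz = np.array([t.mz_mono for t in templates]) + drift
                        iso_ratio = np.array([t.isotope_ratio for t in templates])
                        mz_parts += [mono_mz, mono_mz + C13_MASS_SHIFT]
                        int_parts += [noisy(amp), noisy(amp * iso_ratio)]
                        sat_idx = [
                            j for j, t in enumerate(templates)
                            if t.satellite_offset is not None
                        ]
                        if sat_idx:
                            mz_parts.append(
                                np.array(
                                    [templates[j].mz_mono + templates[j].satellite_offset
                                     + drift for j in sat_idx]
                                )
                            )
                            int_parts.append(
                                noisy(
                                    np.array(
                                        [amp[j] * templates[j].satellite_ratio
                                         for j in sat_idx]
                                    )
                                )
                            )
                    if config.noise_floor > 0 and config.noise_peaks_per_scan > 0:
                        n_noise = int(rng.poisson(config.noise_peaks_per_scan))
                        if n_noise:
                            mz_parts.append(rng.uniform(*MZ_RANGE, n_noise))
                            int_parts.append(rng.exponential(config.noise_floor, n_noise))
                    scans.append(
                        PeakList(
                            np.concatenate(mz_parts), np.concatenate(int_parts)
                        ).sorted_by_mz()
                    )
                series_list.append(
                    ScanSeries(
                        times=times.copy(),
                        scans=scans,
                        polarity="negative",
                        meta={
                            "sample_id": sample_id,
                            "pellet_id": f"{sample_id}/p{p}",
                            "class": cls,
                            "drift": drift,
                        },
                    )
                )
    return series_list, pd.DataFrame(records).set_index("sample_id", drop=False)


def with_planted_signal(
    config: SimulationConfig,
    n_planted: int = 3,
    effect: float = 4.0,
) -> tuple[SimulationConfig, list[float]]:
    """Return a config whose ``n_planted`` strongest peaks discriminate classes.

    Clears all existing class effects and plants a factor-``effect``
    enhancement of the first ``n_planted`` templates in the first class;
    returns the planted monoisotopic m/z values for recovery checks.
    """
    peaks = [replace(t, class_effects={}) for t in config.peaks]
    planted = []
    for j in range(n_planted):
        peaks[j].class_effects = {config.classes[0]: effect}
        planted.append(peaks[j].mz_mono)
    return replace(config, peaks=peaks), planted
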