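# scatreims

Phenotype classification from REIMS fingerprints of faecal pellets.

Rapid evaporative ionisation mass spectrometry (REIMS) turns the aerosol
released while a sample burns under a diathermy electrode into a mass
spectrum, with no sample preparation. Burning a single rodent faecal pellet
yields a rich negative-ion lipid fingerprint (dominated by phosphatidyl
glycerols, phosphatidyl ethanolamines and phosphatidic acids at 600–900
m/z) that is characteristic enough to classify the **species, sex,
maturity or strain** of the animal that produced it — molecular scatology
without DNA.

`scatreims` is an open, tested re-implementation of that workflow for
ecologists and analytical chemists: everything from raw scan series to
confusion matrices, including the preprocessing steps usually hidden in
proprietary vendor software, plus a synthetic REIMS data generator so the
entire pipeline can be exercised and validated with no instrument data.

## The pipeline

1. **Burn-event detection.** Each pellet burn is a 2–5 s burst of total ion
   current (TIC) against a near-zero baseline; contiguous scans above 10%
   of the run maximum form one event.
2. **Thresholded aggregation.** Centroids below 3×10⁵ counts are discarded
   per scan; survivors are summed into one spectrum per burn.
3. **Lockmass recalibration.** Single-point multiplicative correction to a
   reference ion of known mass (leu-enkephalin [M−H]⁻ at 554.26 m/z, or a
   propan-2-ol background ion at 325.19).
4. **Binning.** Centroids are mapped onto an inclusive fixed grid over the
   400–1100 m/z analysis window: 7001 points at 0.1 Da width, 14001 at
   0.05 Da.
5. **Normalisation and averaging.** TIC normalisation (each vector sums to
   1) makes results independent of pellet size — a quarter pellet gives the
   same fingerprint; the 3–4 pellet spectra of one individual are averaged.
6. **Classification.** Two tracks: linear discriminant analysis on the top
   12 principal components (DFA, for visualisation and resubstitution
   accuracy), and a 500-tree random forest reported as a row-percent
   confusion matrix, evaluated either out-of-bag on all samples, on a
   stratified 70/30 split, or on an entirely held-out population.
7. **Diagnostics.** Permutation importance (per-tree out-of-bag mean
   decrease in accuracy, the R `randomForest` convention) ranks the
   discriminant m/z bins; label-randomisation ("pseudospecies") tests
   establish the workflow's chance level; cross-correlation of bins
   1.00336 Da apart separates genuine monoisotopic/¹³C isotopologue pairs
   (r ≥ 0.9 and intensity ratio ≈ 0.0107 × carbon count) from co-regulated
   but non-isotopic ion pairs.

The synthetic generator emulates all of this structure — burn bursts,
lipid-like peak profiles with isotope envelopes, individual/pellet/scan
noise, covariate effects, chemical noise and calibration drift — with
known ground truth. See `docs/methods.md` for the model.

## Worked example

Run the packaged five-species demonstration (5 simulated rodent species,
8 individuals each, 3 pellets per individual):

```sh
scatreims run --config examples/five_species.yaml --out demo_out
```

which prints

```
overall accuracy 97.5% (40 samples, 7001 bins); bundle in demo_out
```

and writes the full report bundle (feature matrix, confusion matrix,
LDA scores, importance ranking, isotope-pair table, manifest). From the
bundle for this config: per-class accuracies are BV 100%, FV 87.5%,
HM 100%, WM 100%, R 100% (one field vole misclassified out of-bag); the
five displayed discriminant bins are m/z 658.7, 889.0, 818.1, 805.0 and
821.8 — note the ranking itself places the ¹³C isotopologue 659.7 first
and its monoisotopic partner 658.7 second, and the display list collapses
each isotope envelope to its monoisotopic member; the isotope screen flags
51 isotopic bin pairs among 8127 candidate pairs 1 Da apart.

The same stages are available individually (`scatreims simulate`,
`preprocess`, `classify`, `explain`, `randomise`, `isopairs`) and as a
Python API:

```python
from scatreims import SimulationConfig, matrix_from_simulation, rf_fit_evaluate

cfg = SimulationConfig(classes=["BV", "FV", "HM", "WM", "R"], seed=42,
                       n_individuals_per_class=20, pellets_per_individual=3)
matrix = matrix_from_simulation(cfg)          # 100 x 7001 feature matrix
report, forest = rf_fit_evaluate(matrix, mode="all_data", seed=42)
print(report.confusion.round(1))              # row-percent confusion matrix
```

Real acquisitions can enter the pipeline as centroided mzML or as the
JSON-lines scan format (`scatreims preprocess --in dir/ --out matrix.csv`).

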