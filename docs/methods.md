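# Methods

This note documents the models, numerical choices and known limitations of
`scatreims`. It covers the synthetic data generator, the preprocessing
chain, the two classification tracks and the diagnostic analyses.

## Synthetic REIMS acquisitions

The generator emulates negative-ion scan series recorded at 1 scan/s over
50–1200 m/z while single faecal pellets burn for 2–5 s. Each acquisition
contains 3 baseline scans, `round(burn_duration_s × scan_rate_hz)` burn
scans, and 3 trailing baseline scans.

**Burn profile.** The total ion current of a burn follows a truncated
Gaussian over the burn window (σ = n_scans/4), a smooth rise–peak–fall
matching the qualitative shape of real burn bursts. Nothing downstream
depends on the exact shape; burn detection only needs a burst that clears
the baseline.

**Peak model.** A `PeakTemplate` is one lipid-like species: a monoisotopic
mass (default profiles draw 60 masses in 600–900 m/z with ≥ 2.5 Da
spacing, so no two envelopes overlap within an isotope spacing), a mean
log-intensity (uniform on log[2×10⁶, 5×10⁷] counts, spanning the decades
seen in real spectra), and a carbon count tied to mass (≈ one carbon per
18 Da, typical of glycerophospholipids). Each template emits its
monoisotopic centroid and a first ¹³C isotopologue at +1.00336 Da with
intensity ratio 0.0107 × carbon count — the linear (single-substitution)
approximation to the binomial isotope envelope, which is within ~1% of the
exact binomial value for C30–C50 species. Only the first isotopologue is
modelled; higher isotopologues are an order of magnitude weaker and play
no role in any analysis here.

A template may also carry a *satellite*: a co-regulated peak at a
configurable offset and intensity ratio that shares the template's
biological variation but is not a ¹³C partner. This reproduces the ion
pairs observed in real data that correlate strongly at 1 Da spacing yet
violate the isotopic intensity relationship (same molecular class, not a
¹²C/¹³C pair).

**Variance components.** Intensities vary log-normally at three levels,
each applied per peak:

| component | default SD (ln scale) | emulates |
|---|---|---|
| individual | 0.4 | diet, microbiome, physiology of the animal |
| pellet | 0.2 | pellet-to-pellet variation within an individual |
| scan (counting) | 0.15 at 10⁷ counts | ion-counting shot noise |

Scan noise follows counting statistics: the relative SD of a centroid with
expected intensity I is `0.15 × sqrt(10⁷ / I)`, capped at 0.8. Weak ions —
including every first isotopologue — are therefore proportionally noisier
than strong ones, as in real ion detection; this is also what makes a
monoisotopic bin a slightly better classifier feature than its
isotopologue partner. The log-normal is mean-corrected (`exp(zσ − σ²/2)`)
so noise never biases expected intensities, keeping the isotopologue ratio
unbiased in expectation.

**Class and covariate effects** are multiplicative factors on template
intensities. The default profile gives 20 of the 60 peaks a ×4 enhancement
in one class (assigned cyclically) and 6 shared peaks a mild ×1.3 sex
effect. Individuals receive balanced deterministic covariates (sex
alternating, two sites, one diet).

**Chemical noise.** Every scan receives ~150 centroids at uniform m/z with
exponential intensities (mean 2×10⁵ counts). After the 3×10⁵ vendor
threshold, roughly a fifth survive; over a cohort this populates thousands
of background bins, which is what gives the isotope screen a realistic
candidate-pair load and the forest a realistic noise floor.

**Calibration drift.** One constant additive m/z offset per acquisition,
drawn uniformly within ±0.02 Da by default (bounded at ±0.05). A lockmass
ion (leu-enkephalin [M−H]⁻ 554.26, C28, 5×10⁶ counts) is emitted in every
scan, emulating continuous infusion.

**Determinism.** All randomness flows from one `numpy` Generator seeded by
`SimulationConfig.seed`; identical configs give bit-identical datasets.

**What the generator does not emulate** — and hence what passing tests do
*not* establish about instrument data: real adduct/fragmentation
chemistry, m/z-dependent resolution and peak shape, detector saturation,
inter-batch drift of the whole intensity scale, chimeric burns of touching
pellets, or biological covariance structure between lipid species (each
template varies independently). Accuracies obtained on synthetic data are
planted-signal recoveries, not predictions of field performance.

## Preprocessing

The chain reproduces the vendor-software steps: per-scan intensity
threshold (3×10⁵ counts) → summation per burn → lockmass correction →
binning over 400–1100 m/z → TIC normalisation → per-individual averaging.

*Bin geometry.* The grid is inclusive: points at `400 + k·w`, giving
7001 points at w = 0.1 (14001 at 0.05). Centroids go to the nearest grid
point; an exact midpoint goes to the lower point. Centroids outside the
outer half-bin margins are discarded.

*Thresholding order.* The threshold is applied per scan before summation —
the conservative reading of "data above the threshold were summed". With
threshold 0 the chain conserves total intensity into the window.

*Lockmass model.* Correction is multiplicative (single-point gain),
because time-of-flight mass error scales with m/z: every m/z is multiplied
by `reference / observed`, where the observed reference is the most
intense centroid within ±0.25 Da of the nominal mass. The correction is
idempotent to machine precision. When the simulator's drift is additive,
a gain correction anchored at 554.26 over-corrects high masses (residual
≈ drift × (1 − m/z / 554.26), at most ~0.03 Da at 900 m/z for a 0.05 Da
offset) — it reduces every peak's error but does not zero it, which the
tests verify as an improvement in shared normalised intensity with the
drift-free truth rather than as exact recovery. If no candidate is found
in the search window the spectrum passes through unchanged with an
"uncorrectable" warning.

*Normalisation.* TIC normalisation (vector sums to 1) stands in for the
undocumented proprietary normalise/scale step. It makes the pipeline
exactly invariant to uniform intensity scaling — quartering every centroid
(a quarter pellet) gives bit-identical feature vectors when the threshold
is disabled, because scaling by a power of two is exact in IEEE floats and
the normalisation ratio cancels it.

*Averaging.* Pellet spectra are normalised first, then averaged per
individual (arithmetic per-bin mean), so a small pellet contributes
equally rather than proportionally to its ion yield.

## Classification

**PCA → LDA (DFA).** PCA (mean-centred, no unit-variance scaling by
default, since TIC-normalised intensities share a scale; scaling is
available as an option) retains the top 12 components; LDA is fitted on
the PC scores with scikit-learn's SVD solver, which handles degenerate
within-class scatter without explicit ridge terms. The first two
discriminant coordinates are the conventional scatter axes; resubstitution
accuracy is reported. Twelve components is the standard choice for this
workflow; with ≥ 13 samples it is never rank-deficient.

**Random forest.** 500 trees, √p features per split, bootstrap sampling —
the R `randomForest` defaults. Three evaluation modes:

- `all_data`: grown on every sample, confusion matrix from **out-of-bag**
  predictions. Resubstitution would be trivially ~100% and is not offered.
- `split_70_30`: stratified random split by seed (stratification keeps
  every class in both halves); confusion on the 30%.
- `holdout_predict`: fit on one population, predict another; test classes
  must be a subset of training classes.

Confusion matrices are row-percentages (each true-class row sums to 100);
overall accuracy is the sample-weighted diagonal mean. Samples are sorted
by id before fitting, so results are invariant to input row order given a
fixed seed.

## Diagnostics

**Permutation importance.** Per-tree out-of-bag mean decrease in accuracy:
for each tree, accuracy on its out-of-bag samples is compared with the
accuracy after permuting one feature within those samples (10 permutations
by default, seeded), and the drop is averaged over trees. The per-tree
form — the R `randomForest` MeanDecreaseAccuracy — is used deliberately
instead of a forest-level permutation score: when two features are
strongly correlated (a monoisotopic bin and its isotopologue), the
aggregated forest compensates for a permuted feature with its partner and
the forest-level score collapses toward zero for both; the per-tree score
still registers the damage to the trees that used the feature. A constant
feature scores exactly zero. Because permuting all ~7000 bins is wasteful
when most hold only sparse noise, candidates are pre-screened by the
forest's impurity importance (top 50 by default); an explicit candidate
list can be supplied instead.

**Display rule for isotope envelopes.** Both members of an isotopic pair
stay in the model and in the ranking, but the *displayed* top-k list walks
the ranking mapping each bin to its envelope's monoisotopic representative
and de-duplicating — a generative form of the reporting convention of
keeping both ions in the analysis while displaying only the monoisotopic.
The display list therefore never contains both members of an isotopic
pair, and a planted discriminant species is recovered whether the forest
happened to lean on its monoisotopic or its isotopologue bin.

**Randomisation ("pseudospecies") test.** The target labels are permuted
`n_shuffles` times and the full all-data OOB evaluation is rerun for each;
the true-label accuracy is compared with the null's 95th percentile. One
property of this null deserves emphasis: OOB accuracy under permuted
labels is systematically a few points *below* 1/k on data with
class-correlated cluster structure, because a sample's own (permuted)
class is underrepresented among its in-bag cluster neighbours. On the
default five-class study design the null mean sits around 13–15% rather
than 20%; the R `randomForest` implementation reproduces the same values
on identical matrices and permutations. The decisive statistic is
therefore the exceedance of the null's 95th percentile, not the distance
of the null mean from 1/k.

**Isotopologue screening.** For every ordered pair of non-constant bins
separated by the ¹³C spacing, the Pearson correlation across samples and
the median intensity ratio (heavy/light, over samples with signal in both)
are computed. Because 1.00336 Da is not an exact bin multiple, both the
floor and ceil whole-bin offsets are screened (10 and 11 bins at 0.1 Da);
a centroid falling in the top few percent of its bin has its partner one
bin further than the nominal offset. Verdicts:

- **isotopic**: r ≥ 0.9, co-occurrence in ≥ 50% of samples, and median
  ratio within [0.1, 1.0] — the envelope range of C10–C90 species;
- **correlated_non_isotopic**: correlated and prevalent but ratio outside
  the band;
- **unrelated**: everything else.

The prevalence requirement is this package's addition: two sparse noise
bins that co-occur in one or two samples can reach r ≈ 1 spuriously, and
with ~10⁴ candidate pairs such coincidences are certain; requiring a
consistent envelope across half the cohort removes them without touching
genuine pairs, which co-occur in essentially every sample. The r ≥ 0.9 and
ratio-band defaults are documented choices (the qualitative criterion
"very high correlation" is not quantified anywhere); both are exposed as
parameters.

**Misclassification annotation.** For each misclassified sample and each
displayed top bin, the table reports the sample's intensity, its true
class's median, and whether the sample lies above or below that median —
the tabular form of the large-symbol overlays on importance plots.

## Problem sizes

Default study configurations were chosen to run comfortably on one CPU:
the five-class design uses 20 individuals per class × 3 pellets (300
acquisitions, a 100 × 7001 matrix), the randomisation null 50 shuffles,
the importance-recovery check 10 independent datasets of 2 × 12
individuals, and the isotope screen 50 individuals with 10 planted pairs.
The full test suite runs in ~2 minutes; `scripts/acceptance.py` in ~1.5.

## Known limitations

- The proprietary normalise/scale internals are undocumented; TIC
  normalisation is a declared stand-in, not a reverse-engineering.
- Single-point gain correction cannot fully remove an additive offset
  (see above); multi-point calibration curves are out of scope.
- Profile-mode spectra are rejected; peak picking must happen upstream.
- The mzML reader is deliberately minimal (single-run centroided MS1,
  32/64-bit, none/zlib compression); it round-trips this package's writer
  exactly and reads conforming vendor exports, but it is not a general
  PSI-MS validator.
- Importance pre-screening by impurity can in principle miss a feature
  that is permutation-important but never chosen for splits; with ≤ 100
  informative bins among thousands of sparse ones this does not occur in
  practice, and the candidate list can be forced explicitly.
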