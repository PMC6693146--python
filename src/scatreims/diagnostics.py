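"""Interpretive analyses on fitted classifiers and feature matrices.

Covers the four diagnostics used to interrogate a fingerprint model:
ranking the most discriminant m/z bins by permutation importance,
label-randomisation ("pseudospecies") null tests of the whole workflow,
cross-correlation screening for monoisotopic/first-13C isotopologue bin
pairs, and annotation of misclassified samples against the top bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)

from .classify import ClassificationReport, FeatureMatrix, rf_fit_evaluate
from .spectra import C13_MASS_SHIFT


def _n_samples_bootstrap(n: int, max_samples) -> int:
    try:
        return _get_n_samples_bootstrap(n, max_samples, None)
    except TypeError:  # older scikit-learn without the sample_weight argument
        return _get_n_samples_bootstrap(n, max_samples)


def _oob_indices(random_state, n: int, n_boot: int) -> np.ndarray:
    try:
        return _generate_unsampled_indices(random_state, n, n_boot, None)
    except TypeError:
        return _generate_unsampled_indices(random_state, n, n_boot)


# ---------------------------------------------------------------------------
# Permutation importance (out-of-bag mean decrease in accuracy)

def oob_permutation_importance(
    rf: RandomForestClassifier,
    X: np.ndarray,
    y: pd.Series,
    candidate_idx: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Per-tree out-of-bag mean decrease in accuracy.

    For every tree, the accuracy on its out-of-bag samples is compared with
    the accuracy after permuting one feature within those samples; the drop,
    averaged over ``n_repeats`` permutations and over trees, is the
    importance. Scoring each tree on its own out-of-bag samples (rather
    than the aggregated forest vote) keeps the measure sensitive when
    informative features are redundant — a forest-level score barely moves
    when a correlated partner bin compensates, a per-tree score still does.

    Only ``candidate_idx`` columns are scored; a constant column scores
    exactly 0. Returns importances on the accuracy scale (fractions).
    """
    rng = np.random.default_rng(seed)
    classes = np.asarray(rf.classes_)
    y_code = np.searchsorted(classes, np.asarray(y)).astype(np.float64)
    n = X.shape[0]
    n_boot = _n_samples_bootstrap(n, rf.max_samples)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    drops = np.zeros(len(candidate_idx))
    used = 0
    for tree in rf.estimators_:
        oob = _oob_indices(tree.random_state, n, n_boot)
        if len(oob) == 0:
            continue
        used += 1
        Xo = X32[oob]
        yo = y_code[oob]
        m = len(oob)
        base = _tree_accuracy(tree, Xo, yo)
        # All repeats of one permuted column are scored in a single pass.
        Xrep = np.ascontiguousarray(np.tile(Xo, (n_repeats, 1)))
        yrep = np.tile(yo, n_repeats)
        for j, f in enumerate(candidate_idx):
            saved = Xrep[:, f].copy()
            for r in range(n_repeats):
                Xrep[r * m : (r + 1) * m, f] = Xo[rng.permutation(m), f]
            perm_acc = _tree_accuracy(tree, Xrep, yrep)
            drops[j] += base - perm_acc
            Xrep[:, f] = saved
    if used == 0:
        raise ValueError("no tree had out-of-bag samples; was the forest bootstrapped?")
    return drops / used


def _tree_accuracy(tree, X32: np.ndarray, y_code: np.ndarray) -> float:
    # Bypasses per-call input validation; X32 must be C-contiguous float32.
    value = tree.tree_.predict(X32)  # per-sample class counts at the leaf
    if value.ndim == 3:  # (n, n_outputs, k) in older scikit-learn
        value = value[:, 0, :]
    pred = np.argmax(value, axis=1)
    return float(np.mean(pred == y_code))


@dataclass
class ImportanceReport:
    """Ranked discriminant m/z bins with isotopologue-pair annotations.

    ``ranked_bins`` is sorted by importance (non-increasing). When a top
    bin's 1-Da-lighter partner forms an isotopic pair, the bin stays in the
    ranking but is dropped from ``display_bins`` so plots show only the
    monoisotopic member of each envelope.
    """

    ranked_bins: pd.DataFrame  # columns: bin_mz, importance
    top_k: int
    pair_annotations: dict[float, dict]
    display_bins: list[float]

    def top_bins(self) -> list[float]:
        return list(self.ranked_bins["bin_mz"].iloc[: self.top_k])

    def to_dict(self) -> dict:
        return {
            "top_k": self.top_k,
            "ranked_bins": self.ranked_bins.head(self.top_k).to_dict("records"),
            "pair_annotations": {
                f"{mz:.2f}": ann for mz, ann in self.pair_annotations.items()
            },
            "display_bins": self.display_bins,
        }


def top_discriminant_bins(
    rf: RandomForestClassifier,
    matrix: FeatureMatrix,
    target: str = "class",
    k: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    n_candidates: int = 50,
    candidates_mz: list[float] | None = None,
    r_min: float = 0.9,
    ratio_band: tuple[float, float] = (0.1, 1.0),
    min_prevalence: float = 0.5,
) -> ImportanceReport:
    """Rank bins by out-of-bag permutation importance and annotate isotope pairs.

    Permuting all ~7000 bins is wasteful when most are empty noise, so
    candidates are pre-screened by the forest's impurity (Gini) importance
    (top ``n_candidates``) and only those are scored by permutation; pass
    ``candidates_mz`` to score an explicit bin list instead.
    """
    n_bins = matrix.grid.n_points
    if k > n_bins:
        raise ValueError(f"k={k} exceeds the number of bins ({n_bins})")
    centers = matrix.bin_mz
    if candidates_mz is not None:
        idx = matrix.grid.bin_index(np.asarray(candidates_mz, dtype=float))
        if np.any(idx < 0):
            raise ValueError("candidate m/z outside the bin grid")
        candidate_idx = np.unique(idx)
    else:
        gini = rf.feature_importances_
        order = np.argsort(gini)[::-1]
        candidate_idx = np.sort(order[: min(n_candidates, n_bins)])
    imp = oob_permutation_importance(
        rf, matrix.X(), matrix.y(target), candidate_idx, n_repeats=n_repeats, seed=seed
    )
    order = np.argsort(imp, kind="stable")[::-1]
    ranked = pd.DataFrame(
        {"bin_mz": centers[candidate_idx[order]], "importance": imp[order]}
    )
    offsets = _isotope_offsets(matrix.grid.width)
    values = matrix.intensities.to_numpy()

    def annotate(b: int) -> dict:
        for offset in offsets:
            if b + offset < n_bins:
                pc = _pair_verdict(
                    values[:, b], values[:, b + offset],
                    centers[b], centers[b + offset],
                    r_min, ratio_band, min_prevalence,
                )
                if pc.verdict == "isotopic":
                    return {
                        "partner_mz": float(centers[b + offset]),
                        "role": "monoisotopic",
                        "displayed": True,
                    }
        for offset in offsets:
            if b - offset >= 0:
                pc = _pair_verdict(
                    values[:, b - offset], values[:, b],
                    centers[b - offset], centers[b],
                    r_min, ratio_band, min_prevalence,
                )
                if pc.verdict == "isotopic":
                    return {
                        "partner_mz": float(centers[b - offset]),
                        "role": "first_isotopologue",
                        "displayed": False,
                    }
        return {"partner_mz": None, "role": "unpaired", "displayed": True}

    annotations: dict[float, dict] = {}
    for mz in ranked["bin_mz"].iloc[:k]:
        b = int(matrix.grid.bin_index(np.array([mz]))[0])
        annotations[float(mz)] = annotate(b)

    # Displayed list: walk the full ranking, represent each isotope envelope
    # by its monoisotopic bin, and keep the first k distinct representatives.
    # Both members of a pair stay in the model and in ranked_bins.
    display: list[float] = []
    for mz in ranked["bin_mz"]:
        if len(display) >= k:
            break
        b = int(matrix.grid.bin_index(np.array([mz]))[0])
        ann = annotate(b)
        rep = float(mz) if ann["displayed"] else float(ann["partner_mz"])
        if rep not in display:
            display.append(rep)
    return ImportanceReport(
        ranked_bins=ranked, top_k=k, pair_annotations=annotations, display_bins=display
    )


# ---------------------------------------------------------------------------
# Randomisation ("pseudospecies") test

@dataclass
class RandomisationResult:
    """Null distribution of workflow accuracy under label permutation."""

    null_accuracies: np.ndarray  # percent
    true_accuracy: float  # percent
    chance_level: float  # percent, 100/k for balanced designs
    n_shuffles: int
    seed: int

    @property
    def null_95th_percentile(self) -> float:
        return float(np.percentile(self.null_accuracies, 95))

    @property
    def exceeds_null(self) -> bool:
        return self.true_accuracy > self.null_95th_percentile

    def to_dict(self) -> dict:
        return {
            "true_accuracy_percent": self.true_accuracy,
            "null_mean_percent": float(self.null_accuracies.mean()),
            "null_95th_percentile_percent": self.null_95th_percentile,
            "chance_level_percent": self.chance_level,
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
            "exceeds_null": self.exceeds_null,
            "null_accuracies_percent": self.null_accuracies.tolist(),
        }


def randomisation_test(
    matrix: FeatureMatrix,
    target: str = "class",
    n_shuffles: int = 50,
    seed: int = 0,
    n_trees: int = 500,
) -> RandomisationResult:
    """Rerun the all-data random-forest evaluation on shuffled labels.

    Each shuffle permutes the target labels across samples and repeats the
    full out-of-bag evaluation; the resulting null accuracies establish the
    chance level of the complete workflow. The true-label accuracy is
    compared against the null's 95th percentile.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    true_report, _ = rf_fit_evaluate(
        matrix, target=target, mode="all_data", seed=seed, n_trees=n_trees
    )
    rng = np.random.default_rng(seed)
    k = matrix.y(target).nunique()
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        labels = matrix.labels.copy()
        labels[target] = rng.permutation(labels[target].to_numpy())
        shuffled = FeatureMatrix(matrix.intensities, labels, matrix.grid)
        rep, _ = rf_fit_evaluate(
            shuffled,
            target=target,
            mode="all_data",
            seed=int(rng.integers(0, 2**31 - 1)),
            n_trees=n_trees,
        )
        null[s] = rep.overall_accuracy
    return RandomisationResult(
        null_accuracies=null,
        true_accuracy=true_report.overall_accuracy,
        chance_level=100.0 / k,
        n_shuffles=n_shuffles,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Isotopologue pair detection

@dataclass
class PairCorrelation:
    """Cross-correlation verdict for a pair of bins ~1 Da apart."""

    bin_a: float  # lighter (candidate monoisotopic) bin m/z
    bin_b: float  # heavier (candidate first-isotopologue) bin m/z
    pearson_r: float
    median_ratio: float  # intensity(b) / intensity(a) where both present
    prevalence: float  # fraction of samples with signal in both bins
    verdict: str  # "isotopic" | "correlated_non_isotopic" | "unrelated"


def _isotope_offsets(width: float, spacing: float = C13_MASS_SHIFT) -> list[int]:
    """Whole-bin offsets a 13C partner can occupy.

    The isotope spacing is not an exact bin multiple, so a partner sits
    either floor(spacing/width) or ceil(spacing/width) bins up depending on
    where the monoisotopic centroid falls within its bin.
    """
    lo, hi = int(np.floor(spacing / width)), int(np.ceil(spacing / width))
    offsets = sorted({o for o in (lo, hi) if o >= 1})
    if not offsets:
        raise ValueError("isotope spacing smaller than one bin")
    return offsets


def _pair_verdict(
    a: np.ndarray,
    b: np.ndarray,
    mz_a: float,
    mz_b: float,
    r_min: float,
    ratio_band: tuple[float, float],
    min_prevalence: float,
) -> PairCorrelation:
    both = (a > 0) & (b > 0)
    prevalence = float(both.mean())
    ratio = float(np.median(b[both] / a[both])) if both.any() else np.nan
    if a.std() == 0 or b.std() == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    if np.isfinite(r) and r >= r_min and prevalence >= min_prevalence:
        lo, hi = ratio_band
        verdict = "isotopic" if lo <= ratio <= hi else "correlated_non_isotopic"
    else:
        verdict = "unrelated"
    return PairCorrelation(mz_a, mz_b, r, ratio, prevalence, verdict)


def isotopomer_pairs(
    matrix: FeatureMatrix,
    spacing: float = C13_MASS_SHIFT,
    r_min: float = 0.9,
    ratio_band: tuple[float, float] = (0.1, 1.0),
    min_prevalence: float = 0.5,
) -> pd.DataFrame:
    """Screen all bin pairs one isotope spacing apart for 13C envelopes.

    For each pair of non-constant bins separated by ``spacing`` (rounded to
    whole bins), the Pearson correlation across samples and the median
    intensity ratio are computed. A pair is "isotopic" when it correlates
    strongly (r >= ``r_min``), co-occurs in at least ``min_prevalence`` of
    samples, and its ratio lies within ``ratio_band`` — the envelope
    expected of C10-C90 lipid species. Strongly correlated pairs with an
    out-of-band ratio are "correlated_non_isotopic" (same molecular class,
    not a 12C/13C pair); everything else is "unrelated".
    """
    if matrix.n_samples < 10:
        raise ValueError("need at least 10 samples for correlation screening")
    offsets = _isotope_offsets(matrix.grid.width, spacing)
    X = matrix.X()
    centers = matrix.bin_mz
    var = X.var(axis=0)
    rows = []
    for offset in offsets:
        idx_a = np.flatnonzero(var[: X.shape[1] - offset] > 0)
        idx_a = idx_a[var[idx_a + offset] > 0]
        for i in idx_a:
            pc = _pair_verdict(
                X[:, i], X[:, i + offset],
                float(centers[i]), float(centers[i + offset]),
                r_min, ratio_band, min_prevalence,
            )
            rows.append(pc)
    return pd.DataFrame(
        [
            {
                "bin_a": pc.bin_a,
                "bin_b": pc.bin_b,
                "pearson_r": pc.pearson_r,
                "median_ratio": pc.median_ratio,
                "prevalence": pc.prevalence,
                "verdict": pc.verdict,
            }
            for pc in rows
        ],
        columns=["bin_a", "bin_b", "pearson_r", "median_ratio", "prevalence", "verdict"],
    )


# ---------------------------------------------------------------------------
# Misclassification annotation

def annotate_misclassified(
    report: ClassificationReport,
    importance: ImportanceReport,
    matrix: FeatureMatrix,
) -> pd.DataFrame:
    """Where misclassified samples sit in the top discriminant bins.

    For every misclassified sample and every displayed top bin, reports the
    sample's intensity, the median of its true class, and whether the
    sample lies above or below that median. Returns an empty table when
    nothing was misclassified.
    """
    if not set(report.predictions.index) <= set(matrix.sample_ids):
        raise ValueError("report refers to samples absent from the matrix")
    cols = ["sample_id", "true", "predicted", "bin_mz", "intensity",
            "class_median", "position"]
    mis = report.misclassified()
    if mis.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for mz in importance.display_bins:
        b = int(matrix.grid.bin_index(np.array([mz]))[0])
        col = matrix.intensities.iloc[:, b]
        true_labels = report.predictions["true"]
        for sid, rec in mis.iterrows():
            cls_samples = true_labels[true_labels == rec["true"]].index
            median = float(col.loc[cls_samples].median())
            val = float(col.loc[sid])
            rows.append(
                {
                    "sample_id": sid,
                    "true": rec["true"],
                    "predicted": rec["predicted"],
                    "bin_mz": mz,
                    "intensity": val,
                    "class_median": median,
                    "position": "above" if val >= median else "below",
                }
            )
    return pd.DataFrame(rows, columns=cols)
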