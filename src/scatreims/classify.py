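"""Fingerprint classification: PCA->LDA and random forests.

Two tracks mirror standard practice for binned ambient-MS fingerprints:
a discriminant-function analysis (LDA on the top principal components) for
visualisation and resubstitution discrimination, and random-forest
classification reported as a row-percentage confusion matrix. The forest
supports three evaluation modes: out-of-bag predictions over all samples
("all_data"), a stratified 70/30 split ("split_70_30"), and prediction of
an entirely held-out population ("holdout_predict").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .spectra import BinGrid


@dataclass
class FeatureMatrix:
    """Per-individual normalised feature vectors plus categorical labels.

    ``intensities`` is samples x bins (columns are m/z labels on the bin
    grid); ``labels`` holds one categorical column per phenotype (class,
    sex, maturity, strain, ...) on the same index.
    """

    intensities: pd.DataFrame
    labels: pd.DataFrame
    grid: BinGrid

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.labels.index):
            raise ValueError("intensities and labels must share the same sample index")
        if self.intensities.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.intensities.shape[1] != self.grid.n_points:
            raise ValueError(
                f"expected {self.grid.n_points} bins, got {self.intensities.shape[1]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def n_samples(self) -> int:
        return len(self.intensities)

    @property
    def bin_mz(self) -> np.ndarray:
        return self.grid.centers()

    def X(self) -> np.ndarray:
        return self.intensities.to_numpy()

    def y(self, target: str) -> pd.Series:
        if target not in self.labels.columns:
            raise KeyError(f"no label column {target!r}")
        return self.labels[target].astype(str)

    def subset(self, sample_ids: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            self.intensities.loc[sample_ids], self.labels.loc[sample_ids], self.grid
        )


@dataclass
class ClassificationReport:
    """Row-percent confusion matrix with per-class and overall accuracy."""

    confusion: pd.DataFrame  # rows: true class, columns: predicted, row %
    per_class_accuracy: pd.Series
    overall_accuracy: float
    mode: str
    seed: int | None
    n: int
    predictions: pd.DataFrame  # index: evaluated samples; columns true, predicted

    def misclassified(self) -> pd.DataFrame:
        p = self.predictions
        return p[p["true"] != p["predicted"]]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "n": self.n,
            "overall_accuracy_percent": self.overall_accuracy,
            "per_class_accuracy_percent": self.per_class_accuracy.to_dict(),
            "confusion_row_percent": {
                cls: row.to_dict() for cls, row in self.confusion.iterrows()
            },
            "predictions": {
                sid: {"true": r["true"], "predicted": r["predicted"]}
                for sid, r in self.predictions.iterrows()
            },
        }


def _build_report(
    y_true: pd.Series,
    y_pred: np.ndarray,
    classes: list[str],
    mode: str,
    seed: int | None,
) -> ClassificationReport:
    counts = confusion_matrix(y_true, y_pred, labels=classes)
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_tot > 0, 100.0 * counts / row_tot, 0.0)
    confusion = pd.DataFrame(pct, index=classes, columns=classes)
    present = row_tot[:, 0] > 0
    per_class = pd.Series(np.diag(pct), index=classes)[
        [c for c, ok in zip(classes, present) if ok]
    ]
    overall = 100.0 * float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))
    predictions = pd.DataFrame(
        {"true": np.asarray(y_true), "predicted": np.asarray(y_pred)},
        index=y_true.index,
    )
    return ClassificationReport(
        confusion=confusion,
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        mode=mode,
        seed=seed,
        n=len(y_true),
        predictions=predictions,
    )


@dataclass
class PcaLdaResult:
    """Discriminant-function analysis of the top principal components."""

    scores: pd.DataFrame  # discriminant coordinates (LD1, LD2, ...)
    class_means: pd.DataFrame
    predictions: pd.DataFrame
    resubstitution_accuracy: float  # percent
    explained_variance_ratio: np.ndarray
    pca: PCA = field(repr=False)
    lda: LinearDiscriminantAnalysis = field(repr=False)


def pca_lda(
    matrix: FeatureMatrix,
    target: str = "class",
    n_components: int = 12,
    scale: bool = False,
) -> PcaLdaResult:
    """Fit PCA on the full matrix, then LDA on the top-PC scores.

    PCA mean-centres each bin; unit-variance scaling is off by default
    because TIC-normalised intensities are already on a common scale.
    Returns per-sample discriminant coordinates (the first two are the
    conventional scatter axes) and the resubstitution classification.
    """
    matrix = matrix.subset(sorted(matrix.sample_ids))
    y = matrix.y(target)
    k = y.nunique()
    if k < 2:
        raise ValueError("need at least two classes for discriminant analysis")
    if matrix.n_samples <= n_components:
        raise ValueError("need more samples than principal components")
    X = matrix.X()
    if scale:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n_components = min(n_components, matrix.n_samples - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=0)
    pcs = pca.fit_transform(X)
    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(pcs, y)
    n_ld = min(k - 1, n_components)
    scores = pd.DataFrame(
        lda.transform(pcs)[:, :n_ld],
        index=matrix.intensities.index,
        columns=[f"LD{i + 1}" for i in range(n_ld)],
    )
    y_pred = lda.predict(pcs)
    class_means = scores.groupby(y).mean()
    report = _build_report(y, y_pred, sorted(y.unique()), "resubstitution", None)
    return PcaLdaResult(
        scores=scores,
        class_means=class_means,
        predictions=report.predictions,
        resubstitution_accuracy=report.overall_accuracy,
        explained_variance_ratio=pca.explained_variance_ratio_,
        pca=pca,
        lda=lda,
    )


def fit_random_forest(
    X: np.ndarray,
    y: pd.Series,
    seed: int,
    n_trees: int = 500,
    oob: bool = True,
) -> RandomForestClassifier:
    """Random forest with the field-standard defaults (500 trees, sqrt mtry)."""
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=oob,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def rf_fit_evaluate(
    matrix: FeatureMatrix,
    target: str = "class",
    mode: str = "all_data",
    seed: int = 0,
    n_trees: int = 500,
) -> tuple[ClassificationReport, RandomForestClassifier]:
    """Random-forest classification in one of the two standard designs.

    ``all_data``: the forest is grown on every sample and the confusion
    matrix uses out-of-bag predictions, the standard all-data error
    estimate (resubstitution would be trivially ~100%). ``split_70_30``:
    stratified random 70/30 split by seed, trained on 70%, confusion on
    the held-out 30%. Samples are sorted by id before fitting, so results
    do not depend on input row order. A single-class matrix yields the
    trivial one-cell confusion matrix.
    """
    matrix = matrix.subset(sorted(matrix.sample_ids))
    y = matrix.y(target)
    classes = sorted(y.unique())
    X = matrix.X()
    if mode == "all_data":
        rf = fit_random_forest(X, y, seed, n_trees, oob=True)
        oob_votes = rf.oob_decision_function_
        if np.isnan(oob_votes).any():
            raise ValueError(
                "some samples were never out of bag; increase n_trees"
            )
        y_pred = rf.classes_[np.argmax(oob_votes, axis=1)]
        return _build_report(y, y_pred, classes, mode, seed), rf
    if mode == "split_70_30":
        counts = y.value_counts()
        if (counts < 5).any():
            raise ValueError("split mode needs >= 5 samples in every class")
        idx_train, idx_test = train_test_split(
            np.arange(len(y)), test_size=0.3, random_state=seed, stratify=y
        )
        rf = fit_random_forest(X[idx_train], y.iloc[idx_train], seed, n_trees, oob=False)
        y_pred = rf.predict(X[idx_test])
        return _build_report(y.iloc[idx_test], y_pred, classes, mode, seed), rf
    raise ValueError(f"unknown mode {mode!r} (use 'all_data' or 'split_70_30')")


def rf_predict_holdout(
    train: FeatureMatrix,
    test: FeatureMatrix,
    target: str = "class",
    seed: int = 0,
    n_trees: int = 500,
) -> tuple[ClassificationReport, RandomForestClassifier]:
    """Train on one population, predict another (e.g. a new trapping site)."""
    if train.grid != test.grid:
        raise ValueError("train and test matrices are on different bin grids")
    train = train.subset(sorted(train.sample_ids))
    test = test.subset(sorted(test.sample_ids))
    y_train, y_test = train.y(target), test.y(target)
    unseen = set(y_test.unique()) - set(y_train.unique())
    if unseen:
        raise ValueError(f"test contains classes absent from training: {sorted(unseen)}")
    rf = fit_random_forest(train.X(), y_train, seed, n_trees, oob=False)
    y_pred = rf.predict(test.X())
    classes = sorted(y_train.unique())
    return _build_report(y_test, y_pred, classes, "holdout_predict", seed), rf
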