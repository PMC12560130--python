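"""Multivariate workflow on fingerprint matrices.

Row-mean standardization (removes the bulk refractive-index shift),
covariance PCA, 50:50 stratified LDA with confusion matrices, and
two-way hierarchical clustering (Euclidean/Ward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage, optimal_leaf_ordering
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .fingerprinting import FingerprintMatrix, METADATA_COLUMNS, SENSOR_COLUMNS


@dataclass
class CenteredMatrix:
    """Fingerprint matrix with each row's own mean subtracted.

    ``centering_log`` records the per-row subtracted mean (nm), so the
    bulk shift each row carried remains auditable.
    """

    frame: pd.DataFrame  # metadata + centred s01..s24
    centering_log: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.frame[SENSOR_COLUMNS].to_numpy(dtype=float)


def row_standardize(matrix: FingerprintMatrix | CenteredMatrix) -> CenteredMatrix:
    """Subtract each row's mean over the 24 sensors from that row.

    This removes the bulk refractive-index contribution (identical on
    every element) while leaving the differential pattern untouched.
    Idempotent; rejects rows with missing entries.
    """
    frame = matrix.frame.copy()
    values = frame[SENSOR_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("rows with missing/non-finite entries cannot be standardized")
    row_means = values.mean(axis=1)
    frame[SENSOR_COLUMNS] = values - row_means[:, None]
    return CenteredMatrix(frame=frame, centering_log=row_means)


def run_pca(
    matrix: FingerprintMatrix | CenteredMatrix, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-mean-centred PCA on the covariance of the 24-sensor data.

    Returns ``(scores, loadings, variance_fractions)`` with
    ``loadings[i]`` the i-th component over sensors.  Sign convention:
    each component's largest-magnitude loading is positive.
    """
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix)
    if values.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    n_components = min(n_components, *values.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(values)
    loadings = pca.components_
    for i in range(n_components):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return scores, loadings, pca.explained_variance_ratio_


def stratified_split(
    matrix: FingerprintMatrix,
    stratify_on: str,
    fraction: float = 0.5,
    seed: int = 0,
) -> tuple[FingerprintMatrix, FingerprintMatrix]:
    """Per-stratum random split; odd strata give the extra row to train.

    Every stratum (unique value of ``stratify_on``) must have >= 2 rows
    so both partitions are populated.  Disjoint and exhaustive.
    """
    frame = matrix.frame
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for _, group in frame.groupby(stratify_on, sort=True):
        if len(group) < 2:
            raise ValueError(
                f"stratum with a single row in {stratify_on!r}; cannot split"
            )
        perm = rng.permutation(group.index.to_numpy())
        n_train = int(np.ceil(fraction * len(perm)))
        train_idx.extend(perm[:n_train])
        val_idx.extend(perm[n_train:])
    train = frame.loc[sorted(train_idx)].reset_index(drop=True)
    val = frame.loc[sorted(val_idx)].reset_index(drop=True)
    return FingerprintMatrix(train), FingerprintMatrix(val)


@dataclass(frozen=True)
class ClassificationReport:
    label_set: tuple[str, ...]
    confusion: np.ndarray  # counts, rows = true label, cols = predicted
    accuracy: float
    split_seed: int
    per_class_recall: dict[str, float]

    @property
    def confusion_percent(self) -> np.ndarray:
        """Row-normalized confusion in percent."""
        totals = self.confusion.sum(axis=1, keepdims=True).astype(float)
        totals[totals == 0] = 1.0
        return 100.0 * self.confusion / totals

    def confusion_frame(self, percent: bool = False) -> pd.DataFrame:
        data = self.confusion_percent if percent else self.confusion
        return pd.DataFrame(data, index=self.label_set, columns=self.label_set)


def lda_classify(
    train: FingerprintMatrix,
    validation: FingerprintMatrix,
    label_column: str = "class_label",
    *,
    split_seed: int = 0,
) -> ClassificationReport:
    """Fit a linear discriminant model on train, report on validation.

    Uses shrinkage-regularized within-class covariance when any class
    has fewer than 3x as many training rows as there are sensors (24-dim
    fingerprints with few replicates are near-singular otherwise).
    """
    y_train = train.frame[label_column].to_numpy()
    y_val = validation.frame[label_column].to_numpy()
    labels = tuple(sorted(set(y_train)))
    if len(labels) < 2:
        raise ValueError("training data must contain at least 2 labels")
    unseen = sorted(set(y_val) - set(labels))
    if unseen:
        raise ValueError(f"validation labels absent from training: {unseen}")

    counts = pd.Series(y_train).value_counts()
    needs_shrinkage = counts.min() < 3 * len(SENSOR_COLUMNS)
    if needs_shrinkage:
        model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    else:
        model = LinearDiscriminantAnalysis(solver="svd")
    model.fit(train.values, y_train)
    predicted = model.predict(validation.values)

    index = {label: i for i, label in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for truth, pred in zip(y_val, predicted):
        confusion[index[truth], index[pred]] += 1
    accuracy = float(np.trace(confusion) / max(1, confusion.sum()))
    recalls = {}
    for label in labels:
        i = index[label]
        total = confusion[i].sum()
        recalls[label] = float(confusion[i, i] / total) if total else float("nan")
    return ClassificationReport(
        label_set=labels,
        confusion=confusion,
        accuracy=accuracy,
        split_seed=split_seed,
        per_class_recall=recalls,
    )


@dataclass
class HCAResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: np.ndarray
    col_order: np.ndarray
    ordered_values: np.ndarray  # heat matrix after both reorderings
    row_labels: list[str]

    def cut_rows(self, k: int) -> np.ndarray:
        """Flat cluster assignment of the rows at k clusters."""
        return fcluster(self.row_linkage, t=k, criterion="maxclust")


def two_way_hca(
    centered: CenteredMatrix, row_label_column: str = "sample_id"
) -> HCAResult:
    """Agglomerative clustering of rows (samples) and columns (sensors).

    Euclidean distance, Ward linkage, leaves ordered by scipy's
    optimal-leaf-ordering for a deterministic heat-map layout.
    """
    values = centered.values
    if values.shape[0] < 3:
        raise ValueError("HCA needs at least 3 rows")
    row_linkage = linkage(values, method="ward")
    col_linkage = linkage(values.T, method="ward")
    row_linkage = optimal_leaf_ordering(row_linkage, values)
    col_linkage = optimal_leaf_ordering(col_linkage, values.T)
    row_order = np.asarray(
        dendrogram(row_linkage, no_plot=True)["leaves"], dtype=int
    )
    col_order = np.asarray(
        dendrogram(col_linkage, no_plot=True)["leaves"], dtype=int
    )
    return HCAResult(
        row_linkage=row_linkage,
        col_linkage=col_linkage,
        row_order=row_order,
        col_order=col_order,
        ordered_values=values[np.ix_(row_order, col_order)],
        row_labels=list(centered.frame[row_label_column].astype(str)),
    )


def cluster_class_purity(
    assignments: np.ndarray, class_labels: np.ndarray | list[str]
) -> float:
    """Majority-class purity of a flat clustering: the fraction of rows
    belonging to their cluster's majority class."""
    frame = pd.DataFrame({"cluster": assignments, "label": list(class_labels)})
    majority = frame.groupby("cluster")["label"].agg(lambda s: s.value_counts().max())
    return float(majority.sum() / len(frame))
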