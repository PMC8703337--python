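"""Seed-group classification: seed-level SVM, pixel-level SVM, 3D CNN.

Three classifiers distinguish the two seed groups (control vs heat
stress, HS = positive class):

* seed-based SVM — one sample per seed (its mean spectrum), PCA-reduced
  to the top components, RBF kernel;
* pixel-based SVM — one sample per seed pixel (its spectrum), RBF kernel,
  with per-seed labels obtained by majority vote over the seed's pixels;
* 3D CNN — one sample per seed pixel, but an S x S x L spatial-spectral
  patch centred on the pixel (see :mod:`seedspectra.cnn`), voted per seed
  the same way.

Dataset bookkeeping follows the two-level protocol: seeds are split 80/20
(stratified by group) into train/test; the pixel-level test set is exactly
the pixels of the test seeds, and the remaining pixels are split 95/5 into
train/validation within each group (training count = floor(0.95 n)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .envi import Hypercube
from .segmentation import SeedMask

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "DatasetSplit",
    "SubCubeSamples",
    "split_dataset",
    "seed_svm_features",
    "train_eval_seed_svm",
    "extract_subcubes",
    "train_pixel_svm",
    "vote_seed_labels",
    "confusion_metrics",
]

CONTROL, HS = 0, 1  # group codes; HS is the positive class throughout


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Accuracy, precision, recall and F-score on [0, 1] scales.

    ``seed_group_prediction_accuracy`` is the fraction of correctly
    labelled seeds; for the seed-level SVM it coincides with ``accuracy``
    (one sample per seed), for pixel-level models it is computed after
    majority voting.
    """

    accuracy: float
    precision: float
    recall: float
    f_score: float
    seed_group_prediction_accuracy: float | None = None


def confusion_metrics(truth, predictions) -> tuple[ConfusionCounts, MetricsReport]:
    """Confusion counts and the four metrics, with HS (=1) as positive.

    accuracy = (TP+TN)/(TP+TN+FP+FN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); F = 2TP/(2TP+FP+FN). Undefined ratios (zero
    denominator) are reported as 0.
    """
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if truth.size == 0:
        raise ValueError("empty label vectors")
    if truth.shape != predictions.shape:
        raise ValueError("truth and prediction vectors must have equal length")
    tp = int(np.sum((truth == HS) & (predictions == HS)))
    tn = int(np.sum((truth == CONTROL) & (predictions == CONTROL)))
    fp = int(np.sum((truth == CONTROL) & (predictions == HS)))
    fn = int(np.sum((truth == HS) & (predictions == CONTROL)))
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return counts, metrics_from_counts(counts)


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    return MetricsReport(
        accuracy=ratio(c.tp + c.tn, c.total),
        precision=ratio(c.tp, c.tp + c.fp),
        recall=ratio(c.tp, c.tp + c.fn),
        f_score=ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


@dataclass
class DatasetSplit:
    """Index bookkeeping for the two-level split (0-based indices).

    ``seed_train``/``seed_test`` index seeds; ``pixel_train`` /
    ``pixel_val`` / ``pixel_test`` index pixel samples. The three pixel
    partitions are disjoint and cover all pixels.
    """

    seed_train: np.ndarray
    seed_test: np.ndarray
    pixel_train: np.ndarray
    pixel_val: np.ndarray
    pixel_test: np.ndarray


def split_dataset(
    seed_groups: np.ndarray,
    pixel_seed_ids: np.ndarray,
    test_fraction: float = 0.2,
    val_fraction: float = 0.05,
    rng_seed: int = 0,
) -> DatasetSplit:
    """Stratified seed split plus the derived pixel split.

    Parameters
    ----------
    seed_groups : array of 0/1
        Group label per seed (index = seed).
    pixel_seed_ids : int array
        For each pixel sample, the (0-based) index of the seed it belongs
        to. Pixels of test seeds form the pixel test set; remaining pixels
        are split train/validation per group with
        ``n_train = floor((1 - val_fraction) * n)``.
    """
    rng = np.random.default_rng(rng_seed)
    seed_groups = np.asarray(seed_groups)
    pixel_seed_ids = np.asarray(pixel_seed_ids)
    if np.any(pixel_seed_ids >= seed_groups.size) or np.any(pixel_seed_ids < 0):
        raise ValueError("pixel sample maps to a seed without a group label")

    seed_train_parts, seed_test_parts = [], []
    for g in (CONTROL, HS):
        idx = np.nonzero(seed_groups == g)[0]
        if idx.size < 2:
            raise ValueError(f"group {g} has {idx.size} seeds; cannot stratify")
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        n_test = min(max(n_test, 1), idx.size - 1)
        seed_test_parts.append(idx[:n_test])
        seed_train_parts.append(idx[n_test:])
    seed_test = np.sort(np.concatenate(seed_test_parts))
    seed_train = np.sort(np.concatenate(seed_train_parts))

    in_test_seed = np.isin(pixel_seed_ids, seed_test)
    pixel_test = np.nonzero(in_test_seed)[0]
    rest = np.nonzero(~in_test_seed)[0]
    pixel_groups = seed_groups[pixel_seed_ids]
    train_parts, val_parts = [], []
    for g in (CONTROL, HS):
        idx = rest[pixel_groups[rest] == g]
        idx = rng.permutation(idx)
        n_train = int(np.floor((1.0 - val_fraction) * idx.size))
        train_parts.append(idx[:n_train])
        val_parts.append(idx[n_train:])
    return DatasetSplit(
        seed_train=seed_train,
        seed_test=seed_test,
        pixel_train=np.sort(np.concatenate(train_parts)),
        pixel_val=np.sort(np.concatenate(val_parts)),
        pixel_test=np.sort(pixel_test),
    )


def seed_svm_features(
    train_spectra: np.ndarray,
    n_components: int = 50,
    test_spectra: np.ndarray | None = None,
) -> tuple[PCA, np.ndarray, np.ndarray | None]:
    """PCA feature extraction fitted on training spectra only.

    Components are ranked by eigenvalue; spectra are centred on the
    training mean (no scaling — reflectance is already on a common scale).
    """
    train_spectra = np.asarray(train_spectra, dtype=float)
    limit = min(train_spectra.shape[0] - 1, train_spectra.shape[1])
    if n_components > limit:
        raise ValueError(f"n_components {n_components} exceeds limit {limit}")
    pca = PCA(n_components=n_components, svd_solver="full")
    train_feat = pca.fit_transform(train_spectra)
    test_feat = pca.transform(np.asarray(test_spectra, dtype=float)) if test_spectra is not None else None
    return pca, train_feat, test_feat


def _fit_rbf_svm(x: np.ndarray, y: np.ndarray) -> SVC:
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    clf = SVC(C=1.0, kernel="rbf", gamma="scale")
    clf.fit(x, y)
    return clf


def train_eval_seed_svm(
    spectra: np.ndarray,
    seed_groups: np.ndarray,
    split: DatasetSplit,
    n_components: int = 50,
) -> tuple[MetricsReport, np.ndarray]:
    """Fit the seed-level RBF SVM on PCA features; evaluate on test seeds.

    Returns the metrics report (with seed_group_prediction_accuracy equal
    to accuracy, one sample per seed) and the per-test-seed predictions.
    """
    spectra = np.asarray(spectra, dtype=float)
    n_components = min(n_components, split.seed_train.size - 1, spectra.shape[1])
    _, train_feat, test_feat = seed_svm_features(
        spectra[split.seed_train], n_components, spectra[split.seed_test]
    )
    clf = _fit_rbf_svm(train_feat, seed_groups[split.seed_train])
    pred = clf.predict(test_feat)
    _, report = confusion_metrics(seed_groups[split.seed_test], pred)
    report.seed_group_prediction_accuracy = report.accuracy
    return report, pred


@dataclass
class SubCubeSamples:
    """All S x S x L patches of a scene's seed pixels, stacked.

    One sample per seed pixel; each patch is labelled by its centre
    pixel's seed group. Border patches are completed by edge-reflection
    padding of the cube.
    """

    patches: np.ndarray  # (n, S, S, L)
    centers: np.ndarray  # (n, 2) as (row, col)
    seed_ids: np.ndarray  # (n,) 0-based seed index
    patch_size: int

    def __len__(self) -> int:
        return self.patches.shape[0]

    @property
    def center_spectra(self) -> np.ndarray:
        """Spectrum of each sample's centre pixel (the pixel-SVM feature)."""
        h = self.patch_size // 2
        return self.patches[:, h, h, :]


def extract_subcubes(cube: Hypercube, masks: SeedMask, patch_size: int = 5) -> SubCubeSamples:
    """Extract one S x S x L patch per seed pixel (S odd, reflect-padded)."""
    if patch_size % 2 == 0:
        raise ValueError("patch_size must be odd")
    h = patch_size // 2
    if patch_size > min(cube.n_lines, cube.n_samples):
        raise ValueError("patch_size exceeds image extent")
    padded = np.pad(cube.data, ((h, h), (h, h), (0, 0)), mode="reflect")
    rows, cols = np.nonzero(masks.labels > 0)
    n = rows.size
    patches = np.empty((n, patch_size, patch_size, cube.n_bands), dtype=float)
    for i in range(n):
        r, c = rows[i], cols[i]
        patches[i] = padded[r : r + patch_size, c : c + patch_size, :]
    return SubCubeSamples(
        patches=patches,
        centers=np.column_stack([rows, cols]),
        seed_ids=masks.labels[rows, cols].astype(int) - 1,
        patch_size=patch_size,
    )


def train_pixel_svm(
    samples: SubCubeSamples,
    seed_groups: np.ndarray,
    split: DatasetSplit,
    max_train: int | None = 20000,
    rng_seed: int = 0,
) -> np.ndarray:
    """RBF SVM on centre-pixel spectra (no spatial context).

    Returns predictions for all pixel test samples, in ``split.pixel_test``
    order. Training pixels beyond *max_train* are subsampled (seeded) to
    bound the quadratic kernel cost.
    """
    x = samples.center_spectra
    y = seed_groups[samples.seed_ids]
    train_idx = split.pixel_train
    if max_train is not None and train_idx.size > max_train:
        rng = np.random.default_rng(rng_seed)
        train_idx = rng.choice(train_idx, size=max_train, replace=False)
    clf = _fit_rbf_svm(x[train_idx], y[train_idx])
    return clf.predict(x[split.pixel_test])


def vote_seed_labels(
    pixel_predictions: np.ndarray,
    pixel_seed_ids: np.ndarray,
    seed_indices: np.ndarray | None = None,
) -> dict[int, int]:
    """Aggregate per-pixel predictions to per-seed labels by majority.

    A seed is control iff strictly more than half of its predicted pixels
    are control; otherwise (including an exact tie) it is HS. Invariant to
    pixel ordering. Raises if a requested seed has no predicted pixels.
    """
    pixel_predictions = np.asarray(pixel_predictions)
    pixel_seed_ids = np.asarray(pixel_seed_ids)
    if seed_indices is None:
        seed_indices = np.unique(pixel_seed_ids)
    out: dict[int, int] = {}
    for s in seed_indices:
        sel = pixel_seed_ids == s
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"seed {s} has no predicted pixels")
        n_control = int(np.sum(pixel_predictions[sel] == CONTROL))
        out[int(s)] = CONTROL if n_control > n / 2 else HS
    return out
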