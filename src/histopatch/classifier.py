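"""Tiling, feature assembly, memory-cell classification, and evaluation.

Tiles are the classification unit. Each tile is described by the
concatenation of its flattened autocorrelogram (spatial color coherence)
and its low-band graph-frequency energies (nonlocal texture), min-max
normalized per feature with training-set statistics so that Euclidean
distances, divided by sqrt(dim), live in [0, 1] ("affinity").

Classification is immune-inspired nearest-prototype: training examples
("antigens") are presented sequentially; an example farther than the
global affinity threshold — the mean pairwise affinity over the training
set — from every same-label prototype founds a new memory cell, otherwise
it stimulates its nearest same-label cell and pulls it toward itself by a
running mean ("area growth"). At capacity the least-stimulated cell is
replaced (never the sole cell of a class). A query takes the label of its
nearest cell; the malignancy score ``d_benign / (d_benign + d_malignant)``
(distances to the nearest cell of each class) is used for ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .correlogram import correlogram, quantize_colors
from .reliability import luminance
from .spectral import (
    build_laplacian,
    extract_patches,
    graph_frequency_energy,
    nonlocal_kernel,
    spectral_basis,
)
from .synthetic import BENIGN, MALIGNANT


@dataclass
class FeatureConfig:
    """Parameters of the per-tile feature vector.

    ``m_colors`` quantized colors and ``d_set`` ring distances for the
    autocorrelogram block (length ``m_colors * len(d_set)``); ``patch_side``,
    ``sample_cap``, ``sigma`` and ``k_bands`` for the graph-spectral block
    (length ``k_bands``). ``sigma=None`` uses the median-distance heuristic.
    """

    m_colors: int = 64
    d_set: tuple[int, ...] = (1, 3, 5, 7)
    patch_side: int = 5
    k_bands: int = 8
    sample_cap: int = 256
    sigma: float | None = None
    seed: int = 0

    @property
    def n_features(self) -> int:
        return self.m_colors * len(self.d_set) + self.k_bands


@dataclass
class TileGrid:
    """Row-major tiling of an image; ``tiles[i] = (row, col, window)``."""

    tile_side: int
    stride: int
    tiles: list

    def __len__(self) -> int:
        return len(self.tiles)


def tile_image(image: np.ndarray, tile_side: int, stride: int | None = None) -> TileGrid:
    """Deterministic row-major tiling with half-open windows."""
    if stride is None:
        stride = tile_side
    if stride <= 0:
        raise ValueError(f"stride must be > 0, got {stride}")
    h, w = image.shape[:2]
    if tile_side > min(h, w):
        raise ValueError(f"tile_side {tile_side} exceeds image extent {(h, w)}")
    tiles = []
    for r in range(0, h - tile_side + 1, stride):
        for c in range(0, w - tile_side + 1, stride):
            tiles.append((r, c, image[r:r + tile_side, c:c + tile_side]))
    return TileGrid(tile_side=tile_side, stride=stride, tiles=tiles)


def tile_features(tile: np.ndarray, config: FeatureConfig | None = None) -> np.ndarray:
    """Raw (unnormalized) feature vector of one tile.

    Concatenates the flattened autocorrelogram with the graph-frequency
    energies of the tile's luminance. A constant tile is well defined: its
    autocorrelogram concentrates on the single occupied color and all
    spectral energy sits in band 0.
    """
    if config is None:
        config = FeatureConfig()
    q = quantize_colors(tile, config.m_colors, seed=config.seed)
    ac = correlogram(q, config.d_set).ac.ravel()

    lum = luminance(tile)
    patches = extract_patches(lum, config.patch_side)
    graph = nonlocal_kernel(
        patches, sigma=config.sigma, sample_cap=config.sample_cap, seed=config.seed
    )
    build_laplacian(graph)
    spectral_basis(graph)
    energies = graph_frequency_energy(lum, graph, config.k_bands)
    return np.concatenate([ac, energies])


@dataclass
class FeatureNormalizer:
    """Per-feature min-max scaling fitted on the training matrix."""

    lo: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureNormalizer":
        lo = X.min(axis=0)
        scale = X.max(axis=0) - lo
        return cls(lo=lo, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.divide(
            X - self.lo, self.scale,
            out=np.zeros_like(X), where=self.scale > 0,
        )
        return np.clip(out, 0.0, 1.0)


def affinity(u: np.ndarray, v: np.ndarray) -> float:
    """Normalized Euclidean distance between [0,1]-features; lies in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return float(np.linalg.norm(u - v) / np.sqrt(u.size))


def similarity_threshold(features: np.ndarray) -> float:
    """Mean pairwise affinity over all feature vectors (n(n-1)/2 pairs)."""
    X = np.asarray(features, dtype=float)
    n = len(X)
    if n < 2:
        raise ValueError(f"need at least 2 vectors, got {n}")
    from scipy.spatial.distance import pdist

    return float(pdist(X).mean() / np.sqrt(X.shape[1]))


@dataclass
class MemoryCellSet:
    """Labeled prototypes with stimulation counts and the training context."""

    cells: np.ndarray  # (K, F)
    labels: np.ndarray  # (K,)
    stimulation: np.ndarray  # (K,)
    threshold: float
    normalizer: FeatureNormalizer | None = None
    feature_config: FeatureConfig | None = None


def train_memory_cells(
    features: np.ndarray,
    labels: np.ndarray,
    capacity: int = 32,
    seed: int = 0,
    threshold: float | None = None,
    normalizer: FeatureNormalizer | None = None,
    feature_config: FeatureConfig | None = None,
) -> MemoryCellSet:
    """Grow the memory-cell set from normalized training features.

    Presentation order is a seeded shuffle. A candidate farther than the
    affinity threshold from every same-label cell is placed as a new cell
    (stimulation 1); otherwise its nearest same-label cell (lowest index on
    ties) gains one stimulation and moves toward the candidate by
    ``1/stimulation`` — a running mean over everything the cell absorbed.
    When placement would exceed ``capacity``, the least-stimulated cell is
    replaced, except a class's last cell, which is never evicted.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, F) with matching labels")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires at least one example per class")
    if threshold is None:
        threshold = similarity_threshold(X)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))

    cells: list[np.ndarray] = []
    cl_labels: list[int] = []
    stim: list[int] = []

    for i in order:
        f, lab = X[i], int(y[i])
        same = [j for j, l in enumerate(cl_labels) if l == lab]
        if same:
            dists = [affinity(f, cells[j]) for j in same]
            jbest = same[int(np.argmin(dists))]
            dbest = min(dists)
        else:
            jbest, dbest = -1, np.inf

        if dbest > threshold:
            if len(cells) >= capacity:
                # Replace the least-stimulated cell, sparing sole class members.
                counts = {c: cl_labels.count(c) for c in set(cl_labels)}
                cand = [
                    j for j in range(len(cells))
                    if counts[cl_labels[j]] > 1 or cl_labels[j] == lab
                ]
                victim = min(cand, key=lambda j: (stim[j], j))
                cells[victim] = f.copy()
                cl_labels[victim] = lab
                stim[victim] = 1
            else:
                cells.append(f.copy())
                cl_labels.append(lab)
                stim.append(1)
        else:
            stim[jbest] += 1
            cells[jbest] = cells[jbest] + (f - cells[jbest]) / stim[jbest]

    return MemoryCellSet(
        cells=np.array(cells),
        labels=np.array(cl_labels, dtype=int),
        stimulation=np.array(stim, dtype=int),
        threshold=float(threshold),
        normalizer=normalizer,
        feature_config=feature_config,
    )


def classify(cells: MemoryCellSet, feature: np.ndarray) -> tuple[int, float]:
    """Label of the nearest cell plus a malignancy score in [0, 1].

    The score is ``d_b / (d_b + d_m)`` with ``d_b``/``d_m`` the affinities
    to the nearest benign/malignant cell; 1 means on top of a malignant
    prototype, 0.5 means equidistant. Ties in the nearest-cell search go to
    the lowest cell index.
    """
    if len(cells.cells) == 0:
        raise ValueError("empty memory-cell set")
    f = np.asarray(feature, dtype=float).ravel()
    d = np.linalg.norm(cells.cells - f, axis=1) / np.sqrt(f.size)
    label = int(cells.labels[int(np.argmin(d))])
    d_b = d[cells.labels == BENIGN].min() if (cells.labels == BENIGN).any() else np.inf
    d_m = d[cells.labels == MALIGNANT].min() if (cells.labels == MALIGNANT).any() else np.inf
    if not np.isfinite(d_b):
        score = 1.0
    elif not np.isfinite(d_m):
        score = 0.0
    elif d_b + d_m == 0:
        score = 0.5
    else:
        score = float(d_b / (d_b + d_m))
    return label, score


def classify_batch(cells: MemoryCellSet, features: np.ndarray):
    """Vector of labels and scores for a feature matrix."""
    out = [classify(cells, f) for f in np.atleast_2d(features)]
    labels = np.array([p[0] for p in out], dtype=int)
    scores = np.array([p[1] for p in out], dtype=float)
    return labels, scores


def score_heatmap(
    image: np.ndarray,
    cells: MemoryCellSet,
    tile_side: int = 32,
    stride: int | None = None,
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Per-tile malignancy scores painted into image coordinates.

    Overlapping tiles are averaged; uncovered border pixels (when stride
    does not tile exactly) are 0. Values lie in [0, 1] by construction of
    the score, so an identical-tiles image maps to a constant heatmap.
    """
    cfg = config or cells.feature_config or FeatureConfig()
    grid = tile_image(image, tile_side, stride)
    acc = np.zeros(image.shape[:2])
    cnt = np.zeros(image.shape[:2])
    for r, c, win in grid.tiles:
        f = tile_features(win, cfg)
        if cells.normalizer is not None:
            f = cells.normalizer.transform(f)[0]
        _, s = classify(cells, f)
        acc[r:r + tile_side, c:c + tile_side] += s
        cnt[r:r + tile_side, c:c + tile_side] += 1.0
    return np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)


@dataclass
class MetricsReport:
    """Confusion-based metrics plus the ROC curve.

    ``auc`` is None when only one class is present in the labels (the ROC
    is undefined there). The positive class is malignant (1).
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    confusion: dict

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "confusion": self.confusion,
        }


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """AUC via the midrank (Mann-Whitney) statistic; None for one class.

    Equals the probability that a random positive outscores a random
    negative, with ties counted half — identical to trapezoidal ROC
    integration.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(
    predictions: np.ndarray, scores: np.ndarray, labels: np.ndarray
) -> MetricsReport:
    """Standard two-class metrics with malignant (1) as the positive class."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    s = np.asarray(scores, dtype=float)
    if not (len(y) == len(p) == len(s)):
        raise ValueError("predictions, scores and labels must have equal length")

    tp = int(((p == 1) & (y == 1)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())

    accuracy = (tp + tn) / len(y)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0

    auc = auc_rank(s, y)
    if auc is not None:
        from sklearn.metrics import roc_curve

        fpr, tpr, _ = roc_curve(y, s)
    else:
        fpr = tpr = np.array([])

    return MetricsReport(
        accuracy=float(accuracy), precision=float(precision),
        recall=float(recall), f1=float(f1), auc=auc,
        roc_fpr=fpr, roc_tpr=tpr,
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    )


def split_dataset(
    labels: np.ndarray, train_fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified split; returns (train_idx, test_idx).

    Per-class training counts are apportioned by largest remainder so the
    total matches ``round(n * train_fraction)`` while class proportions are
    preserved within rounding.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 members to split")

    total_train = int(round(len(y) * train_fraction))
    quotas = counts * train_fraction
    base = np.floor(quotas).astype(int)
    remainder = quotas - base
    short = total_train - base.sum()
    # Hand leftover slots to the classes with the largest remainders.
    for ci in np.argsort(-remainder, kind="stable")[:short]:
        base[ci] += 1

    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls, n_train in zip(classes, base):
        idx = np.nonzero(y == cls)[0]
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))
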