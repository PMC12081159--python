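"""Color quantization and correlogram/autocorrelogram descriptors.

The color correlogram of an image quantized to ``m`` colors is the table

    gamma[i, j, k] = Pr( color(p2) = c_j | color(p1) = c_i, ||p1 - p2||_inf = k )

over all ordered pixel pairs at exact chessboard (L-infinity) distance
``k``; the autocorrelogram keeps only the diagonal ``gamma[i, i, k]`` —
the probability that a color co-occurs with itself at distance ``k`` —
which captures spatial color coherence in O(m d) space. Pairs whose second
pixel would fall outside the image are excluded from both numerator and
denominator, so boundary effects do not bias the probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def linf_distance(p1, p2) -> int:
    """Chessboard (L-infinity) distance between two pixel coordinates."""
    (y1, x1), (y2, x2) = p1, p2
    return int(max(abs(y1 - y2), abs(x1 - x2)))


@dataclass
class QuantizedImage:
    """Integer label raster plus the quantized palette.

    Labels are 0-based in ``{0..m-1}``; ``palette`` holds the m quantized
    colors (bin centers or cluster centroids) as rows.
    """

    labels: np.ndarray
    m: int
    palette: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class CorrelogramTable:
    """Correlogram probabilities with the raw pair counts and histogram."""

    gamma: np.ndarray  # (m, m, |d_set|) conditional probabilities
    counts: np.ndarray  # (m, m, |d_set|) raw ordered-pair counts
    h: np.ndarray  # (m,) pixel counts per color
    d_set: tuple[int, ...]

    @property
    def ac(self) -> np.ndarray:
        """Autocorrelogram slice: ``ac[i, k] = gamma[i, i, k]``, shape (m, |d|)."""
        m = self.gamma.shape[0]
        return self.gamma[np.arange(m), np.arange(m), :]


def quantize_colors(image: np.ndarray, m: int, seed: int = 0) -> QuantizedImage:
    """Quantize an image into ``m`` colors deterministically.

    For RGB input with ``m`` a perfect cube, uniform per-channel binning
    into ``m**(1/3)`` levels per channel is used (the classical choice);
    otherwise a seeded k-means assignment. Grayscale input gets ``m``
    uniform intensity bins.
    """
    if m < 2:
        raise ValueError(f"m must be >= 2, got {m}")
    arr = np.asarray(image, dtype=float)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        arr = arr / 255.0
    arr = np.clip(arr, 0.0, 1.0)

    if arr.ndim == 2:
        bins = np.minimum((arr * m).astype(int), m - 1)
        centers = ((np.arange(m) + 0.5) / m)[:, None]
        return QuantizedImage(labels=bins, m=m, palette=centers)

    b = round(m ** (1 / 3))
    if b**3 == m:
        idx = np.minimum((arr * b).astype(int), b - 1)
        labels = (idx[..., 0] * b + idx[..., 1]) * b + idx[..., 2]
        lv = (np.arange(b) + 0.5) / b
        palette = np.stack(np.meshgrid(lv, lv, lv, indexing="ij"), axis=-1).reshape(-1, 3)
        return QuantizedImage(labels=labels, m=m, palette=palette)

    from sklearn.cluster import KMeans

    flat = arr.reshape(-1, arr.shape[-1])
    km = KMeans(n_clusters=m, n_init=1, random_state=seed).fit(flat)
    return QuantizedImage(
        labels=km.labels_.reshape(arr.shape[:2]), m=m, palette=km.cluster_centers_
    )


def color_histogram(q: QuantizedImage) -> np.ndarray:
    """Pixel counts per quantized color; sums to the pixel count of the image."""
    return np.bincount(q.labels.ravel(), minlength=q.m)


def _ring_offsets(k: int) -> list[tuple[int, int]]:
    """All (dy, dx) with chessboard norm exactly k (the square ring), 8k offsets."""
    offs = []
    for dy in range(-k, k + 1):
        for dx in range(-k, k + 1):
            if max(abs(dy), abs(dx)) == k:
                offs.append((dy, dx))
    return offs


def correlogram(q: QuantizedImage, d_set=(1, 3, 5, 7)) -> CorrelogramTable:
    """Correlogram over the given distance set by shifted-array pair counting.

    For each ``k`` the ordered pairs are enumerated through the 8k offsets
    of the distance-``k`` square ring, restricted to in-image positions.
    Rows of colors absent from the image (or with an empty ring) are zero.
    """
    d_set = tuple(int(k) for k in d_set)
    if any(k < 1 for k in d_set):
        raise ValueError(f"all distances must be >= 1, got {d_set}")
    labels = q.labels
    h_img, w_img = labels.shape
    m = q.m
    counts = np.zeros((m, m, len(d_set)), dtype=np.int64)

    for ki, k in enumerate(d_set):
        for dy, dx in _ring_offsets(k):
            y0, y1 = max(0, -dy), min(h_img, h_img - dy)
            x0, x1 = max(0, -dx), min(w_img, w_img - dx)
            if y0 >= y1 or x0 >= x1:
                continue
            la = labels[y0:y1, x0:x1].ravel()
            lb = labels[y0 + dy:y1 + dy, x0 + dx:x1 + dx].ravel()
            counts[:, :, ki] += np.bincount(
                la * m + lb, minlength=m * m
            ).reshape(m, m)

    row = counts.sum(axis=1, keepdims=True)
    gamma = np.divide(counts, row, out=np.zeros(counts.shape), where=row > 0)
    return CorrelogramTable(gamma=gamma, counts=counts, h=color_histogram(q), d_set=d_set)


def autocorrelogram(table: CorrelogramTable) -> np.ndarray:
    """The diagonal slice of the correlogram, shape ``(m, |d_set|)``."""
    return table.ac


def correlogram_bruteforce(q: QuantizedImage, d_set=(1, 2)) -> np.ndarray:
    """O(n^4) all-pairs enumeration of the correlogram (reference oracle).

    Loops over every ordered pixel pair, tallying those at exact chessboard
    distance ``k``. Deliberately naive and structurally independent of
    :func:`correlogram`; intended for small images only.
    """
    d_set = tuple(int(k) for k in d_set)
    labels = q.labels
    h_img, w_img = labels.shape
    m = q.m
    counts = np.zeros((m, m, len(d_set)), dtype=np.int64)
    kpos = {k: i for i, k in enumerate(d_set)}
    for y1 in range(h_img):
        for x1 in range(w_img):
            for y2 in range(h_img):
                for x2 in range(w_img):
                    k = max(abs(y1 - y2), abs(x1 - x2))
                    if k in kpos:
                        counts[labels[y1, x1], labels[y2, x2], kpos[k]] += 1
    row = counts.sum(axis=1, keepdims=True)
    return np.divide(counts, row, out=np.zeros(counts.shape), where=row > 0)
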