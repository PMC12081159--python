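"""Initial interpolation and the reliable/unreliable pixel partition.

The filtering scheme treats a scalar working channel ``D`` alongside its
color guidance ``I`` (the "guided image" pairing familiar from guided depth
upsampling). On plain histology RGB input the working channel is luminance.
A pixel is *unreliable* when the max-min spread of ``D`` inside its
reference window exceeds a threshold ``tau``; a first-order edge refinement
then rescues fine-detail pixels whose directional derivative exhibits a
zero crossing (thin ridges), since those are genuine structure rather than
interpolation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: Rec. 601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])


def luminance(image: np.ndarray) -> np.ndarray:
    """Luminance (0.299 R + 0.587 G + 0.114 B) of an RGB raster.

    Accepts uint8 (rescaled to [0, 1]) or float input; grayscale input is
    passed through as float.
    """
    arr = np.asarray(image, dtype=float)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        arr = arr / 255.0
    if arr.ndim == 2:
        return arr
    return arr @ _LUMA


@dataclass
class GuidedImage:
    """Color guidance raster ``I`` and scalar working raster ``D`` on one grid."""

    I: np.ndarray  # noqa: E741 - field name from the guided-filter convention
    D: np.ndarray

    def __post_init__(self) -> None:
        if self.I.shape[:2] != self.D.shape:
            raise ValueError(
                f"guidance {self.I.shape[:2]} and working raster {self.D.shape} "
                "must share a grid"
            )
        if not (np.isfinite(self.I).all() and np.isfinite(self.D).all()):
            raise ValueError("guided image contains non-finite values")

    @classmethod
    def from_rgb(cls, image: np.ndarray) -> "GuidedImage":
        """Build from an RGB (or grayscale) raster: I normalized, D = luminance."""
        arr = np.asarray(image, dtype=float)
        if np.issubdtype(np.asarray(image).dtype, np.integer):
            arr = arr / 255.0
        return cls(I=arr, D=luminance(image))


@dataclass
class ReliabilityMask:
    """Boolean raster (True = reliable) with the detection parameters."""

    mask: np.ndarray
    tau: float
    window_radius: int


def init_upsample(low_res: np.ndarray, factor: int, method: str = "bilinear") -> np.ndarray:
    """Upsample by an integer factor with separable interpolation.

    Output pixel ``i`` samples the input at coordinate
    ``i * (n_in - 1) / (n_out - 1)`` (corner-aligned grid), interpolated
    bilinearly (``order=1``) or by cubic spline for ``method='bicubic'``.
    Bilinear is the default used to build the working channel for the
    filter; bicubic is offered for the initial prototype map.
    """
    orders = {"bilinear": 1, "bicubic": 3}
    if method not in orders:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(orders)}")
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    arr = np.asarray(low_res, dtype=float)
    if factor == 1:
        return arr.copy()

    h, w = arr.shape[:2]
    oh, ow = h * factor, w * factor
    rows = np.linspace(0.0, h - 1, oh) if oh > 1 else np.zeros(1)
    cols = np.linspace(0.0, w - 1, ow) if ow > 1 else np.zeros(1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()])

    def _interp(chan: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            chan, coords, order=orders[method], mode="nearest"
        ).reshape(oh, ow)

    if arr.ndim == 2:
        return _interp(arr)
    return np.stack([_interp(arr[..., c]) for c in range(arr.shape[2])], axis=-1)


def detect_unreliable(
    D: np.ndarray, window_radius: int = 1, tau: float = 0.1
) -> ReliabilityMask:
    """Flag pixels whose windowed max-min spread exceeds ``tau``.

    The reference window is the ``(2r+1)^2`` square centered on each pixel,
    clipped at the image border (no padded values are invented: replicated
    border samples coincide with in-window pixels, so the clipped extrema
    are exact).
    """
    if window_radius < 1:
        raise ValueError(f"window_radius must be >= 1, got {window_radius}")
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    arr = np.asarray(D, dtype=float)
    size = 2 * window_radius + 1
    spread = ndimage.maximum_filter(arr, size=size, mode="nearest") - \
        ndimage.minimum_filter(arr, size=size, mode="nearest")
    return ReliabilityMask(mask=spread <= tau, tau=tau, window_radius=window_radius)


def refine_with_edge_filter(mask: ReliabilityMask, D: np.ndarray) -> ReliabilityMask:
    """Restore fine-detail pixels to reliable via first-order zero crossings.

    A pixel is kept reliable when the central-difference gradient of ``D``
    changes sign across it along either axis (a one-pixel ridge or valley:
    the derivative crosses zero at the feature). Refinement only ever turns
    unreliable pixels reliable, never the reverse.
    """
    arr = np.asarray(D, dtype=float)
    gy, gx = np.gradient(arr)

    zc = np.zeros(arr.shape, dtype=bool)
    # Sign change of the horizontal derivative across the pixel.
    zc[:, 1:-1] |= (gx[:, :-2] > 0) & (gx[:, 2:] < 0)
    zc[:, 1:-1] |= (gx[:, :-2] < 0) & (gx[:, 2:] > 0)
    # Sign change of the vertical derivative across the pixel.
    zc[1:-1, :] |= (gy[:-2, :] > 0) & (gy[2:, :] < 0)
    zc[1:-1, :] |= (gy[:-2, :] < 0) & (gy[2:, :] > 0)

    return ReliabilityMask(
        mask=mask.mask | zc, tau=mask.tau, window_radius=mask.window_radius
    )
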