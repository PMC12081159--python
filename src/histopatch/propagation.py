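"""Geodesic ordering, directional confidence, and the ordered filter.

Unreliable pixels are repaired in waves: the chessboard distance transform
``T`` to the reliable set fixes the processing order (iteration ``t``
handles exactly the pixels with ``T = t``), so pixels filtered in earlier
waves feed later ones. Each pixel carries a two-slot confidence pair
``[C(x; +grad T), C(x; -grad T)]`` — trust in the information arriving
along and against the propagation front. Confidence decays by the factor
``a`` per propagation hop and is attenuated by two pairwise consistency
weights:

* ``B(x, y) = exp(-gamma_I ||I_x - I_y||^2) * exp(-gamma_D (D_x - D_y)^2)``
  — photometric/working-channel consistency;
* ``G(x, y) = max(cos(angle(dir_x, dir_y)), delta)`` — boundary-normal
  consistency, floored at ``delta``.

With ``gamma_I = gamma_D = 0`` and ``delta = 1`` every weight collapses to
the confidence itself and the scheme reduces to pure distance-decayed
averaging with ``C(x) = a^T(x)`` — a useful closed-form cross-check.

Reliable pixels are never modified; their confidence pair is ``[1, 0]``
(full trust flowing outward along ``+grad T``, none backward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .reliability import GuidedImage, ReliabilityMask

#: 8-connected neighbor offsets, raster-scan order.
NEIGHBOR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass
class PropagationParams:
    """Tunables of the confidence-propagation filter.

    ``a`` is the per-hop confidence decay in [0, 1); ``gamma_i`` and
    ``gamma_d`` are the inverse-square bandwidths of the color and
    working-channel consistency terms (defaults (0.1)^-2 and (0.01)^-2);
    ``delta`` floors the direction-consistency weight.
    """

    a: float = 0.8
    gamma_i: float = 100.0
    gamma_d: float = 1.0e4
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.a < 1.0:
            raise ValueError(f"decay a must be in [0, 1), got {self.a}")
        if self.gamma_i < 0 or self.gamma_d < 0:
            raise ValueError("gamma_i and gamma_d must be >= 0")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")


@dataclass
class OrderField:
    """Propagation order: distance map ``T``, its unit gradient, reliability."""

    T: np.ndarray  # int raster; 0 exactly on reliable pixels
    dir_plus: np.ndarray  # (H, W, 2) unit (row, col) direction of increasing T
    reliable: np.ndarray  # bool raster

    @property
    def n_steps(self) -> int:
        return int(self.T.max())


@dataclass
class ConfidenceField:
    """Two-direction confidence per pixel, plus the parameters used."""

    c_plus: np.ndarray  # C(x; +grad T)
    c_minus: np.ndarray  # C(x; -grad T)
    params: PropagationParams


def pair_weight_B(i_x, i_y, d_x: float, d_y: float,
                  gamma_i: float, gamma_d: float) -> float:
    """Photometric consistency weight between two pixels, in (0, 1]."""
    if gamma_i < 0 or gamma_d < 0:
        raise ValueError("gamma_i and gamma_d must be >= 0")
    di2 = float(np.sum((np.asarray(i_x, dtype=float) - np.asarray(i_y, dtype=float)) ** 2))
    return float(np.exp(-gamma_i * di2) * np.exp(-gamma_d * (d_x - d_y) ** 2))


def pair_weight_G(dir_x, dir_y, delta: float = 0.0) -> float:
    """Direction consistency: cosine between the two normals, floored at delta."""
    vx = np.asarray(dir_x, dtype=float)
    vy = np.asarray(dir_y, dtype=float)
    nx, ny = np.linalg.norm(vx), np.linalg.norm(vy)
    if nx == 0 or ny == 0:
        raise ValueError("direction vectors must be nonzero")
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    return float(max(vx @ vy / (nx * ny), delta))


def compute_order_field(mask: ReliabilityMask) -> OrderField:
    """Chessboard distance to the reliable set and the propagation direction.

    ``T`` is the 8-neighbor (chessboard) distance transform, so every
    unreliable pixel sits exactly one step above the minimum of its
    neighborhood and iteration ``t`` of the filter processes the level set
    ``T = t``. The direction field is the unit gradient of ``T`` (central
    differences); where it vanishes it falls back to the direction of
    increasing distance — away from the nearest reliable pixel for
    unreliable ones, toward the nearest unreliable pixel for reliable ones.
    """
    reliable = np.asarray(mask.mask, dtype=bool)
    if not reliable.any():
        raise ValueError("propagation requires at least one reliable pixel")
    unreliable = ~reliable

    T = ndimage.distance_transform_cdt(unreliable, metric="chessboard").astype(int)

    Tf = T.astype(float)
    gy = np.gradient(Tf, axis=0) if T.shape[0] > 1 else np.zeros_like(Tf)
    gx = np.gradient(Tf, axis=1) if T.shape[1] > 1 else np.zeros_like(Tf)
    dirs = np.stack([gy, gx], axis=-1)
    norms = np.linalg.norm(dirs, axis=-1)

    fallback = np.zeros_like(dirs)
    h, w = T.shape
    pos = np.stack(np.mgrid[0:h, 0:w], axis=-1).astype(float)
    if unreliable.any():
        # Unreliable pixels: point away from the nearest reliable pixel.
        idx = ndimage.distance_transform_edt(
            unreliable, return_indices=True, return_distances=False
        )
        nearest = np.stack([idx[0], idx[1]], axis=-1).astype(float)
        fallback[unreliable] = (pos - nearest)[unreliable]
        # Reliable pixels: point toward the nearest unreliable pixel.
        idx_r = ndimage.distance_transform_edt(
            reliable, return_indices=True, return_distances=False
        )
        nearest_u = np.stack([idx_r[0], idx_r[1]], axis=-1).astype(float)
        fallback[reliable] = (nearest_u - pos)[reliable]
    fb_norms = np.linalg.norm(fallback, axis=-1)
    use_fb = (norms == 0) & (fb_norms > 0)
    dirs[use_fb] = fallback[use_fb] / fb_norms[use_fb, None]
    ok = norms > 0
    dirs[ok] /= norms[ok, None]
    # Degenerate (all-reliable image): any unit vector will do, it is unused.
    still = np.linalg.norm(dirs, axis=-1) == 0
    dirs[still] = (0.0, 1.0)

    return OrderField(T=T, dir_plus=dirs, reliable=reliable)


def _guidance_channels(guided: GuidedImage) -> np.ndarray:
    I = np.asarray(guided.I, dtype=float)
    return I[..., None] if I.ndim == 2 else I


def _neighbor_view(ys, xs, di, dj, shape):
    """Indices of the (di, dj) neighbors plus the in-bounds selector."""
    ny, nx = ys + di, xs + dj
    ok = (ny >= 0) & (ny < shape[0]) & (nx >= 0) & (nx < shape[1])
    return ny, nx, ok


def propagate_confidence(
    order: OrderField, guided: GuidedImage, params: PropagationParams | None = None
) -> ConfidenceField:
    """Carry directional confidence from the reliable set into unreliable pixels.

    Pixels are processed level set by level set in increasing ``T``. For
    each direction slot ``s grad T(x)`` the confidence is the
    ``B*G``-normalized average over already-processed 8-neighbors of their
    (direction-matched) confidence, decayed by ``a`` per hop::

        C(x; s) = sum_y a^(T(x)-T(y)) B(x,y) G(s_x, d_y) C(y; d_y) / sum_y B G

    A neighbor's slot ``d_y`` is the one of its two directions aligned with
    the slot being computed (reliable neighbors always contribute their
    ``+`` slot, value 1). All propagated values lie in [0, 1].
    """
    if params is None:
        params = PropagationParams()
    T, dirp, reliable = order.T, order.dir_plus, order.reliable
    h, w = T.shape
    I = _guidance_channels(guided)
    D = np.asarray(guided.D, dtype=float)

    c_plus = np.where(reliable, 1.0, 0.0)
    c_minus = np.zeros((h, w))

    for t in range(1, order.n_steps + 1):
        ys, xs = np.nonzero(T == t)
        if ys.size == 0:
            continue
        num = {+1: np.zeros(ys.size), -1: np.zeros(ys.size)}
        den = {+1: np.zeros(ys.size), -1: np.zeros(ys.size)}
        d_ref = {+1: dirp[ys, xs], -1: -dirp[ys, xs]}
        any_processed = np.zeros(ys.size, dtype=bool)

        for di, dj in NEIGHBOR_OFFSETS:
            ny, nx, inb = _neighbor_view(ys, xs, di, dj, (h, w))
            nyc, nxc = np.clip(ny, 0, h - 1), np.clip(nx, 0, w - 1)
            valid = inb & (T[nyc, nxc] < t)
            if not valid.any():
                continue
            any_processed |= valid
            vy, vx = nyc[valid], nxc[valid]
            cy, cx = ys[valid], xs[valid]

            di2 = np.sum((I[cy, cx] - I[vy, vx]) ** 2, axis=-1)
            b = np.exp(-params.gamma_i * di2 - params.gamma_d * (D[cy, cx] - D[vy, vx]) ** 2)
            decay = params.a ** (t - T[vy, vx])
            nbr_dir = dirp[vy, vx]
            nbr_rel = reliable[vy, vx]

            for s in (+1, -1):
                dref = d_ref[s][valid]
                dot = np.sum(nbr_dir * dref, axis=-1)
                use_plus = nbr_rel | (dot >= 0)
                c_sel = np.where(use_plus, c_plus[vy, vx], c_minus[vy, vx])
                d_sel = np.where(use_plus[:, None], nbr_dir, -nbr_dir)
                g = np.maximum(np.sum(dref * d_sel, axis=-1), params.delta)
                num[s][valid] += decay * b * g * c_sel
                den[s][valid] += b * g

        if not any_processed.all():
            raise AssertionError(
                "pixel reached its turn with no processed neighbor; "
                "the chessboard ordering should make this impossible"
            )
        tiny = np.finfo(float).tiny  # denormal sums are numerically void
        for s, target in ((+1, c_plus), (-1, c_minus)):
            vals = np.divide(num[s], den[s], out=np.zeros(ys.size), where=den[s] > tiny)
            target[ys, xs] = np.clip(vals, 0.0, 1.0)

    return ConfidenceField(c_plus=c_plus, c_minus=c_minus, params=params)


def ordered_filter(
    guided: GuidedImage,
    order: OrderField,
    conf: ConfidenceField,
    params: PropagationParams | None = None,
) -> np.ndarray:
    """Repair unreliable pixels wave by wave; reliable pixels pass through.

    At iteration ``t`` each pixel with ``T = t`` receives the confidence-
    weighted mean of its already-processed 8-neighbors::

        D(x) = sum_y w(x, y) D(y) / sum_y w,   w = B(x, y) G(x, y) C(y -> x)

    where ``C(y -> x)`` is the neighbor's confidence slot aligned with the
    direction from ``y`` to ``x``. Newly filtered values participate in
    later waves. If every weight vanishes (possible with ``delta = 0``) the
    plain neighbor mean is used so every pixel is assigned exactly once.
    """
    if params is None:
        params = conf.params
    T, dirp, reliable = order.T, order.dir_plus, order.reliable
    h, w = T.shape
    I = _guidance_channels(guided)
    D = np.asarray(guided.D, dtype=float).copy()

    for t in range(1, order.n_steps + 1):
        ys, xs = np.nonzero(T == t)
        if ys.size == 0:
            continue
        num = np.zeros(ys.size)
        den = np.zeros(ys.size)
        nsum = np.zeros(ys.size)
        ncnt = np.zeros(ys.size)

        for di, dj in NEIGHBOR_OFFSETS:
            ny, nx, inb = _neighbor_view(ys, xs, di, dj, (h, w))
            nyc, nxc = np.clip(ny, 0, h - 1), np.clip(nx, 0, w - 1)
            valid = inb & (T[nyc, nxc] < t)
            if not valid.any():
                continue
            vy, vx = nyc[valid], nxc[valid]
            cy, cx = ys[valid], xs[valid]

            di2 = np.sum((I[cy, cx] - I[vy, vx]) ** 2, axis=-1)
            b = np.exp(-params.gamma_i * di2 - params.gamma_d * (D[cy, cx] - D[vy, vx]) ** 2)

            # Direction from neighbor y to pixel x.
            u = np.array([-di, -dj], dtype=float)
            u /= np.linalg.norm(u)
            nbr_dir = dirp[vy, vx]
            use_plus = reliable[vy, vx] | (nbr_dir @ u >= 0)
            c_sel = np.where(use_plus, conf.c_plus[vy, vx], conf.c_minus[vy, vx])
            d_sel = np.where(use_plus[:, None], nbr_dir, -nbr_dir)
            g = np.maximum(np.sum(dirp[cy, cx] * d_sel, axis=-1), params.delta)

            wgt = b * g * c_sel
            num[valid] += wgt * D[vy, vx]
            den[valid] += wgt
            nsum[valid] += D[vy, vx]
            ncnt[valid] += 1.0

        tiny = np.finfo(float).tiny  # guard against denormal weight sums
        vals = np.where(
            den > tiny,
            np.divide(num, den, out=np.zeros_like(num), where=den > tiny),
            np.divide(nsum, ncnt, out=np.zeros_like(nsum), where=ncnt > 0),
        )
        D[ys, xs] = vals

    return D


def reduced_distance_decay_filter(
    D: np.ndarray, reliable: np.ndarray, a: float
) -> np.ndarray:
    """Independent reference: pure distance-decayed averaging.

    The closed-form limit of the ordered filter when both consistency
    weights are switched off (``gamma_i = gamma_d = 0``, ``delta = 1``):
    confidence is exactly ``a^T(y)`` and each wave takes the
    ``a^T``-weighted mean of processed 8-neighbors. Implemented from
    scratch (own breadth-first distance transform, plain Python loops) as a
    cross-check oracle for the full machinery.
    """
    reliable = np.asarray(reliable, dtype=bool)
    if not reliable.any():
        raise ValueError("requires at least one reliable pixel")
    h, w = reliable.shape
    out = np.asarray(D, dtype=float).copy()

    # Breadth-first chessboard distance.
    T = np.full((h, w), -1, dtype=int)
    T[reliable] = 0
    frontier = [(i, j) for i in range(h) for j in range(w) if reliable[i, j]]
    t = 0
    while frontier:
        t += 1
        nxt = []
        for i, j in frontier:
            for di, dj in NEIGHBOR_OFFSETS:
                y, x = i + di, j + dj
                if 0 <= y < h and 0 <= x < w and T[y, x] < 0:
                    T[y, x] = t
                    nxt.append((y, x))
        frontier = nxt

    for level in range(1, T.max() + 1):
        updates = {}
        for i in range(h):
            for j in range(w):
                if T[i, j] != level:
                    continue
                num = den = 0.0
                for di, dj in NEIGHBOR_OFFSETS:
                    y, x = i + di, j + dj
                    if 0 <= y < h and 0 <= x < w and 0 <= T[y, x] < level:
                        wgt = a ** T[y, x]
                        num += wgt * out[y, x]
                        den += wgt
                updates[(i, j)] = num / den
        for (i, j), v in updates.items():
            out[i, j] = v
    return out
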