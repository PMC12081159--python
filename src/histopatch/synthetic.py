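"""Seeded generation of tissue-like test images.

The generator emulates two-class prostate-tissue morphology at desk scale:
benign regions contain regular gland motifs (rings of epithelium around a
clear lumen embedded in stroma), while malignant regions contain irregular,
fused glandular blobs. A single ``regularity`` knob in [0, 1] controls the
amplitude of a low-order sinusoidal perturbation of each gland boundary:
high regularity gives near-circular glands, low regularity gives the
distorted, fused shapes typical of high-grade disease. Colors come from a
small stain-like palette and corruption is additive Gaussian noise.

Everything is deterministic under a fixed seed (bit-identical output), so
the images double as reproducible fixtures for every downstream stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

BENIGN = 0
MALIGNANT = 1
LABEL_NAMES = {BENIGN: "benign", MALIGNANT: "malignant"}

#: Default class conditions: benign glands are regular, malignant ones are not.
BENIGN_REGULARITY = 0.9
MALIGNANT_REGULARITY = 0.2

#: Stain-like palette: (stroma pink, epithelium purple, lumen off-white).
DEFAULT_PALETTE = ((226, 178, 200), (118, 62, 142), (244, 238, 244))


@dataclass(frozen=True)
class TissueSpec:
    """Parameters of one synthetic tissue image.

    Attributes
    ----------
    side_length : int
        Image side in pixels (square image), at least 32.
    class_label : int
        ``BENIGN`` (0) or ``MALIGNANT`` (1).
    gland_count : int
        Number of gland motifs drawn, at least 1.
    regularity : float
        Boundary regularity in [0, 1]; the sinusoidal boundary perturbation
        has amplitude ``(1 - regularity) * radius``.
    palette : tuple
        Stain-like RGB triples ``(stroma, epithelium, lumen)``.
    noise_sd : float
        Standard deviation of additive Gaussian noise on 8-bit values.
    seed : int
        RNG seed; identical specs produce bit-identical images.
    """

    side_length: int = 64
    class_label: int = BENIGN
    gland_count: int = 4
    regularity: float = BENIGN_REGULARITY
    palette: tuple = DEFAULT_PALETTE
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side_length < 32:
            raise ValueError(f"side_length must be >= 32, got {self.side_length}")
        if self.gland_count < 1:
            raise ValueError(f"gland_count must be >= 1, got {self.gland_count}")
        if not 0.0 <= self.regularity <= 1.0:
            raise ValueError(f"regularity must be in [0, 1], got {self.regularity}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.class_label not in LABEL_NAMES:
            raise ValueError(f"class_label must be 0 or 1, got {self.class_label}")


def generate_tissue_image(spec: TissueSpec) -> np.ndarray:
    """Render one tissue image from a spec.

    Returns a ``(side, side, 3)`` uint8 raster. Gland motifs are perturbed
    annuli: at angle theta the outer boundary radius is
    ``r0 * (1 + amp * sum_h a_h sin(h*theta + phi_h))`` with
    ``amp = 1 - regularity`` and harmonics h = 2..5; the lumen boundary is
    a fixed fraction of the outer boundary. Later glands overwrite earlier
    ones, which at low regularity produces fused, cribriform-like masses.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.side_length
    stroma, epithelium, lumen = (np.asarray(c, dtype=float) for c in spec.palette)

    img = np.empty((n, n, 3), dtype=float)
    img[:] = stroma

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    amp = 1.0 - spec.regularity
    harmonics = np.arange(2, 6)

    # Benign glands sit on an even grid (orderly tissue); as regularity
    # drops, center jitter grows and glands crowd and fuse.
    g = spec.gland_count
    grid = int(np.ceil(np.sqrt(g)))
    spacing = 0.7 * n / grid
    anchors = [
        (0.15 * n + (gi + 0.5) * spacing, 0.15 * n + (gj + 0.5) * spacing)
        for gi in range(grid) for gj in range(grid)
    ][:g]

    for cy0, cx0 in anchors:
        jy, jx = rng.uniform(-1.0, 1.0, size=2) * amp * spacing
        cy = float(np.clip(cy0 + jy, 0.1 * n, 0.9 * n))
        cx = float(np.clip(cx0 + jx, 0.1 * n, 0.9 * n))
        r0 = rng.uniform(0.10, 0.18) * n * (1.0 + 0.5 * amp)
        coeffs = rng.normal(0.0, 1.0, size=harmonics.size)
        coeffs /= max(np.abs(coeffs).sum(), 1e-12)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=harmonics.size)

        dy, dx = yy - cy, xx - cx
        theta = np.arctan2(dy, dx)
        wobble = np.zeros_like(theta)
        for h, c, p in zip(harmonics, coeffs, phases):
            wobble += c * np.sin(h * theta + p)
        boundary = r0 * np.clip(1.0 + amp * 1.6 * wobble, 0.2, 2.5)

        dist = np.hypot(dy, dx)
        gland = dist <= boundary
        lumen_mask = dist <= 0.45 * boundary
        img[gland] = epithelium
        img[lumen_mask] = lumen

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def degrade_image(
    image: np.ndarray, factor: int, noise_sd: float, seed: int
) -> np.ndarray:
    """Block-downsample an image by ``factor`` and add Gaussian noise.

    ``factor`` must divide both image sides. Provides the low-resolution,
    corrupted input the restoration path starts from.
    """
    if factor < 2:
        raise ValueError(f"factor must be >= 2, got {factor}")
    h, w = image.shape[:2]
    if h % factor or w % factor:
        raise ValueError(f"factor {factor} does not divide image shape {(h, w)}")
    arr = np.asarray(image, dtype=float)
    chans = arr[..., None] if arr.ndim == 2 else arr
    small = chans.reshape(h // factor, factor, w // factor, factor, -1).mean(axis=(1, 3))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        small = small + rng.normal(0.0, noise_sd, size=small.shape)
    if arr.ndim == 2:
        small = small[..., 0]
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return np.clip(np.rint(small), info.min, info.max).astype(image.dtype)
    return small.astype(image.dtype)


def generate_dataset(
    n_per_class: int,
    base_spec: TissueSpec | None = None,
    seed: int = 0,
    regularity_benign: float = BENIGN_REGULARITY,
    regularity_malignant: float = MALIGNANT_REGULARITY,
) -> tuple[list[np.ndarray], np.ndarray, list[TissueSpec]]:
    """Generate a balanced labeled image set.

    Per-image seeds are ``seed + index`` (index over the 2*n_per_class
    images, benign first), so the whole set is reproducible from the master
    seed while each image differs.

    Returns ``(images, labels, specs)`` with ``labels`` an int array of
    ``BENIGN``/``MALIGNANT``.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    base = base_spec if base_spec is not None else TissueSpec()
    images: list[np.ndarray] = []
    labels: list[int] = []
    specs: list[TissueSpec] = []
    idx = 0
    for label, reg in ((BENIGN, regularity_benign), (MALIGNANT, regularity_malignant)):
        for _ in range(n_per_class):
            sp = replace(base, class_label=label, regularity=reg, seed=seed + idx)
            specs.append(sp)
            images.append(generate_tissue_image(sp))
            labels.append(label)
            idx += 1
    return images, np.asarray(labels, dtype=int), specs


def generate_insert_image(
    side: int = 96,
    insert_frac: float = 0.5,
    seed: int = 0,
    noise_sd: float = 4.0,
    gland_density: float = 1 / 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Benign background with a square malignant insert.

    Returns ``(image, insert_mask)`` where ``insert_mask`` is True inside
    the malignant region. Used to probe heatmap localization: a correct
    classifier scores the insert higher than the background.
    ``gland_density`` (glands per pixel) defaults to the density of the
    standard training images so tile statistics match.
    """
    count = max(2, round(side * side * gland_density))
    benign = generate_tissue_image(
        TissueSpec(side_length=side, class_label=BENIGN,
                   regularity=BENIGN_REGULARITY, noise_sd=noise_sd, seed=seed,
                   gland_count=count)
    )
    malignant = generate_tissue_image(
        TissueSpec(side_length=side, class_label=MALIGNANT,
                   regularity=MALIGNANT_REGULARITY, noise_sd=noise_sd,
                   seed=seed + 1, gland_count=count)
    )
    box = int(round(side * insert_frac))
    r0 = (side - box) // 2
    mask = np.zeros((side, side), dtype=bool)
    mask[r0:r0 + box, r0:r0 + box] = True
    out = benign.copy()
    out[mask] = malignant[mask]
    return out, mask


def write_dataset(
    images: list[np.ndarray],
    labels: np.ndarray,
    specs: list[TissueSpec],
    out_dir: str | Path,
) -> Path:
    """Write images as PNG plus a ``manifest.csv`` (filename,label,seed)."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "seed"])
        for i, (img, lab, sp) in enumerate(zip(images, labels, specs)):
            name = f"{LABEL_NAMES[int(lab)]}_{i:04d}.png"
            Image.fromarray(img).save(out / name)
            writer.writerow([name, LABEL_NAMES[int(lab)], sp.seed])
    return manifest
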