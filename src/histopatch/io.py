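"""Raster readers/writers and deterministic output manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image


def read_image(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PNG/TIFF raster, normalized to [0, 1].

    Returns ``(raster, bit_depth)``; the original bit depth (8 or 16) is
    recorded so writers can restore the scale. Float TIFFs pass through
    with bit depth 0 (no rescaling).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such image: {p}")
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(p)
    elif suffix == ".png":
        arr = np.asarray(Image.open(p))
    else:
        raise ValueError(f"unsupported image format: {suffix} (expected PNG/TIFF)")

    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(float), 0
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0, 8
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0, 16
    raise ValueError(f"unsupported bit depth: {arr.dtype}")


def write_image(raster: np.ndarray, path: str | Path, bit_depth: int = 8) -> Path:
    """Write a [0, 1] raster as PNG (8/16-bit) or float TIFF (bit_depth 0)."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    if p.suffix.lower() in (".tif", ".tiff"):
        if bit_depth == 0:
            tifffile.imwrite(p, np.asarray(raster, dtype=np.float32))
        else:
            scale = 2**bit_depth - 1
            dtype = np.uint8 if bit_depth == 8 else np.uint16
            tifffile.imwrite(p, np.clip(np.rint(raster * scale), 0, scale).astype(dtype))
    else:
        arr = np.clip(np.rint(np.asarray(raster) * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(p)
    return p


def config_hash(config_dict: dict) -> str:
    """Stable sha256 of a JSON-serializable config."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_outputs(
    results: dict, out_dir: str | Path, config_dict: dict, force: bool = False
) -> dict:
    """Write stage artifacts plus a manifest JSON.

    ``results`` maps filename -> content, where content is ``bytes``,
    ``str``, or a JSON-serializable object (written as sorted-key JSON).
    The manifest lists every artifact with the config hash; an existing
    manifest blocks the write unless ``force`` is set. All output is
    deterministic for a fixed config and inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{manifest_path} exists; pass force=True (--force) to overwrite"
        )

    entries = []
    for name, content in sorted(results.items()):
        path = out / name
        path.parent.mkdir(parents=True, exist_ok=True)
        if isinstance(content, bytes):
            path.write_bytes(content)
        elif isinstance(content, str):
            path.write_text(content)
        else:
            path.write_text(json.dumps(content, sort_keys=True, indent=2) + "\n")
        entries.append({"file": name, "sha256": hashlib.sha256(path.read_bytes()).hexdigest()})

    manifest = {
        "config_hash": config_hash(config_dict),
        "artifacts": entries,
    }
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return manifest
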