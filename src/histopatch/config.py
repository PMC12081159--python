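"""Flat pipeline configuration with strict validation.

Every stage parameter lives in one flat YAML-serializable record; unknown
keys are rejected on load so silent typos in the many tunables cannot pass
unnoticed. Coordinates are row-major and 0-based with half-open tile
windows throughout the package.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import __version__ as _version


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline (see each module's docs)."""

    # synthetic data
    n_per_class: int = 200
    image_side: int = 64
    gland_count: int = 4
    regularity_benign: float = 0.9
    regularity_malignant: float = 0.2
    noise_sd: float = 4.0
    # restoration path
    restore: bool = True
    degrade_factor: int = 2
    degrade_noise_sd: float = 5.0
    tau: float = 0.1
    window_radius: int = 1
    a: float = 0.8
    gamma_i: float = 100.0
    gamma_d: float = 1.0e4
    delta: float = 0.0
    # features
    m_colors: int = 64
    d_set: tuple = (1, 3, 5, 7)
    patch_side: int = 5
    sigma: float | None = None
    k_bands: int = 8
    sample_cap: int = 256
    # classifier
    tile_side: int = 64
    stride: int = 64
    capacity: int = 32
    train_fraction: float = 0.7
    # global
    seed: int = 42
    version: str = _version

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.image_side < 32:
            raise ValueError("image_side must be >= 32")
        if not 0.0 <= self.a < 1.0:
            raise ValueError("decay a must be in [0, 1)")
        if self.tau < 0 or self.window_radius < 1:
            raise ValueError("tau must be >= 0 and window_radius >= 1")
        if self.gamma_i < 0 or self.gamma_d < 0 or self.delta < 0:
            raise ValueError("gamma_i, gamma_d and delta must be >= 0")
        if self.m_colors < 2:
            raise ValueError("m_colors must be >= 2")
        if any(k < 1 for k in self.d_set):
            raise ValueError("all d_set distances must be >= 1")
        if self.patch_side % 2 == 0 or self.patch_side < 1:
            raise ValueError("patch_side must be a positive odd integer")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be > 0 (or null for the median heuristic)")
        if self.k_bands < 1 or self.sample_cap < self.k_bands:
            raise ValueError("need 1 <= k_bands <= sample_cap")
        if self.tile_side > self.image_side or self.stride < 1:
            raise ValueError("tile_side must fit the image and stride be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.capacity < 2:
            raise ValueError("capacity must be >= 2 (one cell per class minimum)")
        if self.degrade_factor < 2 or self.image_side % self.degrade_factor:
            raise ValueError("degrade_factor must be >= 2 and divide image_side")
        self.d_set = tuple(int(k) for k in self.d_set)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["d_set"] = list(self.d_set)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        p = Path(path)
        p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return p

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "d_set" in data:
            data = dict(data, d_set=tuple(data["d_set"]))
        return cls(**data)
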