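"""End-to-end pipeline: simulate, restore, featurize, train, evaluate.

The single master seed drives every random choice (dataset seeds, the
degradation noise, graph subsampling, the split, the presentation order),
so two runs with an identical config produce byte-identical artifacts.
"""

from __future__ import annotations

import io as _stdio
import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .classifier import (
    FeatureConfig,
    FeatureNormalizer,
    MetricsReport,
    classify_batch,
    evaluate,
    split_dataset,
    tile_features,
    tile_image,
    train_memory_cells,
)
from .config import PipelineConfig
from .io import write_outputs
from .propagation import (
    PropagationParams,
    compute_order_field,
    ordered_filter,
    propagate_confidence,
)
from .reliability import (
    GuidedImage,
    detect_unreliable,
    init_upsample,
    refine_with_edge_filter,
)
from .synthetic import TissueSpec, degrade_image, generate_dataset

log = logging.getLogger("histopatch")


def restore_image(image: np.ndarray, config: PipelineConfig, seed: int) -> np.ndarray:
    """Degrade-then-restore one image through the ordered filter.

    The image is block-downsampled with noise, bilinearly upsampled back,
    and each RGB channel is repaired by confidence-propagation filtering
    (reliability detection and the confidence map are computed once on the
    luminance working channel). Returns a float RGB raster in [0, 1].
    """
    low = degrade_image(image, config.degrade_factor, config.degrade_noise_sd, seed)
    up = init_upsample(low.astype(float) / 255.0, config.degrade_factor, "bilinear")
    guided = GuidedImage.from_rgb(np.clip(up, 0.0, 1.0))

    mask = detect_unreliable(guided.D, config.window_radius, config.tau)
    mask = refine_with_edge_filter(mask, guided.D)
    if not mask.mask.any():
        return guided.I
    params = PropagationParams(
        a=config.a, gamma_i=config.gamma_i, gamma_d=config.gamma_d, delta=config.delta
    )
    order = compute_order_field(mask)
    conf = propagate_confidence(order, guided, params)

    out = np.empty_like(guided.I)
    for c in range(3):
        chan = GuidedImage(I=guided.I, D=guided.I[..., c])
        out[..., c] = ordered_filter(chan, order, conf, params)
    return np.clip(out, 0.0, 1.0)


def extract_dataset_features(
    images: list[np.ndarray], config: PipelineConfig
) -> np.ndarray:
    """Raw tile-feature matrix, one row per tile over all images.

    With the default ``tile_side = image_side`` each image is one tile.
    """
    fc = FeatureConfig(
        m_colors=config.m_colors, d_set=config.d_set,
        patch_side=config.patch_side, k_bands=config.k_bands,
        sample_cap=config.sample_cap, sigma=config.sigma, seed=config.seed,
    )
    rows = []
    for img in images:
        grid = tile_image(img, config.tile_side, config.stride)
        for _, _, win in grid.tiles:
            rows.append(tile_features(win, fc))
    return np.array(rows)


@dataclass
class PipelineResult:
    report: MetricsReport
    cells: object
    artifacts: dict
    timings: dict


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    dry_run: bool = False,
    force: bool = False,
) -> PipelineResult:
    """Run simulate -> restore -> features -> train -> evaluate.

    When ``out_dir`` is given, metrics JSON, ROC CSV, the config echo and a
    manifest are written there (refusing to overwrite an existing manifest
    unless ``force``). ``dry_run`` prints the stage plan and writes
    nothing.
    """
    config = config or PipelineConfig()
    stages = ["simulate", "restore" if config.restore else "restore (skipped)",
              "features", "train", "evaluate"]
    if dry_run:
        for s in stages:
            log.info("plan: %s", s)
        print("pipeline plan: " + " -> ".join(stages))
        return PipelineResult(report=None, cells=None, artifacts={}, timings={})

    timings = {}
    t0 = time.perf_counter()
    base = TissueSpec(side_length=config.image_side, gland_count=config.gland_count,
                      noise_sd=config.noise_sd, seed=config.seed)
    images, labels, _ = generate_dataset(
        config.n_per_class, base, seed=config.seed,
        regularity_benign=config.regularity_benign,
        regularity_malignant=config.regularity_malignant,
    )
    timings["simulate"] = time.perf_counter() - t0

    if config.restore:
        t0 = time.perf_counter()
        images = [
            (restore_image(img, config, seed=config.seed + 10_000 + i) * 255).astype(np.uint8)
            for i, img in enumerate(images)
        ]
        timings["restore"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    raw = extract_dataset_features(images, config)
    tiles_per_image = len(raw) // len(images)
    tile_labels = np.repeat(labels, tiles_per_image)
    timings["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    train_idx, test_idx = split_dataset(tile_labels, config.train_fraction, config.seed)
    norm = FeatureNormalizer.fit(raw[train_idx])
    X = norm.transform(raw)
    cells = train_memory_cells(
        X[train_idx], tile_labels[train_idx], capacity=config.capacity,
        seed=config.seed, normalizer=norm,
    )
    timings["train"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    preds, scores = classify_batch(cells, X[test_idx])
    report = evaluate(preds, scores, tile_labels[test_idx])
    timings["evaluate"] = time.perf_counter() - t0
    for stage, dt in timings.items():
        log.info("stage %-9s %.2fs", stage, dt)

    artifacts = {}
    if out_dir is not None:
        roc_buf = _stdio.StringIO()
        roc_buf.write("fpr,tpr\n")
        for f, t in zip(report.roc_fpr, report.roc_tpr):
            roc_buf.write(f"{f!r},{t!r}\n")
        results = {
            "metrics.json": report.to_dict(),
            "roc.csv": roc_buf.getvalue(),
            "config.json": config.to_dict(),
        }
        artifacts = write_outputs(results, out_dir, config.to_dict(), force=force)

    return PipelineResult(report=report, cells=cells, artifacts=artifacts, timings=timings)
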