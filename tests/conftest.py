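import numpy as np
import pytest

from histopatch import (
    FeatureNormalizer,
    PipelineConfig,
    TissueSpec,
    generate_dataset,
    train_memory_cells,
)
from histopatch.pipeline import extract_dataset_features


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_tissue_image():
    return __import__("histopatch").generate_tissue_image(TissueSpec(seed=3))


@pytest.fixture(scope="session")
def trained_tile_cells():
    """Memory-cell set trained on 32-px tiles, shared across heatmap tests."""
    cfg = PipelineConfig(
        n_per_class=40, image_side=32, tile_side=32, stride=32,
        gland_count=2, restore=False, seed=7, degrade_factor=2,
    )
    base = TissueSpec(side_length=32, gland_count=2, noise_sd=4.0, seed=7)
    images, labels, _ = generate_dataset(40, base, seed=7)
    raw = extract_dataset_features(images, cfg)
    norm = FeatureNormalizer.fit(raw)
    return train_memory_cells(
        norm.transform(raw), labels, capacity=32, seed=7, normalizer=norm
    )
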