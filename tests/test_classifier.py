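"""Tiling, features, memory-cell training, classification, and metrics."""

import numpy as np
import pytest

from histopatch import (
    BENIGN,
    MALIGNANT,
    FeatureConfig,
    MemoryCellSet,
    auc_rank,
    classify,
    evaluate,
    score_heatmap,
    similarity_threshold,
    split_dataset,
    tile_features,
    tile_image,
    train_memory_cells,
)


class TestTileImage:
    def test_non_overlapping_count(self):
        img = np.zeros((128, 128, 3), np.uint8)
        assert len(tile_image(img, 32, 32)) == 16

    def test_whole_image_single_tile(self):
        img = np.zeros((64, 64, 3), np.uint8)
        grid = tile_image(img, 64)
        assert len(grid) == 1
        assert grid.tiles[0][2].shape == (64, 64, 3)

    def test_overlapping_count_formula(self):
        img = np.zeros((64, 64, 3), np.uint8)
        grid = tile_image(img, 32, 16)
        assert len(grid) == ((64 - 32) // 16 + 1) ** 2

    def test_invalid_stride_rejected(self):
        with pytest.raises(ValueError):
            tile_image(np.zeros((64, 64, 3), np.uint8), 32, 0)


class TestTileFeatures:
    CFG = FeatureConfig(m_colors=8, d_set=(1, 2), patch_side=3, k_bands=4,
                        sample_cap=64, seed=0)

    def test_constant_tile_energy_block(self):
        tile = np.full((16, 16, 3), 120, np.uint8)
        f = tile_features(tile, self.CFG)
        energy = f[-4:]
        np.testing.assert_allclose(energy, [1, 0, 0, 0], atol=1e-12)

    def test_feature_length(self):
        tile = np.zeros((16, 16, 3), np.uint8)
        assert tile_features(tile, self.CFG).size == 8 * 2 + 4 == self.CFG.n_features

    def test_identical_tiles_identical_features(self, rng):
        tile = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        assert np.array_equal(tile_features(tile, self.CFG), tile_features(tile, self.CFG))


class TestSimilarityThreshold:
    def test_single_pair(self):
        F = 4
        u = np.zeros(F)
        v = np.full(F, 0.5)  # affinity = 0.5
        assert similarity_threshold(np.stack([u, v])) == pytest.approx(0.5)

    def test_mean_of_three_pairs(self):
        # Collinear points at 0, 0.2, 0.6 -> pair affinities 0.2, 0.4, 0.6.
        X = np.array([[0.0], [0.2], [0.6]])
        assert similarity_threshold(X) == pytest.approx(0.4)

    def test_identical_vectors_zero(self):
        X = np.tile([0.3, 0.3], (4, 1))
        assert similarity_threshold(X) == 0.0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            similarity_threshold(np.zeros((1, 3)))


class TestTrainMemoryCells:
    def test_single_point_per_class_keeps_both(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([BENIGN, MALIGNANT])
        cells = train_memory_cells(X, y, seed=0)
        assert len(cells.cells) == 2
        assert set(cells.labels) == {BENIGN, MALIGNANT}

    def test_duplicates_stimulate_one_cell(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((1, 2))])
        y = np.array([BENIGN] * 5 + [MALIGNANT])
        cells = train_memory_cells(X, y, seed=1)
        ben = cells.labels == BENIGN
        assert ben.sum() == 1
        assert cells.stimulation[ben][0] == 5

    def test_separated_clusters_each_get_a_cell(self):
        rng = np.random.default_rng(42)
        c = []
        y = []
        for label, centers in [(BENIGN, [(0, 0), (10, 10)]),
                               (MALIGNANT, [(0, 10), (10, 0)])]:
            for cx, cy in centers:
                c.append(rng.normal([cx, cy], 0.1, size=(20, 2)))
                y += [label] * 20
        X = np.vstack(c) / 10.0  # normalize into ~[0,1]
        cells = train_memory_cells(X, np.array(y), seed=42)
        for label, centers in [(BENIGN, [(0, 0), (10, 10)]),
                               (MALIGNANT, [(0, 10), (10, 0)])]:
            own = cells.cells[cells.labels == label] * 10.0
            for cx, cy in centers:
                assert np.linalg.norm(own - [cx, cy], axis=1).min() < 2.0

    def test_capacity_bounds_cell_count(self, rng):
        X = rng.random((60, 3))
        y = np.array([BENIGN, MALIGNANT] * 30)
        cells = train_memory_cells(X, y, capacity=4, seed=0, threshold=0.01)
        assert len(cells.cells) <= 4
        assert set(cells.labels) == {BENIGN, MALIGNANT}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_memory_cells(np.zeros((4, 2)), np.zeros(4, dtype=int))


class TestClassify:
    CELLS = MemoryCellSet(
        cells=np.array([[0.0, 0.0], [1.0, 1.0]]),
        labels=np.array([BENIGN, MALIGNANT]),
        stimulation=np.array([1, 1]),
        threshold=0.5,
    )

    def test_query_on_cell_gets_its_label_and_extreme_score(self):
        label, score = classify(self.CELLS, np.array([1.0, 1.0]))
        assert label == MALIGNANT and score == 1.0
        label, score = classify(self.CELLS, np.array([0.0, 0.0]))
        assert label == BENIGN and score == 0.0

    def test_equidistant_query_scores_half(self):
        _, score = classify(self.CELLS, np.array([0.5, 0.5]))
        assert score == pytest.approx(0.5)

    def test_score_monotone_along_line_toward_malignant(self):
        ts = np.linspace(0, 1, 21)
        scores = [classify(self.CELLS, np.array([t, t]))[1] for t in ts]
        assert all(b >= a for a, b in zip(scores, scores[1:]))


class TestEvaluate:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        p = y.copy()
        s = np.array([0.1, 0.2, 0.8, 0.9])
        r = evaluate(p, s, y)
        assert r.accuracy == 1.0 and r.auc == 1.0 and r.f1 == 1.0

    def test_four_point_worked_example(self):
        # Pair enumeration: of the 4 (pos, neg) pairs, 3 are ordered
        # correctly -> AUC = 0.75.
        s = np.array([0.9, 0.8, 0.4, 0.2])
        y = np.array([1, 0, 1, 0])
        r = evaluate((s > 0.5).astype(int), s, y)
        assert r.auc == pytest.approx(0.75)

    def test_rank_auc_equals_trapezoidal_roc(self, rng):
        from sklearn.metrics import roc_curve

        for _ in range(20):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = rng.random(n)
            fpr, tpr, _ = roc_curve(y, s)
            assert auc_rank(s, y) == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-10)

    def test_random_scores_auc_near_half(self, rng):
        n = 4000
        y = rng.integers(0, 2, n)
        s = rng.random(n)
        assert auc_rank(s, y) == pytest.approx(0.5, abs=0.05)

    def test_single_class_auc_undefined(self):
        r = evaluate(np.array([0, 0]), np.array([0.2, 0.3]), np.array([0, 0]))
        assert r.auc is None

    def test_metrics_consistent_with_confusion(self):
        y = np.array([1, 1, 0, 0, 1])
        p = np.array([1, 0, 0, 1, 1])
        s = np.array([0.9, 0.4, 0.2, 0.6, 0.7])
        r = evaluate(p, s, y)
        c = r.confusion
        assert c == {"tp": 2, "tn": 1, "fp": 1, "fn": 1}
        assert r.accuracy == pytest.approx(3 / 5)
        assert r.precision == pytest.approx(2 / 3)
        assert r.recall == pytest.approx(2 / 3)


class TestSplitDataset:
    def test_ten_items_seventy_percent(self):
        y = np.array([0] * 5 + [1] * 5)
        tr, te = split_dataset(y, 0.7, seed=0)
        assert len(tr) == 7 and len(te) == 3
        assert set(tr) | set(te) == set(range(10))

    def test_stratification_preserved(self):
        y = np.array([0] * 40 + [1] * 20)
        tr, _ = split_dataset(y, 0.5, seed=1)
        assert abs((y[tr] == 0).sum() - 20) <= 1
        assert abs((y[tr] == 1).sum() - 10) <= 1

    def test_fixed_seed_identical_split(self):
        y = np.array([0, 1] * 10)
        assert np.array_equal(split_dataset(y, 0.7, 5)[0], split_dataset(y, 0.7, 5)[0])

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(np.array([0, 0, 1]), 0.7, 0)


class TestScoreHeatmap:
    def test_identical_tiles_constant_heatmap(self, trained_tile_cells):
        tile = np.full((32, 32, 3), 150, np.uint8)
        img = np.tile(tile, (2, 2, 1))
        heat = score_heatmap(img, trained_tile_cells, tile_side=32, stride=32)
        assert np.allclose(heat, heat.flat[0])

    def test_values_in_unit_interval(self, trained_tile_cells, small_tissue_image):
        heat = score_heatmap(small_tissue_image, trained_tile_cells, 32, 16)
        assert heat.min() >= 0.0 and heat.max() <= 1.0

    def test_malignant_insert_scores_above_background(self, trained_tile_cells):
        from histopatch import generate_insert_image

        hits = 0
        for s in range(5):
            img, mask = generate_insert_image(side=96, seed=300 + s)
            heat = score_heatmap(img, trained_tile_cells, 32, 16)
            hits += heat[mask].mean() > heat[~mask].mean()
        assert hits >= 4
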