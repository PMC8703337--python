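import numpy as np
import pytest

from seedspectra.segmentation import (
    EllipseParams,
    SegmentationParams,
    decompose_overlaps,
    fill_holes,
    filter_components,
    label_components,
    segment_scene,
    threshold_mask,
)
from seedspectra.synthetic import SceneSpec, generate_scene, match_seeds


def rasterize(e: EllipseParams, shape=(80, 80)) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    ct, st = np.cos(e.theta), np.sin(e.theta)
    u = (cc - e.cx) * ct + (rr - e.cy) * st
    v = -(cc - e.cx) * st + (rr - e.cy) * ct
    return (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0


class TestThreshold:
    def test_strict_bounds(self):
        img = np.array([[400, 401], [1999, 2000]])
        mask = threshold_mask(img, 400, 2000)
        np.testing.assert_array_equal(mask, [[False, True], [True, False]])

    def test_interior_value_kept(self):
        assert threshold_mask(np.array([[1000]]), 400, 2000).all()

    def test_all_zero_slice_empty(self):
        assert not threshold_mask(np.zeros((5, 5)), 400, 2000).any()

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(np.zeros((2, 2)), 2000, 400)


class TestLabelComponents:
    def test_diagonal_pixels_are_one_component(self):
        # hand-enumerated 3x3 case: 8-connectivity joins diagonals
        mask = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 0]], dtype=bool)
        labels = label_components(mask)
        assert labels.max() == 1

    def test_background_row_separates(self):
        mask = np.array([[1, 1, 1], [0, 0, 0], [1, 1, 1]], dtype=bool)
        assert label_components(mask).max() == 2

    def test_empty_mask_zero_components(self):
        assert label_components(np.zeros((4, 4), dtype=bool)).max() == 0


class TestFilterComponents:
    def _two_blobs(self, n_small):
        img = np.zeros((40, 80), dtype=bool)
        img[1:26, 1:21] = True  # 500 px
        img[30, 30 : 30 + n_small] = True
        return label_components(img)

    def test_strictly_smaller_removed(self):
        out = filter_components(self._two_blobs(9), min_pixels=10)
        assert out.max() == 1

    def test_exact_threshold_kept_and_relabelled(self):
        labels = self._two_blobs(10)
        out = filter_components(labels, min_pixels=10)
        assert out.max() == 2
        assert set(np.unique(out)) == {0, 1, 2}

    def test_all_small_gives_empty(self):
        out = filter_components(self._two_blobs(5), min_pixels=10_000)
        assert out.max() == 0


class TestFillHoles:
    def test_ring_becomes_disk(self):
        ring = rasterize(EllipseParams(40, 40, 15, 15, 0)) & ~rasterize(
            EllipseParams(40, 40, 6, 6, 0)
        )
        filled = fill_holes(ring)
        np.testing.assert_array_equal(filled, rasterize(EllipseParams(40, 40, 15, 15, 0)))

    def test_solid_blob_unchanged(self):
        blob = rasterize(EllipseParams(40, 40, 10, 6, 0.5))
        np.testing.assert_array_equal(fill_holes(blob), blob)

    def test_open_cavity_unchanged(self):
        c = np.zeros((20, 20), dtype=bool)
        c[5:15, 5:15] = True
        c[8:12, 10:] = False  # channel to the border
        np.testing.assert_array_equal(fill_holes(c), c)


class TestDecomposeOverlaps:
    def test_single_ellipse_recovered(self):
        planted = EllipseParams(40, 38, 30, 15, 0.4)
        parts = decompose_overlaps(rasterize(planted), max_k=4)
        assert len(parts) == 1
        fit = parts[0][0]
        assert fit.a == pytest.approx(planted.a, rel=0.10)
        assert fit.b == pytest.approx(planted.b, rel=0.10)

    def test_two_overlapping_ellipses_split(self):
        e1 = EllipseParams(28, 40, 16, 9, 0.1)
        e2 = EllipseParams(52, 42, 15, 10, 2.0)
        mask = rasterize(e1) | rasterize(e2)
        # overlap ~20% of the smaller seed by construction
        parts = decompose_overlaps(mask, max_k=4)
        assert len(parts) == 2
        centres = sorted((p[0].cx, p[0].cy) for p in parts)
        assert abs(centres[0][0] - e1.cx) <= 3 and abs(centres[0][1] - e1.cy) <= 3
        assert abs(centres[1][0] - e2.cx) <= 3 and abs(centres[1][1] - e2.cy) <= 3

    def test_disk_is_one_seed_with_equal_axes(self):
        parts = decompose_overlaps(rasterize(EllipseParams(40, 40, 14, 14, 0)), max_k=4)
        assert len(parts) == 1
        assert parts[0][0].a == pytest.approx(parts[0][0].b, rel=0.05)

    def test_submasks_partition_component(self):
        mask = rasterize(EllipseParams(28, 40, 16, 9, 0.1)) | rasterize(
            EllipseParams(52, 42, 15, 10, 2.0)
        )
        parts = decompose_overlaps(mask, max_k=4)
        union = np.zeros_like(mask)
        total = 0
        for _, sub in parts:
            assert not (union & sub).any()  # pairwise disjoint
            union |= sub
            total += sub.sum()
        np.testing.assert_array_equal(union, mask)
        assert total == mask.sum()

    def test_tiny_component_returned_unchanged(self):
        tiny = np.zeros((10, 10), dtype=bool)
        tiny[4:6, 4:7] = True
        parts = decompose_overlaps(tiny, max_k=4)
        assert len(parts) == 1
        np.testing.assert_array_equal(parts[0][1], tiny)


class TestSegmentScene:
    def test_planted_count_recovered(self, small_scene, desk_params):
        raw, _, truth = small_scene
        mask = segment_scene(raw, desk_params)
        assert mask.n_seeds == truth.n_seeds

    def test_touching_pairs_need_ellipse_fitting(self, overlap_scene, desk_params):
        raw, _, truth = overlap_scene
        from dataclasses import replace

        with_fit = segment_scene(raw, desk_params)
        without = segment_scene(raw, replace(desk_params, ellipse_fitting=False))
        assert with_fit.n_seeds == truth.n_seeds
        assert without.n_seeds == truth.n_seeds - 2  # two merged pairs

    def test_blank_scene_zero_seeds(self, desk_params):
        from seedspectra.envi import Hypercube

        blank = Hypercube(
            data=np.zeros((50, 50, 25), dtype=np.uint16),
            wavelengths_nm=np.linspace(600, 1700, 25),
        )
        assert segment_scene(blank, desk_params).n_seeds == 0

    def test_deterministic(self, overlap_scene, desk_params):
        raw, _, _ = overlap_scene
        m1 = segment_scene(raw, desk_params)
        m2 = segment_scene(raw, desk_params)
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_raising_min_pixels_never_increases_count(self, small_scene):
        raw, _, _ = small_scene
        counts = [
            segment_scene(raw, SegmentationParams(min_pixels=m, rng_seed=0)).n_seeds
            for m in (50, 150, 400)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_labels_partition_and_centres_match_truth(self, small_scene, desk_params):
        raw, _, truth = small_scene
        mask = segment_scene(raw, desk_params)
        counts = mask.pixel_counts()
        assert counts.size == mask.n_seeds
        assert (counts >= desk_params.min_pixels).all()
        matches = match_seeds(truth, mask)
        assert len(matches) == truth.n_seeds
        assert max(d for *_, d in matches) <= 3.0
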