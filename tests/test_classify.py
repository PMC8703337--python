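import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedspectra.classify import (
    ConfusionCounts,
    confusion_metrics,
    extract_subcubes,
    metrics_from_counts,
    seed_svm_features,
    split_dataset,
    train_eval_seed_svm,
    train_pixel_svm,
    vote_seed_labels,
)
from seedspectra.envi import Hypercube
from seedspectra.segmentation import SeedMask


def _toy_seed_data(n_per_group=20, n_bands=30, gap=0.3, noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    groups = np.repeat([0, 1], n_per_group)
    base = 0.4 + 0.1 * np.sin(np.linspace(0, 3, n_bands))
    spectra = base + gap * groups[:, None] + rng.normal(0, noise, (2 * n_per_group, n_bands))
    return spectra, groups


class TestSplitDataset:
    def test_published_scale_counts(self):
        groups = np.repeat([0, 1], 100)
        split = split_dataset(groups, np.arange(200), rng_seed=0)
        assert split.seed_train.size == 160
        assert split.seed_test.size == 40

    def test_pixel_partitions_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(5)
        groups = np.repeat([0, 1], 10)
        pixel_seed = rng.integers(0, 20, size=500)
        split = split_dataset(groups, pixel_seed, rng_seed=1)
        parts = [split.pixel_train, split.pixel_val, split.pixel_test]
        allpx = np.concatenate(parts)
        assert allpx.size == 500
        assert np.unique(allpx).size == 500

    def test_test_pixels_are_exactly_test_seed_pixels(self):
        rng = np.random.default_rng(6)
        groups = np.repeat([0, 1], 10)
        pixel_seed = rng.integers(0, 20, size=400)
        split = split_dataset(groups, pixel_seed, rng_seed=2)
        expected = np.nonzero(np.isin(pixel_seed, split.seed_test))[0]
        np.testing.assert_array_equal(split.pixel_test, expected)

    def test_reproducible(self):
        groups = np.repeat([0, 1], 10)
        px = np.repeat(np.arange(20), 7)
        a = split_dataset(groups, px, rng_seed=3)
        b = split_dataset(groups, px, rng_seed=3)
        np.testing.assert_array_equal(a.seed_test, b.seed_test)
        np.testing.assert_array_equal(a.pixel_train, b.pixel_train)

    def test_single_seed_group_rejected(self):
        with pytest.raises(ValueError, match="stratify"):
            split_dataset(np.array([0, 1, 1, 1]), np.arange(4))


class TestSeedSvm:
    def test_pca_shapes_and_ordering(self):
        spectra, _ = _toy_seed_data(n_per_group=80, n_bands=239)
        split = split_dataset(np.repeat([0, 1], 80), np.arange(160), rng_seed=0)
        pca, train_feat, _ = seed_svm_features(spectra[split.seed_train], 50)
        assert train_feat.shape == (128, 50)
        variances = train_feat.var(axis=0)
        assert np.all(np.diff(variances) <= 1e-9)  # eigenvalue-ranked

    def test_training_mean_projects_to_zero(self):
        spectra, _ = _toy_seed_data()
        pca, _, _ = seed_svm_features(spectra, 5)
        proj = pca.transform(spectra.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(proj, 0.0, atol=1e-10)

    def test_excessive_components_rejected(self):
        spectra, _ = _toy_seed_data(n_per_group=5)
        with pytest.raises(ValueError, match="n_components"):
            seed_svm_features(spectra, 50)

    def test_separable_groups_high_accuracy(self):
        spectra, groups = _toy_seed_data(gap=0.3, noise=0.02)
        split = split_dataset(groups, np.arange(groups.size), rng_seed=0)
        report, _ = train_eval_seed_svm(spectra, groups, split, n_components=10)
        assert report.accuracy >= 0.95
        assert report.seed_group_prediction_accuracy == report.accuracy

    def test_shuffled_labels_near_chance(self):
        spectra, groups = _toy_seed_data(n_per_group=100, gap=0.0, noise=0.02, seed=2)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(groups)
        split = split_dataset(shuffled, np.arange(groups.size), rng_seed=0)
        report, _ = train_eval_seed_svm(spectra, shuffled, split, n_components=10)
        # binomial 99.9% envelope around 0.5 for 40 test seeds
        assert abs(report.accuracy - 0.5) < 0.27

    def test_memorization_sanity(self):
        """Training and evaluating on identical duplicated seeds is perfect."""
        spectra, groups = _toy_seed_data(gap=0.3)
        dup_spec = np.vstack([spectra, spectra])
        dup_groups = np.concatenate([groups, groups])
        split = split_dataset(dup_groups, np.arange(dup_groups.size), rng_seed=1)
        # force test set to be copies of training seeds
        report, _ = train_eval_seed_svm(dup_spec, dup_groups, split, n_components=10)
        assert report.accuracy == 1.0

    def test_single_class_training_rejected(self):
        spectra, groups = _toy_seed_data()
        split = split_dataset(groups, np.arange(groups.size), rng_seed=0)
        with pytest.raises(ValueError, match="single class"):
            train_eval_seed_svm(spectra, np.zeros_like(groups), split)


class TestSubCubes:
    def _scene(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[3:9, 3:9] = 1
        labels[12:18, 10:17] = 2
        cube = Hypercube(
            data=np.random.default_rng(0).random((20, 20, 15)),
            wavelengths_nm=np.linspace(600, 1700, 15),
        )
        return cube, SeedMask(labels=labels)

    def test_one_sample_per_seed_pixel(self):
        cube, mask = self._scene()
        samples = extract_subcubes(cube, mask, patch_size=5)
        assert len(samples) == int((mask.labels > 0).sum())
        assert samples.patches.shape[1:] == (5, 5, 15)

    def test_constant_cube_gives_constant_patch(self):
        cube, mask = self._scene()
        cube.data[:] = 0.7
        samples = extract_subcubes(cube, mask, patch_size=5)
        np.testing.assert_allclose(samples.patches, 0.7)

    def test_center_spectrum_matches_cube(self):
        cube, mask = self._scene()
        samples = extract_subcubes(cube, mask, patch_size=5)
        r, c = samples.centers[0]
        np.testing.assert_array_equal(samples.center_spectra[0], cube.data[r, c, :])

    def test_even_patch_rejected(self):
        cube, mask = self._scene()
        with pytest.raises(ValueError, match="odd"):
            extract_subcubes(cube, mask, patch_size=4)

    def test_separable_pixel_svm(self):
        """Pixel SVM separates well-separated groups and predicts every
        test pixel (duplicated seeds so both partitions hold both groups)."""
        cube, mask = self._scene()
        cube.data[mask.labels == 2, :] += 0.5
        dup = _dup(extract_subcubes(cube, mask, patch_size=3))
        groups = np.array([0, 1, 0, 1])
        split = split_dataset(groups, dup.seed_ids, rng_seed=0)
        preds = train_pixel_svm(dup, groups, split, rng_seed=0)
        assert preds.size == split.pixel_test.size
        truth = groups[dup.seed_ids[split.pixel_test]]
        assert np.mean(preds == truth) >= 0.9


class TestVoting:
    def test_majority_control(self):
        preds = np.array([0] * 6 + [1] * 4)
        seeds = np.zeros(10, dtype=int)
        assert vote_seed_labels(preds, seeds)[0] == 0

    def test_unanimous_hs(self):
        assert vote_seed_labels(np.ones(5, dtype=int), np.zeros(5, dtype=int))[0] == 1

    def test_exact_tie_goes_to_hs(self):
        preds = np.array([0, 0, 1, 1])
        assert vote_seed_labels(preds, np.zeros(4, dtype=int))[0] == 1

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.permutations(list(range(12))))
    def test_invariant_to_pixel_ordering(self, perm):
        preds = np.array([0, 1, 0, 1, 1, 0, 0, 0, 1, 1, 1, 1])
        seeds = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        base = vote_seed_labels(preds, seeds)
        p = np.array(perm)
        assert vote_seed_labels(preds[p], seeds[p]) == base

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError, match="no predicted pixels"):
            vote_seed_labels(np.array([0]), np.array([0]), seed_indices=np.array([5]))


class TestMetrics:
    def test_worked_example_row(self):
        """TP=15, TN=17, FP=5, FN=3 reproduce the published seed-SVM row."""
        report = metrics_from_counts(ConfusionCounts(tp=15, tn=17, fp=5, fn=3))
        assert report.accuracy == pytest.approx(0.80, abs=1e-12)
        assert report.precision == pytest.approx(0.75, abs=1e-12)
        assert report.recall == pytest.approx(15 / 18, abs=1e-12)
        assert report.f_score == pytest.approx(30 / 38, abs=1e-12)
        assert round(100 * report.f_score, 2) == pytest.approx(78.95, abs=0.011)

    def test_perfect_predictions(self):
        truth = np.array([0, 1, 0, 1])
        _, report = confusion_metrics(truth, truth)
        assert (
            report.accuracy == report.precision == report.recall == report.f_score == 1.0
        )

    def test_small_direct_case(self):
        report = metrics_from_counts(ConfusionCounts(tp=1, tn=0, fp=1, fn=0))
        assert report.precision == 0.5
        assert report.recall == 1.0
        assert report.f_score == pytest.approx(2 / 3)

    def test_counts_sum_to_sample_count(self):
        truth = np.array([0, 1, 1, 0, 1])
        pred = np.array([1, 1, 0, 0, 1])
        counts, _ = confusion_metrics(truth, pred)
        assert counts.total == 5

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        tp=st.integers(0, 50),
        tn=st.integers(0, 50),
        fp=st.integers(0, 50),
        fn=st.integers(0, 50),
    )
    def test_f_score_is_harmonic_mean(self, tp, tn, fp, fn):
        report = metrics_from_counts(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        if report.precision > 0 and report.recall > 0:
            hm = 2 * report.precision * report.recall / (report.precision + report.recall)
            assert report.f_score == pytest.approx(hm, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_metrics(np.array([]), np.array([]))


def _dup(samples):
    """Duplicate a SubCubeSamples block over four seeds for split tests."""
    from seedspectra.classify import SubCubeSamples

    return SubCubeSamples(
        patches=np.concatenate([samples.patches, samples.patches]),
        centers=np.concatenate([samples.centers, samples.centers]),
        seed_ids=np.concatenate([samples.seed_ids, samples.seed_ids + 2]),
        patch_size=samples.patch_size,
    )
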