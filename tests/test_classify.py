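"""Feature extraction and the contour/tissue pixel classifier."""

from __future__ import annotations

import numpy as np
import pytest

from organocyte import classify
from organocyte.classify import (PixelClassifier, clean_contour_mask,
                                 extract_features, predict_masks,
                                 train_classifier)
from organocyte.config import DEFAULT_FEATURES, PipelineConfig
from organocyte.core_io import Calibration
from organocyte.errors import ConfigError, TrainingError
from organocyte.preprocess import GrayImage
from organocyte.synthesize import (annotations_from_truth, render_scene)

from conftest import enhanced_of, small_scene_spec

CAL = Calibration(1.0, 1.0)


def gray(px):
    return GrayImage(np.asarray(px, dtype=float), CAL)


class TestExtractFeatures:
    def test_default_stack_has_14_named_features(self):
        fs = extract_features(gray(np.random.default_rng(0).uniform(
            0, 255, (32, 32))))
        assert fs.data.shape == (32, 32, 14)
        assert fs.names == DEFAULT_FEATURES

    def test_constant_image_derivative_features_zero(self):
        fs = extract_features(gray(np.full((32, 32), 120.0)))
        by = dict(zip(fs.names, np.moveaxis(fs.data, -1, 0)))
        for name in ("gradient_s1", "gradient_s2", "variance_w7",
                     "haralick_contrast_w15"):
            assert np.allclose(by[name], 0.0, atol=1e-4), name
        # truncated discrete kernel leaves a tiny residual on the Laplacian
        assert np.allclose(by["log_s2"], 0.0, atol=0.05)
        for name in ("intensity", "gaussian_s4", "median_r2"):
            assert np.allclose(by[name], 120.0, atol=1e-3), name

    def test_impulse_gaussian_center_matches_kernel_peak(self):
        px = np.zeros((33, 33))
        px[16, 16] = 200.0
        fs = extract_features(gray(px), ["gaussian_s2"])
        expected = 200.0 / (2 * np.pi * 2.0**2)  # amplitude x kernel peak
        assert fs.data[16, 16, 0] == pytest.approx(expected, rel=0.02)

    def test_unknown_feature_rejected(self):
        with pytest.raises(ConfigError):
            extract_features(gray(np.zeros((8, 8))), ["wavelet_w3"])


def toy_example(seed=0, size=48):
    """Perfectly separable toy: bright contour band vs dark tissue."""
    rng = np.random.default_rng(seed)
    px = np.full((size, size), 20.0) + rng.normal(0, 1.0, (size, size))
    ann = np.full((size, size), 2, dtype=np.uint8)
    px[10:14, :] = 200.0
    ann[10:14, :] = 1
    return extract_features(gray(px)), ann


class TestTrainClassifier:
    def test_separable_toy_high_training_accuracy(self):
        fs, ann = toy_example()
        model = train_classifier([(fs, ann)], seed=0, n_trees=25)
        proba = model.predict_proba(fs)
        pred = np.where(proba[:, :, 0] >= 0.5, 1, 2)
        assert (pred == ann).mean() >= 0.99

    def test_empty_example_list_raises(self):
        with pytest.raises(TrainingError):
            train_classifier([], seed=0)

    def test_single_class_pool_raises(self):
        fs, ann = toy_example()
        ann = np.where(ann == 1, 2, ann).astype(np.uint8)
        with pytest.raises(TrainingError):
            train_classifier([(fs, ann)], seed=0)

    def test_same_seed_identical_predictions(self):
        fs, ann = toy_example()
        probe, _ = toy_example(seed=9)
        a = train_classifier([(fs, ann)], seed=3, n_trees=20)
        b = train_classifier([(fs, ann)], seed=3, n_trees=20)
        np.testing.assert_array_equal(a.predict_proba(probe),
                                      b.predict_proba(probe))

    def test_probabilities_sum_to_one(self):
        fs, ann = toy_example()
        model = train_classifier([(fs, ann)], seed=0, n_trees=10)
        proba = model.predict_proba(fs)
        np.testing.assert_allclose(proba.sum(axis=-1), 1.0, atol=1e-9)

    def test_save_load_bitcompatible(self, tmp_path):
        fs, ann = toy_example()
        model = train_classifier([(fs, ann)], seed=0, n_trees=10)
        path = tmp_path / "clf.ocmodel"
        model.save(path)
        restored = PixelClassifier.load(path)
        np.testing.assert_array_equal(model.predict_proba(fs),
                                      restored.predict_proba(fs))
        assert restored.feature_names == model.feature_names


class TestPredictMasks:
    def test_masks_disjoint_and_ring_recovered(self, fast_model):
        cfg = PipelineConfig(calibration_x_um=2.0, calibration_y_um=2.0)
        image, truth = render_scene(small_scene_spec(77))
        fs = extract_features(enhanced_of(image, cfg), cfg.features)
        contour, background = predict_masks(fast_model, fs, 0.5)
        assert not (contour & background).any()
        # contour pixels recover the true membrane band
        assert contour[truth.membrane_mask].mean() >= 0.8

    def test_threshold_one_allows_empty_masks(self, fast_model):
        cfg = PipelineConfig(calibration_x_um=2.0, calibration_y_um=2.0)
        image, _ = render_scene(small_scene_spec(78))
        fs = extract_features(enhanced_of(image, cfg), cfg.features)
        contour, background = predict_masks(fast_model, fs, 1.0)
        assert not (contour & background).any()  # disjoint even here

    def test_generalizes_to_unseen_scenes(self, fast_model):
        """Contour-pixel recall on unseen cluttered scenes (desk-scale
        version of the train-on-6 / predict-on-unseen protocol)."""
        cfg = PipelineConfig(calibration_x_um=2.0, calibration_y_um=2.0)
        hits = total = 0
        for seed in (91, 92, 93):
            image, truth = render_scene(small_scene_spec(seed))
            fs = extract_features(enhanced_of(image, cfg), cfg.features)
            contour, _ = predict_masks(fast_model, fs, 0.5)
            hits += int(contour[truth.membrane_mask].sum())
            total += int(truth.membrane_mask.sum())
        assert hits / total >= 0.8


class TestCleanContourMask:
    def test_area_threshold_keeps_only_large(self):
        mask = np.zeros((20, 40), bool)
        mask[2:7, 2:7] = True     # 25 px = 25 um^2 at 1 um/px
        mask[10:13, 30:35] = True  # 15 px
        out = clean_contour_mask(mask, 20.0, CAL)
        assert out[2:7, 2:7].all()
        assert not out[10:13, 30:35].any()

    def test_zero_threshold_identity(self):
        rng = np.random.default_rng(0)
        mask = rng.random((15, 15)) > 0.7
        np.testing.assert_array_equal(clean_contour_mask(mask, 0.0, CAL),
                                      mask)

    def test_empty_mask(self):
        out = clean_contour_mask(np.zeros((5, 5), bool), 20.0, CAL)
        assert not out.any()

    def test_idempotent_and_never_adds(self):
        rng = np.random.default_rng(5)
        mask = rng.random((40, 40)) > 0.6
        once = clean_contour_mask(mask, 9.0, CAL)
        twice = clean_contour_mask(once, 9.0, CAL)
        np.testing.assert_array_equal(once, twice)
        assert not (once & ~mask).any()
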