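"""Shared fixtures: calibrations, small scenes, trained classifiers.

Two classifier tiers: ``fast_model`` (small scenes, few trees) for unit
tests of downstream stages, and the session-scoped ``benchmark_model``
trained with the full default protocol (six mixed-complexity scenes) for
the end-to-end suites.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from organocyte import classify, pipeline
from organocyte.config import PipelineConfig
from organocyte.core_io import Calibration
from organocyte.membrane import detect_membrane, enhance_grayscale
from organocyte.preprocess import GrayImage, subtract_background, to_grayscale
from organocyte.synthesize import (SceneSpec, annotations_from_truth,
                                   complexity_preset, render_scene)


@pytest.fixture
def cal1() -> Calibration:
    return Calibration(1.0, 1.0)


@pytest.fixture
def cal2() -> Calibration:
    return Calibration(2.0, 2.0)


@pytest.fixture
def cfg2() -> PipelineConfig:
    """Default pipeline config at the synthetic scenes' 2 μm/px grid."""
    return PipelineConfig(calibration_x_um=2.0, calibration_y_um=2.0)


def small_scene_spec(seed: int, **overrides) -> SceneSpec:
    """A 256×256 scene with a handful of organoids for fast tests."""
    base = dict(width=256, height=256, n_organoids=5,
                immune_density_per_mm2=30.0, cluster_count=1,
                cluster_cells=25, seed=seed)
    base.update(overrides)
    return SceneSpec(**base)


def enhanced_of(image, cfg: PipelineConfig) -> GrayImage:
    work = subtract_background(to_grayscale(image), cfg.background_radius_px)
    mem = detect_membrane(work, cfg.membrane_max_width_px,
                          cfg.membrane_min_prominence)
    return enhance_grayscale(work, mem, cfg.membrane_boost)


def train_on_scenes(specs, cfg: PipelineConfig, seed: int = 1,
                    n_trees: int = 100, max_px: int = 20000):
    examples = []
    for spec in specs:
        image, truth = render_scene(spec)
        feats = classify.extract_features(enhanced_of(image, cfg),
                                          cfg.features)
        examples.append((feats, annotations_from_truth(truth)))
    return classify.train_classifier(examples, seed=seed, n_trees=n_trees,
                                     max_pixels_per_class=max_px)


@pytest.fixture(scope="session")
def fast_model():
    """Small forest trained on two small cluttered scenes."""
    cfg = PipelineConfig(calibration_x_um=2.0, calibration_y_um=2.0)
    specs = [small_scene_spec(11), small_scene_spec(12, gap_prob=0.3)]
    return train_on_scenes(specs, cfg, seed=7, n_trees=30, max_px=5000)


@pytest.fixture(scope="session")
def benchmark_model():
    """Classifier trained with the default six-scene protocol."""
    cfg = PipelineConfig(calibration_x_um=2.0, calibration_y_um=2.0)
    specs = [complexity_preset(lvl, seed=i)
             for i, lvl in zip(range(1, 7), [1, 2, 3, 1, 2, 3])]
    return train_on_scenes(specs, cfg, seed=1)


@pytest.fixture(scope="session")
def benchmark_results(benchmark_model):
    """Full pooled benchmark: 20 unseen scenes per complexity level."""
    from organocyte.evaluate import MatchResult, match_detections

    cfg = PipelineConfig(calibration_x_um=2.0, calibration_y_um=2.0)
    out = {}
    for level, base in [(1, 101), (2, 201), (3, 301)]:
        pooled = MatchResult(0, 0, 0)
        pairs = []
        for s in range(base, base + 20):
            image, truth = render_scene(complexity_preset(level, seed=s))
            res = pipeline.detect_organoids(image, benchmark_model, cfg)
            m = match_detections(res.labels, truth.labels, cfg.iou_min)
            pooled = pooled + m
            area = truth.calibration.pixel_area_um2
            for pid, tid, _ in m.pairs:
                pairs.append((float((res.labels == pid).sum()) * area,
                              float((truth.labels == tid).sum()) * area))
        out[level] = (pooled, pairs)
    return out


def clean_scene(n_organoids: int, seed: int) -> SceneSpec:
    """A clutter-free, artifact-free full-size scene."""
    return dataclasses.replace(
        complexity_preset(1, seed=seed), n_organoids=n_organoids,
        immune_density_per_mm2=0.0, cluster_count=0,
        fusion_prob=0.0, gap_prob=0.0)
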