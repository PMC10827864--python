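"""End-to-end detection: wire all stages into one call.

Stage order: grayscale → median background subtraction → membrane
profile-scan + enhancement → feature extraction → pixel classification →
contour cleaning and bridging → background/inner-area separation by size →
seed generation → ring-support and intensity validation → compactness
gating → radius-limited geodesic growing → small-contour rescue →
measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import classify, measure, membrane, preprocess, segment
from .classify import PixelClassifier
from .config import PipelineConfig
from .core_io import Calibration, RasterImage, SampleID

log = logging.getLogger("organocyte")


@dataclass
class DetectionResult:
    """Everything the pipeline produced for one frame."""

    labels: np.ndarray
    records: list[measure.OrganoidRecord]
    enhanced: preprocess.GrayImage
    membrane_mask: np.ndarray
    contour_mask: np.ndarray
    background_mask: np.ndarray
    seeds: list[segment.SeedRegion] = field(default_factory=list)
    calibration: Calibration | None = None

    @property
    def count(self) -> int:
        return int(self.labels.max(initial=0))


def grow_radii_um(config: PipelineConfig, calibration: Calibration
                  ) -> tuple[float, float]:
    """The two growing limits in μm (config may state them in pixels)."""
    seed_r = config.seed_grow_radius_um
    org_r = config.organoid_grow_radius_um
    if config.radii_in_px:
        seed_r *= calibration.x_um
        org_r *= calibration.x_um
    return seed_r, org_r


def detect_organoids(image: RasterImage, model: PixelClassifier,
                     config: PipelineConfig,
                     sample: SampleID | None = None) -> DetectionResult:
    """Run the full detection pipeline on one imported frame."""
    cal = image.calibration
    if sample is None:
        sample = SampleID("P0", "A0", "na", 0.0)

    log.debug("stage=grayscale")
    gray = preprocess.to_grayscale(image)
    log.debug("stage=background")
    work = preprocess.subtract_background(gray, config.background_radius_px)
    log.debug("stage=membrane")
    mem = membrane.detect_membrane(work, config.membrane_max_width_px,
                                   config.membrane_min_prominence)
    enhanced = membrane.enhance_grayscale(work, mem, config.membrane_boost)
    log.debug("stage=features")
    feats = classify.extract_features(enhanced, config.features)
    log.debug("stage=classify")
    contour, tissue = classify.predict_masks(model, feats,
                                             config.prob_threshold)
    contour = classify.clean_contour_mask(contour, config.min_contour_area_um2,
                                          cal)
    # bridge short membrane breaks at the solid-footprint level, so a
    # disrupted outline still encloses its inner area
    footprints = segment.bridge_fill(contour, config.contour_close_radius_px)
    log.debug("stage=seeds")
    # background size criterion runs on the tissue field outside the
    # footprints: an inner area sealed off by bridging must not be dragged
    # into the background component through the former break
    background = segment.select_background_components(
        tissue & ~footprints, config.seed_area_max_um2, cal)
    seeds = segment.generate_seed_candidates(
        contour, background, enhanced, cal,
        config.seed_area_min_um2, config.seed_area_max_um2)
    seeds = segment.validate_seeds(
        seeds, contour, config.ring_support_min, config.ring_probe_px,
        config.intensity_min, config.intensity_max)
    seeds = segment.compactness_gate(
        seeds, cal, config.compactness_min, config.compactness_max,
        config.seed_smooth_radius_px, contour.shape)
    log.debug("stage=grow n_seeds=%d", len(seeds))
    seed_r, org_r = grow_radii_um(config, cal)
    labels = segment.grow_organoids(seeds, contour, cal, seed_r, org_r,
                                    enclosed=footprints)
    labels = segment.rescue_small_contours(
        contour, labels, cal, config.min_contour_area_um2,
        config.small_organoid_max_area_um2)
    log.debug("stage=measure n_labels=%d", int(labels.max(initial=0)))
    records = measure.measure_organoids(labels, enhanced, sample, cal,
                                        config.size_class_edges_um2)
    return DetectionResult(labels=labels, records=records, enhanced=enhanced,
                           membrane_mask=mem, contour_mask=contour,
                           background_mask=background, seeds=seeds,
                           calibration=cal)
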