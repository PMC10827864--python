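"""Pipeline configuration.

Every tunable of the detection pipeline lives in :class:`PipelineConfig`,
serialized field-for-field to/from YAML.  Physical thresholds are in μm or
μm²; the pixel calibration (μm per pixel per axis) converts them to the
image grid at run time, so one config applies across magnifications.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

#: Feature families computed by default (see :mod:`organocyte.classify`).
DEFAULT_FEATURES = [
    "intensity",
    "gaussian_s1",
    "gaussian_s2",
    "gaussian_s4",
    "gaussian_s8",
    "median_r2",
    "median_r4",
    "gradient_s1",
    "gradient_s2",
    "log_s2",
    "variance_w7",
    "entropy_w7",
    "haralick_contrast_w15",
    "haralick_homogeneity_w15",
]

#: Default filename pattern: ``{plate}_{well}_{stim}_{time}`` with a
#: ``dNhM`` / ``hM`` / plain-hours time token.
DEFAULT_FILENAME_PATTERN = (
    r"^(?P<plate>[^_]+)_(?P<well>[^_]+)_(?P<stim>[^_]+)_(?P<time>[^_.]+)"
    r"(?:\.[A-Za-z0-9]+)?$"
)


@dataclass
class PipelineConfig:
    """All knobs of the organoid detection pipeline with their defaults.

    Radii and areas are physical (μm / μm²) unless the name says ``_px``.
    The two grow radii reproduce the two growing-limit knobs of the
    interactive tool this pipeline automates: ``seed_grow_radius_um``
    bounds geodesic travel from the seed centroid, ``organoid_grow_radius_um``
    bounds expansion beyond the seed boundary.
    """

    # calibration / import
    calibration_x_um: float = 1.0
    calibration_y_um: float = 1.0
    bit_depth: int = 8
    fov_enabled: bool = False
    fov_width: int = 2560
    fov_height: int = 2000
    filename_pattern: str = DEFAULT_FILENAME_PATTERN

    # preprocessing
    background_radius_px: int = 25

    # membrane detection / enhancement
    membrane_max_width_px: int = 9
    membrane_min_prominence: float = 20.0
    membrane_boost: float = 60.0

    # pixel classifier
    features: list[str] = field(default_factory=lambda: list(DEFAULT_FEATURES))
    prob_threshold: float = 0.5
    n_trees: int = 100
    max_depth: int | None = None
    max_train_pixels_per_class: int = 20000

    # contour post-processing
    min_contour_area_um2: float = 20.0
    contour_close_radius_px: int = 5

    # seed generation and gating
    seed_area_min_um2: float = 200.0
    seed_area_max_um2: float = 500_000.0
    intensity_min: float = 0.0
    intensity_max: float = 1.0e9
    ring_support_min: float = 0.6
    ring_probe_px: int = 3
    compactness_min: float = 0.3
    compactness_max: float = 1.0
    seed_smooth_radius_px: int = 2

    # growing and rescue
    seed_grow_radius_um: float = 280.0
    organoid_grow_radius_um: float = 90.0
    radii_in_px: bool = False
    small_organoid_max_area_um2: float = 2000.0

    # reporting
    size_class_edges_um2: list[float] = field(
        default_factory=lambda: [18_000.0, 60_000.0, 120_000.0]
    )

    # evaluation
    iou_min: float = 0.3

    random_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.calibration_x_um <= 0 or self.calibration_y_um <= 0:
            raise ConfigError("calibration components must be > 0")
        if self.bit_depth not in (8, 16):
            raise ConfigError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.fov_width < 1 or self.fov_height < 1:
            raise ConfigError("FOV target dimensions must be positive")
        if self.background_radius_px < 1:
            raise ConfigError("background_radius_px must be >= 1")
        if self.membrane_max_width_px < 1:
            raise ConfigError("membrane_max_width_px must be >= 1")
        if self.membrane_min_prominence <= 0:
            raise ConfigError("membrane_min_prominence must be > 0")
        if self.membrane_boost < 0:
            raise ConfigError("membrane_boost must be >= 0")
        if not 0.0 <= self.prob_threshold <= 1.0:
            raise ConfigError("prob_threshold must lie in [0, 1]")
        for name in (
            "min_contour_area_um2",
            "seed_grow_radius_um",
            "organoid_grow_radius_um",
            "small_organoid_max_area_um2",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.seed_area_min_um2 > self.seed_area_max_um2:
            raise ConfigError("seed area gate minimum exceeds maximum")
        if self.intensity_min > self.intensity_max:
            raise ConfigError("intensity gate minimum exceeds maximum")
        if not 0.0 <= self.ring_support_min <= 1.0:
            raise ConfigError("ring_support_min must lie in [0, 1]")
        if not (0.0 <= self.compactness_min <= self.compactness_max <= 1.0):
            raise ConfigError("compactness gate must satisfy 0 <= min <= max <= 1")
        if self.min_contour_area_um2 > self.small_organoid_max_area_um2:
            raise ConfigError("min_contour_area_um2 exceeds small_organoid_max_area_um2")
        edges = list(self.size_class_edges_um2)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigError("size_class_edges_um2 must be strictly increasing")
        if not 0.0 < self.iou_min <= 1.0:
            raise ConfigError("iou_min must lie in (0, 1]")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
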