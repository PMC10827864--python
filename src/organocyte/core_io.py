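"""Image and table I/O, sample identity, field-of-view normalization.

Images arrive as 8- or 16-bit TIFF/PNG/JPEG exports from live-cell imagers
(e.g. 1,536 × 1,152 px 8-bit frames).  They carry no trusted physical
calibration, so μm-per-pixel always comes from the configuration.  Every
frame must be identifiable by plate, well, stimulation and time point,
parsed from its filename.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize

from .errors import FormatError, ImageIOError, SampleIDParseError
from .config import DEFAULT_FILENAME_PATTERN


@dataclass(frozen=True)
class Calibration:
    """Physical pixel size, μm per pixel, per axis (x = columns, y = rows)."""

    x_um: float
    y_um: float

    def __post_init__(self):
        if self.x_um <= 0 or self.y_um <= 0:
            raise FormatError("calibration components must be > 0")

    @property
    def pixel_area_um2(self) -> float:
        return self.x_um * self.y_um


@dataclass
class RasterImage:
    """A raw imported frame: integer pixel grid + bit depth + calibration.

    ``pixels`` is ``(H, W)`` for grayscale or ``(H, W, 3)`` for RGB.
    """

    pixels: np.ndarray
    bit_depth: int
    calibration: Calibration

    def __post_init__(self):
        if self.pixels.ndim not in (2, 3):
            raise FormatError(f"expected 2D or 3D pixel array, got ndim={self.pixels.ndim}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise FormatError(f"3D images must have 3 channels, got {self.pixels.shape[2]}")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise FormatError("image must be at least 1x1")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass(frozen=True, order=True)
class SampleID:
    """Identity of one imaged field: plate, well, stimulation, time point."""

    plate: str
    well: str
    stimulation: str
    timepoint_hours: float

    def __post_init__(self):
        if not self.plate or not self.well:
            raise SampleIDParseError("plate and well must be non-empty")
        if self.timepoint_hours < 0:
            raise SampleIDParseError("timepoint_hours must be >= 0")

    def to_filename(self, suffix: str = ".tif") -> str:
        """Render with the default template ``{plate}_{well}_{stim}_dNhM``."""
        total = self.timepoint_hours
        d, h = divmod(total, 24.0)
        h = int(h) if float(h).is_integer() else h
        return f"{self.plate}_{self.well}_{self.stimulation}_d{int(d)}h{h}{suffix}"


_TIME_DH = re.compile(r"^d(?P<d>\d+)h(?P<h>\d+(?:\.\d+)?)$", re.IGNORECASE)
_TIME_H = re.compile(r"^h?(?P<h>\d+(?:\.\d+)?)$", re.IGNORECASE)


def _parse_time_token(token: str) -> float:
    m = _TIME_DH.match(token)
    if m:
        return int(m.group("d")) * 24.0 + float(m.group("h"))
    m = _TIME_H.match(token)
    if m:
        return float(m.group("h"))
    raise SampleIDParseError(f"cannot interpret time token {token!r}")


def parse_sample_id(filename: str, pattern: str = DEFAULT_FILENAME_PATTERN) -> SampleID:
    """Extract the plate/well/stimulation/time identity from a filename.

    ``pattern`` must define the named groups ``plate``, ``well``, ``stim``
    and ``time``; the time group accepts ``dNhM`` (days + hours), ``hM``,
    or a plain number of hours.
    """
    name = Path(filename).name
    rx = re.compile(pattern)
    required = {"plate", "well", "stim", "time"}
    missing = required - set(rx.groupindex)
    if missing:
        raise SampleIDParseError(f"pattern lacks required groups: {sorted(missing)}")
    m = rx.match(name)
    if not m:
        raise SampleIDParseError(
            f"filename {name!r} does not match the sample-ID pattern; "
            f"missing groups: {sorted(required)}"
        )
    return SampleID(
        plate=m.group("plate"),
        well=m.group("well"),
        stimulation=m.group("stim"),
        timepoint_hours=_parse_time_token(m.group("time")),
    )


def read_image(path: str | Path, calibration: Calibration) -> RasterImage:
    """Read a TIFF/PNG/JPEG frame into a :class:`RasterImage`.

    Bit depth is inferred from the sample dtype; images never carry a
    trusted physical calibration, so it is supplied by the caller.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such image file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise FormatError(f"unsupported image layout {arr.shape} in {path}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(
            f"unsupported sample format {arr.dtype} in {path}: only 8/16-bit "
            "unsigned integer images carry a declared intensity range"
        )
    return RasterImage(pixels=arr, bit_depth=depth, calibration=calibration)


def fov_correct(image: RasterImage, target: tuple[int, int]) -> RasterImage:
    """Resample a frame to the analysis grid (default 2,560 × 2,000 px).

    Bilinear interpolation; the calibration is rescaled per axis so the
    physical extent in μm is unchanged.
    """
    tw, th = target
    if tw < 1 or th < 1:
        raise FormatError("target dimensions must be positive")
    if (image.width, image.height) == (tw, th):
        return image
    out_shape = (th, tw) if image.pixels.ndim == 2 else (th, tw, 3)
    resampled = resize(
        image.pixels.astype(np.float64),
        out_shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    resampled = np.clip(np.rint(resampled), 0, image.max_value).astype(image.pixels.dtype)
    cal = Calibration(
        x_um=image.calibration.x_um * image.width / tw,
        y_um=image.calibration.y_um * image.height / th,
    )
    return RasterImage(pixels=resampled, bit_depth=image.bit_depth, calibration=cal)


RESULT_COLUMNS = [
    "plate",
    "well",
    "stimulation",
    "timepoint_hours",
    "organoid_id",
    "area_um2",
    "compactness",
    "centroid_x_um",
    "centroid_y_um",
    "size_class",
]


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Per-organoid records → tidy table, ordered by sample then organoid id."""
    rows = [
        {
            "plate": r.sample.plate,
            "well": r.sample.well,
            "stimulation": r.sample.stimulation,
            "timepoint_hours": r.sample.timepoint_hours,
            "organoid_id": r.organoid_id,
            "area_um2": r.area_um2,
            "compactness": r.compactness,
            "centroid_x_um": r.centroid_um[0],
            "centroid_y_um": r.centroid_um[1],
            "size_class": r.size_class,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["plate", "well", "stimulation", "timepoint_hours", "organoid_id"],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def write_results(records: Sequence, path: str | Path, format: str | None = None) -> None:
    """Write per-organoid measurements as CSV or XLSX (one row per organoid)."""
    path = Path(path)
    fmt = format or ("xlsx" if path.suffix.lower() == ".xlsx" else "csv")
    if fmt not in ("csv", "xlsx"):
        raise FormatError(f"unsupported results format {fmt!r}")
    df = records_to_frame(records)
    try:
        if fmt == "csv":
            df.to_csv(path, index=False, lineterminator="\n")
        else:
            df.to_excel(path, index=False, engine="openpyxl")
    except OSError as exc:
        raise ImageIOError(f"cannot write results to {path}: {exc}") from exc


def write_label_tiff(labels: np.ndarray, path: str | Path) -> None:
    """Persist a label image as 16-bit single-channel TIFF."""
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise FormatError("more labels than a 16-bit TIFF can hold")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_label_tiff(path: str | Path) -> np.ndarray:
    try:
        arr = tifffile.imread(Path(path))
    except Exception as exc:
        raise ImageIOError(f"cannot read label image {path}: {exc}") from exc
    return arr.astype(np.int32)
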