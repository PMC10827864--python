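"""Per-organoid and per-well quantification.

Area, perimeter, compactness, centroid, size class per detected organoid;
count/size/compactness summaries per well and time point.  Compactness is
the 2D isoperimetric circularity 4πA/P² — 1 for a circle, smaller for
elongated or ragged outlines.  The perimeter is the length of the
sub-pixel iso-contour of the region, smoothed along the boundary to
suppress rasterization staircase bias (a raw pixel-edge perimeter would
bias circularity of a disk down to ≈ 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import find_objects, gaussian_filter1d
from skimage.measure import find_contours

from .core_io import Calibration, SampleID
from .errors import ParameterError
from .preprocess import GrayImage

_BOUNDARY_SMOOTH_SIGMA = 2.0  # samples along the traced boundary


@dataclass
class OrganoidRecord:
    """Measurements of one detected organoid, tied to its sample identity."""

    sample: SampleID
    organoid_id: int
    area_um2: float
    perimeter_um: float
    compactness: float
    centroid_um: tuple[float, float]  # (x, y)
    size_class: str
    border_flag: bool


@dataclass
class WellSummary:
    """Aggregate readout of one well at one time point."""

    sample: SampleID
    total_count: int
    class_counts: dict[str, int]
    median_area_um2: float
    mean_compactness: float


def _boundary_length(region: np.ndarray, calibration: Calibration) -> float:
    """Smoothed iso-contour length of a binary region, in μm."""
    padded = np.pad(region, 1).astype(np.float64)
    total = 0.0
    for c in find_contours(padded, 0.5):
        closed = np.allclose(c[0], c[-1])
        pts = c[:-1] if closed else c
        if len(pts) < 3:
            continue
        mode = "wrap" if closed else "nearest"
        sm = np.column_stack([
            gaussian_filter1d(pts[:, 0], _BOUNDARY_SMOOTH_SIGMA, mode=mode),
            gaussian_filter1d(pts[:, 1], _BOUNDARY_SMOOTH_SIGMA, mode=mode),
        ])
        if closed:
            sm = np.vstack([sm, sm[:1]])
        dy = np.diff(sm[:, 0]) * calibration.y_um
        dx = np.diff(sm[:, 1]) * calibration.x_um
        total += float(np.hypot(dx, dy).sum())
    return total


def compactness(region: np.ndarray, calibration: Calibration) -> float:
    """Isoperimetric circularity 4πA/P² of a binary region, clipped to [0, 1]."""
    region = np.asarray(region, dtype=bool)
    area_px = int(region.sum())
    if area_px == 0:
        raise ParameterError("compactness of an empty region is undefined")
    area = area_px * calibration.pixel_area_um2
    perim = _boundary_length(region, calibration)
    if perim <= 0:
        return 1.0  # single-pixel-scale region: treat as maximally compact
    return float(np.clip(4.0 * np.pi * area / perim**2, 0.0, 1.0))


def size_class(area_um2: float, edges: Sequence[float]) -> str:
    """Name the size bin of an area; bins are lower-inclusive.

    With the default edges 18,000 / 60,000 / 120,000 μm² the classes are
    ``"<18000"``, ``"18000-60000"``, ``"60000-120000"``, ``">=120000"``.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ParameterError("size-class edges must be strictly increasing")

    def fmt(x: float) -> str:
        return str(int(x)) if float(x).is_integer() else str(x)

    if area_um2 < edges[0]:
        return f"<{fmt(edges[0])}"
    for lo, hi in zip(edges, edges[1:]):
        if lo <= area_um2 < hi:
            return f"{fmt(lo)}-{fmt(hi)}"
    return f">={fmt(edges[-1])}"


def size_class_names(edges: Sequence[float]) -> list[str]:
    """All class names, ordered from smallest to largest."""
    edges = list(edges)
    probes = [edges[0] - 1.0] + edges[:]
    return [size_class(p, edges) for p in probes]


def measure_organoids(labels: np.ndarray, enhanced: GrayImage,
                      sample: SampleID, calibration: Calibration,
                      size_edges: Sequence[float]) -> list[OrganoidRecord]:
    """One record per positive label, ordered by label id."""
    if labels.shape != enhanced.shape:
        raise ParameterError("label image and working image shapes differ")
    records: list[OrganoidRecord] = []
    h, w = labels.shape
    slices = find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        region = labels[sl] == lab
        area = float(region.sum()) * calibration.pixel_area_um2
        perim = _boundary_length(region, calibration)
        comp = compactness(region, calibration)
        ys, xs = np.nonzero(region)
        cy = (ys.mean() + sl[0].start) * calibration.y_um
        cx = (xs.mean() + sl[1].start) * calibration.x_um
        border = (sl[0].start == 0 or sl[1].start == 0
                  or sl[0].stop == h or sl[1].stop == w)
        records.append(OrganoidRecord(
            sample=sample, organoid_id=lab, area_um2=area,
            perimeter_um=perim, compactness=comp,
            centroid_um=(float(cx), float(cy)),
            size_class=size_class(area, size_edges), border_flag=border))
    return records


def summarize(records: Sequence[OrganoidRecord],
              size_edges: Sequence[float] | None = None) -> list[WellSummary]:
    """Group records by sample; counts, per-class counts, median area,
    mean compactness.  Groups ordered by plate, well, time point."""
    if not records:
        return []
    if size_edges is None:
        classes = sorted({r.size_class for r in records})
    else:
        classes = size_class_names(size_edges)
    by_sample: dict[SampleID, list[OrganoidRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample, []).append(r)
    out = []
    for sid in sorted(by_sample, key=lambda s: (s.plate, s.well,
                                                s.timepoint_hours, s.stimulation)):
        rs = by_sample[sid]
        counts = {c: 0 for c in classes}
        for r in rs:
            counts[r.size_class] = counts.get(r.size_class, 0) + 1
        out.append(WellSummary(
            sample=sid, total_count=len(rs), class_counts=counts,
            median_area_um2=float(np.median([r.area_um2 for r in rs])),
            mean_compactness=float(np.mean([r.compactness for r in rs]))))
    return out


def summaries_to_frame(summaries: Sequence[WellSummary]) -> pd.DataFrame:
    """Long-format per-well table: one row per well × time point."""
    rows = []
    for s in summaries:
        row = {
            "plate": s.sample.plate,
            "well": s.sample.well,
            "stimulation": s.sample.stimulation,
            "timepoint_hours": s.sample.timepoint_hours,
            "total_count": s.total_count,
            "median_area_um2": s.median_area_um2,
            "mean_compactness": s.mean_compactness,
        }
        for cls, n in s.class_counts.items():
            row[f"count_{cls}"] = n
        rows.append(row)
    return pd.DataFrame(rows)
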