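"""From masks to labeled organoids: seeds, gates, radius-limited growing.

The classifier delivers a contour mask (membranes) and a tissue mask
(everything else).  Organoid *seeds* are the small non-contour objects —
candidate inner areas (lumens) — selected by an area gate; the vast
connected tissue field and over-large clutter are excluded as background
by the same size criterion.  Seeds are then validated by the membrane ring
around them (ring support), gated on intensity and on shape compactness
after morphological smoothing, and finally grown outward on a growing mask
(seeds ∪ contours ∪ enclosed interiors) by a geodesic-distance algorithm
with two physical limits: the organoid grow radius bounds expansion beyond
the seed boundary, the seed grow radius bounds travel from the seed
centroid.  Small closed contours with no recoverable inner area are
rescued as small organoids at the end.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import (binary_dilation, binary_erosion,
                           binary_fill_holes, distance_transform_edt,
                           find_objects)
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.measure import label as cc_label
from skimage.morphology import closing as binary_closing
from skimage.morphology import disk
from skimage.morphology import opening as binary_opening

from .core_io import Calibration, RasterImage
from .errors import ParameterError
from .measure import compactness as region_compactness
from .preprocess import GrayImage


@dataclass
class SeedRegion:
    """A candidate organoid inner area (8-connected pixel set)."""

    id: int
    rows: np.ndarray
    cols: np.ndarray
    area_um2: float
    mean_intensity: float
    compactness: float
    centroid_px: tuple[float, float]  # (y, x)
    touches_border: bool
    ring_support: float | None = None

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


def _seed_from_component(seed_id: int, rows: np.ndarray, cols: np.ndarray,
                         enhanced: GrayImage, calibration: Calibration,
                         shape: tuple[int, int]) -> SeedRegion:
    h, w = shape
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    local = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    local[rows - r0, cols - c0] = True
    return SeedRegion(
        id=seed_id, rows=rows, cols=cols,
        area_um2=float(rows.size) * calibration.pixel_area_um2,
        mean_intensity=float(enhanced.pixels[rows, cols].mean()),
        compactness=region_compactness(local, calibration),
        centroid_px=(float(rows.mean()), float(cols.mean())),
        touches_border=bool(r0 == 0 or c0 == 0 or r1 == h - 1 or c1 == w - 1),
    )


def bridge_fill(contour: np.ndarray, radius_px: int) -> np.ndarray:
    """Solid organoid footprints from a possibly broken contour mask.

    Dilating a contour by ``radius_px`` seals membrane breaks up to
    ~2·radius, hole-filling recovers the solid footprint, and eroding by
    the same radius restores the outline scale.  Unlike a plain
    morphological closing of the thin contour, the bridge here is backed
    by the whole filled region, so the erosion step cannot re-open it.

    Each 8-connected contour component is bridged separately: a broken
    membrane is still one connected arc and seals its own gap, whereas
    interstitial pockets bounded by several distinct outlines must not be
    sealed into phantom inner areas.
    """
    if radius_px <= 0:
        return binary_fill_holes(contour)
    fp = disk(radius_px).astype(bool)
    out = np.zeros_like(contour, dtype=bool)
    lab, n = cc_label(contour, connectivity=2, return_num=True)
    pad = radius_px + 1
    h, w = contour.shape
    for comp, sl in enumerate(find_objects(lab), start=1):
        if sl is None:
            continue
        r0 = max(0, sl[0].start - pad)
        r1 = min(h, sl[0].stop + pad)
        c0 = max(0, sl[1].start - pad)
        c1 = min(w, sl[1].stop + pad)
        sub = lab[r0:r1, c0:c1] == comp
        dil = binary_dilation(sub, structure=fp)
        filled = binary_fill_holes(dil)
        core = binary_erosion(filled, structure=fp, border_value=0)
        out[r0:r1, c0:c1] |= core
    return out | contour


def select_background_components(tissue: np.ndarray, max_inner_area_um2: float,
                                 calibration: Calibration) -> np.ndarray:
    """Size criterion separating true background from organoid inner areas.

    Tissue components larger than the seed-area gate maximum (the
    connected culture background and over-large clutter fields) form the
    background mask to exclude; small tissue objects stay available as
    seed candidates.
    """
    if not tissue.any():
        return np.zeros_like(tissue, dtype=bool)
    lab = cc_label(tissue, connectivity=2)
    areas = np.bincount(lab.ravel())[1:] * calibration.pixel_area_um2
    big = np.concatenate([[False], areas > max_inner_area_um2])
    return big[lab]


def generate_seed_candidates(contour: np.ndarray, background: np.ndarray,
                             enhanced: GrayImage, calibration: Calibration,
                             seed_area_min_um2: float,
                             seed_area_max_um2: float) -> list[SeedRegion]:
    """Connected components of NOT contour AND NOT background, area-gated.

    Components touching the image border are kept but flagged.
    """
    if contour.shape != background.shape or contour.shape != enhanced.shape:
        raise ParameterError("masks and image must share dimensions")
    candidates = ~contour & ~background
    if not candidates.any():
        return []
    lab, n = cc_label(candidates, connectivity=2, return_num=True)
    seeds: list[SeedRegion] = []
    slices = find_objects(lab)
    next_id = 1
    for comp, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        sub = lab[sl] == comp
        area = float(sub.sum()) * calibration.pixel_area_um2
        if not seed_area_min_um2 <= area <= seed_area_max_um2:
            continue
        ys, xs = np.nonzero(sub)
        rows = ys + sl[0].start
        cols = xs + sl[1].start
        seeds.append(_seed_from_component(next_id, rows, cols, enhanced,
                                          calibration, contour.shape))
        next_id += 1
    return seeds


def validate_seeds(seeds: list[SeedRegion], contour: np.ndarray,
                   ring_support_min: float, ring_probe_px: int,
                   intensity_min: float = 0.0,
                   intensity_max: float = float("inf")) -> list[SeedRegion]:
    """Keep seeds enclosed by membrane and inside the intensity gate.

    ring_support = fraction of a seed's outer boundary pixels whose
    distance to the nearest contour pixel is ≤ ``ring_probe_px``.  The
    boundary is taken in a one-pixel-padded frame: where a region is
    clipped by the image edge its virtual outside neighbors count as
    unsupported, so frame-bounded background areas cannot masquerade as
    membrane-enclosed seeds.
    """
    if not 0.0 <= ring_support_min <= 1.0:
        raise ParameterError("ring_support_min must lie in [0, 1]")
    if not seeds:
        return []
    dist = np.pad(distance_transform_edt(~contour), 1,
                  constant_values=np.inf)
    kept: list[SeedRegion] = []
    shape = contour.shape
    struct = np.ones((3, 3), dtype=bool)
    for seed in seeds:
        m = np.pad(seed.mask(shape), 1)
        boundary = binary_dilation(m, structure=struct) & ~m
        if not boundary.any():
            support = 0.0
        else:
            support = float((dist[boundary] <= ring_probe_px).mean())
        seed = replace(seed, ring_support=support)
        if (support >= ring_support_min
                and intensity_min <= seed.mean_intensity <= intensity_max):
            kept.append(seed)
    return kept


def compactness_gate(seeds: list[SeedRegion], calibration: Calibration,
                     compactness_min: float, compactness_max: float,
                     smooth_radius_px: int,
                     image_shape: tuple[int, int]) -> list[SeedRegion]:
    """Morphologically smooth each seed (closing, then opening), keep seeds
    whose smoothed compactness falls inside the gate."""
    if not (0.0 <= compactness_min <= compactness_max <= 1.0):
        raise ParameterError("compactness gate bounds must satisfy 0<=min<=max<=1")
    out: list[SeedRegion] = []
    h, w = image_shape
    fp = disk(smooth_radius_px) if smooth_radius_px > 0 else None
    for seed in seeds:
        r0, r1 = seed.rows.min(), seed.rows.max()
        c0, c1 = seed.cols.min(), seed.cols.max()
        pad = smooth_radius_px + 1
        local = np.zeros((r1 - r0 + 1 + 2 * pad, c1 - c0 + 1 + 2 * pad), bool)
        local[seed.rows - r0 + pad, seed.cols - c0 + pad] = True
        if fp is not None:
            local = binary_opening(binary_closing(local, fp), fp)
        if not local.any():
            continue
        lab = cc_label(local, connectivity=2)
        largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        local = lab == largest
        ys, xs = np.nonzero(local)
        rows = ys + r0 - pad
        cols = xs + c0 - pad
        inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        rows, cols = rows[inside], cols[inside]
        if rows.size == 0:
            continue
        comp = region_compactness(local, calibration)
        if compactness_min <= comp <= compactness_max:
            updated = replace(
                seed, rows=rows, cols=cols,
                area_um2=float(rows.size) * calibration.pixel_area_um2,
                compactness=comp,
                centroid_px=(float(rows.mean()), float(cols.mean())))
            out.append(updated)
    return out


def _fill_label_holes(labels: np.ndarray) -> np.ndarray:
    out = labels.copy()
    for lab, sl in enumerate(find_objects(out), start=1):
        if sl is None:
            continue
        sub = out[sl] == lab
        filled = binary_fill_holes(sub)
        add = filled & (out[sl] == 0)
        out[sl][add] = lab
    return out


def grow_organoids(seeds: list[SeedRegion], contour: np.ndarray,
                   calibration: Calibration, seed_grow_radius_um: float,
                   organoid_grow_radius_um: float,
                   enclosed: np.ndarray | None = None) -> np.ndarray:
    """Expand each seed by geodesic dilation inside the growing mask.

    The growing mask is seeds ∪ contour ∪ interiors enclosed by contour
    components that contain a seed (``enclosed`` overrides the interior
    mask, e.g. with a break-bridged footprint).  A pixel joins the geodesically
    nearest seed (ties to the lower seed id) provided its geodesic
    distance from that seed's boundary is ≤ the organoid grow radius and
    from that seed's centroid is ≤ the seed grow radius; seed pixels
    always keep their own label.  Enclosed holes are filled and labels
    renumbered 1..N in seed order.
    """
    if organoid_grow_radius_um < 0 or seed_grow_radius_um < organoid_grow_radius_um:
        raise ParameterError(
            "require seed_grow_radius >= organoid_grow_radius >= 0")
    shape = contour.shape
    labels = np.zeros(shape, dtype=np.int32)
    if not seeds:
        return labels
    n = len(seeds)
    seed_lab = np.zeros(shape, dtype=np.int32)
    for i, s in enumerate(seeds, start=1):
        seed_lab[s.rows, s.cols] = i

    if enclosed is None:
        enclosed = binary_fill_holes(contour)
    interior = enclosed & ~contour
    ilab = cc_label(interior, connectivity=2)
    with_seed = np.unique(ilab[(ilab > 0) & (seed_lab > 0)])
    keep_interior = np.isin(ilab, with_seed) & (ilab > 0)
    growing = (seed_lab > 0) | contour | keep_interior

    node_of = np.full(shape, -1, dtype=np.int64)
    ys, xs = np.nonzero(growing)
    v = ys.size
    node_of[ys, xs] = np.arange(v)

    dx, dy = calibration.x_um, calibration.y_um
    diag = float(np.hypot(dx, dy))
    h, w = shape
    rows_e, cols_e, wts = [], [], []
    for dr, dc, wt in ((0, 1, dx), (1, 0, dy), (1, 1, diag), (1, -1, diag)):
        sr = slice(0, h - dr)
        tr = slice(dr, h)
        sc = slice(0, w - dc) if dc >= 0 else slice(-dc, w)
        tc = slice(dc, w) if dc >= 0 else slice(0, w + dc)
        src = node_of[sr, sc]
        dst = node_of[tr, tc]
        ok = (src >= 0) & (dst >= 0)
        rows_e.append(src[ok])
        cols_e.append(dst[ok])
        wts.append(np.full(int(ok.sum()), wt))

    # supernode per seed (distance-from-boundary source) + centroid node
    sup = v + np.arange(n)
    centroid_nodes = np.empty(n, dtype=np.int64)
    for i, s in enumerate(seeds):
        node_ids = node_of[s.rows, s.cols]
        rows_e.append(np.full(node_ids.size, sup[i]))
        cols_e.append(node_ids)
        # tiny positive weight: sparse csgraph drops explicit zeros
        wts.append(np.full(node_ids.size, 1e-9))
        d2 = (s.rows - s.centroid_px[0]) ** 2 + (s.cols - s.centroid_px[1]) ** 2
        k = int(np.argmin(d2))
        centroid_nodes[i] = node_of[s.rows[k], s.cols[k]]

    total = v + n
    graph = coo_matrix(
        (np.concatenate(wts),
         (np.concatenate(rows_e), np.concatenate(cols_e))),
        shape=(total, total)).tocsr()
    limit = max(seed_grow_radius_um, organoid_grow_radius_um) + 1e-9
    D = dijkstra(graph, directed=False,
                 indices=np.concatenate([sup, centroid_nodes]), limit=limit)
    d_boundary = D[:n, :v]
    d_centroid = D[n:, :v]

    best = np.argmin(d_boundary, axis=0)  # first minimum -> lowest seed id
    idx = np.arange(v)
    db = d_boundary[best, idx]
    dc_ = d_centroid[best, idx]
    assign = np.where(
        (db <= organoid_grow_radius_um) & (dc_ <= seed_grow_radius_um),
        best + 1, 0).astype(np.int32)
    own = seed_lab[ys, xs]
    assign = np.where(own > 0, own, assign)
    labels[ys, xs] = assign
    labels = _fill_label_holes(labels)

    # renumber consecutively, preserving seed order
    present = np.unique(labels)
    present = present[present > 0]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[present] = np.arange(1, present.size + 1)
    return remap[labels]


def rescue_small_contours(contour: np.ndarray, labels: np.ndarray,
                          calibration: Calibration,
                          min_contour_area_um2: float,
                          small_organoid_max_area_um2: float) -> np.ndarray:
    """Add small closed contours with no detected inner area as organoids.

    Contour components untouched by existing labels whose hole-filled area
    lies in [min_contour_area, small_organoid_max_area] μm² become new
    labels (their filled region).  The component must actually enclose at
    least one interior pixel: a contour with no inner area is clutter, not
    a small organoid outline.
    """
    if min_contour_area_um2 > small_organoid_max_area_um2:
        raise ParameterError("min_contour_area exceeds small_organoid_max_area")
    out = labels.copy()
    if not contour.any():
        return out
    lab_c, n = cc_label(contour, connectivity=2, return_num=True)
    next_label = int(out.max()) + 1
    for comp, sl in enumerate(find_objects(lab_c), start=1):
        if sl is None:
            continue
        sub = lab_c[sl] == comp
        if (out[sl][sub] > 0).any():
            continue
        filled = binary_fill_holes(sub)
        if filled.sum() == sub.sum():  # no enclosed interior: not a ring
            continue
        area = float(filled.sum()) * calibration.pixel_area_um2
        if min_contour_area_um2 <= area <= small_organoid_max_area_um2:
            target = filled & (out[sl] == 0)
            out[sl][target] = next_label
            next_label += 1
    return out


def label_color(label_id: int) -> tuple[int, int, int]:
    """Deterministic golden-angle color for one label id."""
    hue = (label_id * 0.6180339887498949) % 1.0
    r, g, b = colorsys.hsv_to_rgb(hue, 0.9, 1.0)
    return int(r * 255), int(g * 255), int(b * 255)


def backgate_overlay(labels: np.ndarray, image: GrayImage) -> RasterImage:
    """RGB rendering with per-label colored fills and outlines for QC."""
    if labels.shape != image.shape:
        raise ParameterError("label image and working image shapes differ")
    base = np.clip(image.pixels / max(image.max_value, 1e-12), 0, 1) * 255
    rgb = np.repeat(base[..., None], 3, axis=2)
    struct = np.ones((3, 3), dtype=bool)
    for lab, sl in enumerate(find_objects(labels), start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        color = np.asarray(label_color(lab), dtype=np.float64)
        patch = rgb[sl]
        patch[sub] = 0.65 * patch[sub] + 0.35 * color
        eroded = sub & ~binary_dilation(~sub, structure=struct)
        outline = sub & ~eroded
        patch[outline] = color
    return RasterImage(pixels=np.clip(np.rint(rgb), 0, 255).astype(np.uint8),
                       bit_depth=8, calibration=image.calibration)
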