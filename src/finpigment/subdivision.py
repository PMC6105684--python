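"""Partition the fin interior into two patch systems.

Grid scheme: 10 equal bands stacked along the base-normal axis, split
within-band along the base-parallel axis into 4/4/4/4/4/3/3/3/2/2 patches
from the base upward (33 patches); a half-band at the fin tip is ignored
because it often carries specular highlights.

Contour scheme: the Euclidean distance transform to the fin outline is cut
into five equal-width iso-distance bands; the four outer bands are split at
the medial axis into a leading-edge and a trailing-edge half, the innermost
band stays whole (9 patches).

Extents along both base axes use the pixel-count convention
(max - min + 1), so an axis-aligned rectangle of height 105 yields a band
height of exactly 10 with a 5-row ignored tip strip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from finpigment.registration import FinContour

__all__ = [
    "BaseLine",
    "GridPartition",
    "ContourPartition",
    "SubdivisionError",
    "estimate_base",
    "grid_subdivide",
    "contour_subdivide",
    "partition_summary",
    "PER_BAND_SPLITS",
    "GRID_PATCH_COUNT",
    "CONTOUR_PATCH_COUNT",
]

PER_BAND_SPLITS = (4, 4, 4, 4, 4, 3, 3, 3, 2, 2)  # base band first
GRID_PATCH_COUNT = sum(PER_BAND_SPLITS)  # 33
CONTOUR_PATCH_COUNT = 9
N_BANDS = len(PER_BAND_SPLITS)  # 10
N_DISTANCE_BANDS = 5

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


class SubdivisionError(ValueError):
    pass


@dataclass(frozen=True)
class BaseLine:
    """Fin base: anchor point, body-parallel direction, tip-ward normal."""

    point: tuple[float, float]
    direction: tuple[float, float]
    normal: tuple[float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        if not (np.isclose(np.linalg.norm(d), 1.0, atol=1e-6) and np.isclose(np.linalg.norm(n), 1.0, atol=1e-6)):
            raise SubdivisionError("direction and normal must be unit vectors")
        if abs(float(d @ n)) > 1e-6:
            raise SubdivisionError("direction and normal must be perpendicular")


@dataclass
class GridPartition:
    """Per-pixel grid-patch labels: 1..33 on the fin, 0 elsewhere."""

    labels: np.ndarray  # int16 raster
    ignored: np.ndarray  # bool raster: fin pixels in the tip strip
    band_height: float
    band_count: int = N_BANDS
    per_band_splits: tuple[int, ...] = PER_BAND_SPLITS

    @property
    def n_patches(self) -> int:
        return sum(self.per_band_splits)

    def patch_pixels(self, patch: int) -> np.ndarray:
        return self.labels == patch


@dataclass
class ContourPartition:
    """Per-pixel contour-patch labels: 1..9 on the fin, 0 elsewhere.

    Patches 1-8 are the leading/trailing halves of iso-distance bands 1-4
    (outermost first); patch 9 is the unsplit innermost band.
    """

    labels: np.ndarray
    band_width: float
    medial_axis: np.ndarray  # bool raster
    edge_side: np.ndarray  # int8: +1 leading, -1 trailing, 0 background
    distance: np.ndarray  # the distance transform (float, 0 outside fin)

    @property
    def n_patches(self) -> int:
        return CONTOUR_PATCH_COUNT

    def patch_pixels(self, patch: int) -> np.ndarray:
        return self.labels == patch


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise SubdivisionError("zero-length vector")
    return v / n


def estimate_base(
    contour: FinContour,
    body_direction_hint: tuple[float, float] | None = None,
    *,
    leading_left: bool = True,
) -> BaseLine:
    """Locate the fin base line on a contour.

    The anchor is the leading-edge inflection where the fin outline flows
    into the body (detected as a sharp turn among the lower contour points);
    if no such corner exists the chord between the two lowermost contour
    extremes is used.  The direction is the supplied hint, else the
    principal axis of the lowest 20% of contour points, oriented so the
    leading edge sits at lower base-parallel coordinate.
    """
    pts = contour.points
    y = pts[:, 1]
    ymin, ymax = float(y.min()), float(y.max())
    height = ymax - ymin
    if height <= 0:
        raise SubdivisionError("flat contour")

    if body_direction_hint is not None:
        direction = np.asarray(body_direction_hint, dtype=float)
        if not np.isclose(np.linalg.norm(direction), 1.0, atol=1e-6):
            raise SubdivisionError("body_direction_hint must be a unit vector")
    else:
        low = pts[y >= ymax - 0.2 * height]
        if len(low) < 2:
            low = pts[np.argsort(-y)[:5]]
        cov = np.cov((low - low.mean(axis=0)).T)
        _, vecs = np.linalg.eigh(cov)
        direction = _unit(vecs[:, -1])
        sign = 1.0 if leading_left else -1.0
        if sign * direction[0] < 0:
            direction = -direction

    # corner detection on the lower quarter: turn angle between neighbouring segments
    lower = y >= ymax - 0.25 * height
    prev_pts, next_pts = np.roll(pts, 1, axis=0), np.roll(pts, -1, axis=0)
    v1, v2 = pts - prev_pts, next_pts - pts
    ang1 = np.arctan2(v1[:, 1], v1[:, 0])
    ang2 = np.arctan2(v2[:, 1], v2[:, 0])
    turn = np.abs((ang2 - ang1 + np.pi) % (2 * np.pi) - np.pi)
    candidates = np.where(lower & (turn > np.deg2rad(15.0)))[0]
    t_coord = pts @ direction
    if len(candidates):
        anchor = pts[candidates[np.argmin(t_coord[candidates])]]
    else:
        warnings.warn("no base inflection found; falling back to lowermost chord", stacklevel=2)
        bottom = np.where(y >= ymax - 1.5)[0]
        anchor = pts[bottom[np.argmin(t_coord[bottom])]]

    normal = np.array([-direction[1], direction[0]])
    centroid = pts.mean(axis=0)
    if float((centroid - anchor) @ normal) < 0:
        normal = -normal
    return BaseLine(point=tuple(anchor), direction=tuple(direction), normal=tuple(normal))


def _base_coordinates(mask: np.ndarray, base: BaseLine) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Base-normal and base-parallel coordinates of fin pixels.

    Returns (rows, cols, normal_coord, parallel_coord); normal coordinates
    are shifted so their minimum over the fin is 0.
    """
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols, rows]).astype(float)  # (x, y)
    d = np.asarray(base.direction)
    n = np.asarray(base.normal)
    anchor = np.asarray(base.point)
    cn = (pts - anchor) @ n
    cn -= cn.min()
    ct = (pts - anchor) @ d
    return rows, cols, cn, ct


def grid_subdivide(
    mask: np.ndarray,
    base: BaseLine,
    *,
    include_tip: bool = False,
) -> GridPartition:
    """Assign every fin pixel a grid-patch label 1..33 (or mark it ignored).

    The fin's base-normal extent H (pixel-count convention) is cut into 10
    bands of height h = H/10.5 plus an ignored tip strip of height h/2;
    ``include_tip`` switches to h = H/10 with no ignored strip.  Within band
    k the fin pixels are split into ``PER_BAND_SPLITS[k-1]`` equal-width
    patches between that band's own extreme pixels, numbered leading to
    trailing, base band first.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SubdivisionError("empty mask")
    rows, cols, cn, ct = _base_coordinates(mask, base)
    extent = cn.max() + 1.0  # pixel-count convention
    if extent <= 1.0:
        raise SubdivisionError("fin has no base-normal extent")
    denom = float(N_BANDS) if include_tip else N_BANDS + 0.5
    h = extent / denom

    band = np.floor(cn / h).astype(int)  # 0-based
    ignored = band >= N_BANDS
    band = np.clip(band, 0, N_BANDS - 1)

    labels = np.zeros(mask.shape, dtype=np.int16)
    ignored_raster = np.zeros(mask.shape, dtype=bool)
    ignored_raster[rows[ignored], cols[ignored]] = True

    offsets = np.concatenate([[0], np.cumsum(PER_BAND_SPLITS)])
    empty_bands = []
    for k in range(N_BANDS):
        sel = (band == k) & ~ignored
        if not sel.any():
            empty_bands.append(k + 1)
            continue
        t = ct[sel]
        m = PER_BAND_SPLITS[k]
        width = (t.max() - t.min()) + 1.0
        idx = np.floor((t - t.min()) / (width / m)).astype(int)
        idx = np.clip(idx, 0, m - 1)
        labels[rows[sel], cols[sel]] = offsets[k] + idx + 1
    if empty_bands:
        warnings.warn(f"grid bands with no fin pixels: {empty_bands}", stacklevel=2)
    return GridPartition(labels=labels, ignored=ignored_raster, band_height=h)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Fin pixels with a 4-neighbour outside the mask (the pixel outline)."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=_FOUR_CONN, border_value=0)
    return mask & ~interior


def outline_distance(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance of every fin pixel to the nearest outline pixel.

    Outline pixels themselves have distance 0; the result is 0 outside the
    fin.
    """
    boundary = boundary_pixels(mask)
    dist = ndimage.distance_transform_edt(~boundary)
    return np.where(mask, dist, 0.0)


def _split_contour_arcs(contour: FinContour, base: BaseLine) -> np.ndarray:
    """Per-contour-point side: +1 leading, -1 trailing.

    The closed contour is cut at the fin tip (maximal base-normal
    coordinate) and at the base (minimal base-normal coordinate); of the two
    resulting arcs, the one with the smaller mean base-parallel coordinate
    is the leading edge.
    """
    pts = contour.points
    n = np.asarray(base.normal)
    d = np.asarray(base.direction)
    anchor = np.asarray(base.point)
    cn = (pts - anchor) @ n
    ct = (pts - anchor) @ d
    tip = int(np.argmax(cn))
    bottom = int(np.argmin(cn))
    m = len(pts)
    idx = np.arange(m)
    # arc A: indices from tip forward to bottom; arc B: the rest
    in_a = ((idx - tip) % m) <= ((bottom - tip) % m)
    side = np.empty(m, dtype=np.int8)
    mean_a = ct[in_a].mean() if in_a.any() else np.inf
    mean_b = ct[~in_a].mean() if (~in_a).any() else np.inf
    side[in_a] = 1 if mean_a <= mean_b else -1
    side[~in_a] = -1 if mean_a <= mean_b else 1
    return side


def contour_subdivide(
    mask: np.ndarray,
    contour: FinContour,
    base: BaseLine,
    *,
    medial_tolerance: float = 1.0,
) -> ContourPartition:
    """Assign every fin pixel a contour-patch label 1..9.

    The distance transform to the pixel outline is cut into five equal
    bands of width D/5 (D = maximum distance, half-open lower-inclusive
    intervals, maximal pixels into band 5).  Pixels in bands 1-4 are
    assigned to the leading or trailing half by the outline arc containing
    their nearest outline pixel; band 5 stays whole.  The medial axis is the
    set of fin pixels whose leading- and trailing-edge distances agree
    within ``medial_tolerance``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SubdivisionError("empty mask")
    dist = outline_distance(mask)
    D = float(dist[mask].max())
    if D <= 0:
        raise SubdivisionError("degenerate mask: no interior (distance transform all zero)")
    band_width = D / N_DISTANCE_BANDS
    band = np.floor(dist / band_width).astype(int)  # 0-based outermost
    band = np.clip(band, 0, N_DISTANCE_BANDS - 1)

    # side of each outline pixel = side of its nearest contour point
    boundary = boundary_pixels(mask)
    brow, bcol = np.nonzero(boundary)
    bpts = np.column_stack([bcol, brow]).astype(float)
    contour_side = _split_contour_arcs(contour, base)
    _, nearest_cpt = cKDTree(contour.points).query(bpts)
    bside = contour_side[nearest_cpt]

    # side of each fin pixel = side of its nearest outline pixel
    _, (inds_r, inds_c) = ndimage.distance_transform_edt(~boundary, return_indices=True)
    side_raster = np.zeros(mask.shape, dtype=np.int8)
    side_raster[brow, bcol] = bside
    edge_side = np.where(mask, side_raster[inds_r, inds_c], 0).astype(np.int8)

    # distances to each edge separately, for the medial axis
    lead_b = np.zeros(mask.shape, dtype=bool)
    lead_b[brow[bside == 1], bcol[bside == 1]] = True
    trail_b = np.zeros(mask.shape, dtype=bool)
    trail_b[brow[bside == -1], bcol[bside == -1]] = True
    if lead_b.any() and trail_b.any():
        d_lead = ndimage.distance_transform_edt(~lead_b)
        d_trail = ndimage.distance_transform_edt(~trail_b)
        medial = mask & (np.abs(d_lead - d_trail) <= medial_tolerance)
    else:
        medial = np.zeros(mask.shape, dtype=bool)

    labels = np.zeros(mask.shape, dtype=np.int16)
    outer = mask & (band < N_DISTANCE_BANDS - 1)
    labels[outer] = 2 * band[outer] + np.where(edge_side[outer] == 1, 1, 2)
    labels[mask & (band == N_DISTANCE_BANDS - 1)] = CONTOUR_PATCH_COUNT
    return ContourPartition(
        labels=labels,
        band_width=band_width,
        medial_axis=medial,
        edge_side=edge_side,
        distance=dist,
    )


def export_labels_png(partition: GridPartition | ContourPartition, path) -> None:
    """Write the patch-label raster as 16-bit PNG (0 = background/ignored)
    for visual QC."""
    from PIL import Image

    Image.fromarray(partition.labels.astype(np.uint16), mode="I;16").save(path)


def partition_summary(partition: GridPartition | ContourPartition) -> pd.DataFrame:
    """One row per patch (including empty ones): index, pixel count, centroid."""
    rows = []
    for patch in range(1, partition.n_patches + 1):
        sel = partition.labels == patch
        count = int(sel.sum())
        if count:
            r, c = np.nonzero(sel)
            cx, cy = float(c.mean()), float(r.mean())
        else:
            cx = cy = float("nan")
        rows.append({"patch": patch, "pixel_count": count, "centroid_x": cx, "centroid_y": cy})
    return pd.DataFrame(rows)
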