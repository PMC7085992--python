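"""Whole-psoas CT segmentation.

The muscle volume between a cranial bound (soma of D12) and a caudal bound
(the L5-S1 plane) is extracted slice by slice: each axial CT slice is
histogram-equalized within a soft-tissue HU window, edges are detected with
a Canny filter, and — because the edge chain around a muscle is rarely
already closed — an alpha-shape is used to close the contour around a
tracked point inside each psoas body. The two bodies (left/right of the
midline) are followed down the stack by centroid tracking with area-ratio
gating, and the selected per-slice polygons are rasterized into a 3-label
mask (0 background, 1 left, 2 right) on the CT grid.

The slice bounds and the two first-slice seed points stand in for the
operator's visual identification of D12 and L5-S1; everything downstream is
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
import shapely
from shapely import affinity
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
from skimage import exposure, feature

from .imaging_io import VolumeGrid

log = logging.getLogger(__name__)

SIDE_LEFT = 1
SIDE_RIGHT = 2


class SegmentationError(RuntimeError):
    """A slice/side could not be segmented and could not be recovered."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the slice-wise psoas extraction.

    Attributes
    ----------
    slice_start, slice_stop
        Half-open slice range [start, stop) to segment; the cranial and
        caudal anatomical bounds chosen by the operator.
    seeds
        Two (row, col) points on slice ``slice_start``, one inside each
        psoas body; ordered (left, right) by column after normalization.
    body_window
        HU window applied before histogram equalization; default covers
        soft tissue (fat through muscle) and saturates bone.
    canny_sigma, canny_low, canny_high
        Gaussian scale and hysteresis thresholds of the Canny detector,
        applied to the equalized [0, 1] image. With
        ``canny_relative_thresholds`` (the default) the thresholds are
        fractions of the slice's maximum gradient magnitude, which keeps
        the detector calibrated across noise levels and slice content; set
        it False for absolute thresholds on the equalized intensity scale.
    alpha
        Fixed alpha-shape parameter (1/mm of the alpha-disc radius, in
        pixel units 1/px). ``None`` auto-tunes per slice/side: the smallest
        closing radius that yields a closed contour around the tracking
        point.
    area_ratio_bounds
        Admissible ratio of a candidate's area to the previous slice's
        area for the same side; candidates outside are rejected.
    search_radius_px
        Edge points farther than this from the tracking point are ignored
        when closing a side's contour.
    k_missing
        Maximum run of consecutive per-side slice failures repaired by
        copying the nearest successfully segmented polygon.
    """

    slice_start: int
    slice_stop: int
    seeds: tuple[tuple[float, float], tuple[float, float]]
    body_window: tuple[float, float] = (-200.0, 300.0)
    canny_sigma: float = 2.0
    canny_low: float = 0.10
    canny_high: float = 0.30
    canny_relative_thresholds: bool = True
    alpha: float | None = None
    area_ratio_bounds: tuple[float, float] = (0.5, 2.0)
    search_radius_px: float = 45.0
    k_missing: int = 2

    def __post_init__(self):
        if not self.slice_start < self.slice_stop:
            raise ValueError(
                f"slice_start ({self.slice_start}) must be < slice_stop ({self.slice_stop})"
            )
        if len(self.seeds) != 2:
            raise ValueError(f"exactly two seeds required, got {len(self.seeds)}")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0 (or None for auto-tuning)")
        if not 0 < self.canny_low < self.canny_high:
            raise ValueError(
                f"need 0 < canny_low < canny_high, got {self.canny_low}, {self.canny_high}"
            )
        lo, hi = self.area_ratio_bounds
        if not 0 < lo <= 1 <= hi:
            raise ValueError(f"area_ratio_bounds must bracket 1, got {self.area_ratio_bounds}")

    def validate_for(self, ct: VolumeGrid) -> None:
        n = ct.shape[0]
        if not (0 <= self.slice_start < self.slice_stop <= n):
            raise ValueError(
                f"slice range [{self.slice_start}, {self.slice_stop}) outside volume of {n} slices"
            )


@dataclass(frozen=True)
class SideRegion:
    """One side's selected contour on one slice."""

    polygon: Polygon                    # in (col=x, row=y) pixel coordinates
    closed_by_alpha_shape: bool
    carried_over: bool = False          # repaired from a neighbouring slice

    @property
    def area_px(self) -> float:
        return self.polygon.area

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.y, c.x)  # (row, col)


@dataclass(frozen=True)
class SliceRegions:
    """Selected left/right regions on one slice (either may be missing)."""

    slice_index: int
    left: SideRegion | None
    right: SideRegion | None


@dataclass(frozen=True)
class BinaryMask3D:
    """Integer label volume {0 background, 1 left psoas, 2 right psoas}."""

    labels: np.ndarray
    grid_id: str = ""

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if not np.isin(np.unique(labels), [0, SIDE_LEFT, SIDE_RIGHT]).all():
            raise ValueError("labels must contain only {0, 1, 2}")
        object.__setattr__(self, "labels", labels.astype(np.uint8))

    def side(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def any(self) -> np.ndarray:
        return self.labels > 0

    def count(self, label: int | None = None) -> int:
        if label is None:
            return int(np.count_nonzero(self.labels))
        return int(np.count_nonzero(self.labels == label))


# ---------------------------------------------------------------------------
# Per-slice primitives
# ---------------------------------------------------------------------------

def equalize_slice(ct_slice: np.ndarray, body_window: tuple[float, float] = (-200.0, 300.0)) -> np.ndarray:
    """Global histogram equalization of one CT slice within an HU window.

    HU values are clipped to ``body_window`` first, so air and bone saturate
    and the soft-tissue range receives the full dynamic range. Output is in
    [0, 1]; a constant slice has no contrast and maps to all zeros.
    """
    s = np.asarray(ct_slice, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("CT slice contains non-finite values")
    lo, hi = body_window
    s = np.clip(s, lo, hi)
    if s.max() == s.min():
        log.info("constant CT slice: equalization returns zeros")
        return np.zeros_like(s)
    return exposure.equalize_hist(s)


def detect_edges(eq_slice: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Canny edge detection on an equalized slice.

    Returns an ``(n, 2)`` array of (row, col) edge-pixel coordinates; may be
    empty for featureless input.
    """
    img = np.asarray(eq_slice, dtype=np.float64)
    low, high = config.canny_low, config.canny_high
    if config.canny_relative_thresholds:
        # same smoothed-Sobel magnitude Canny thresholds internally
        from scipy import ndimage

        sm = ndimage.gaussian_filter(img, config.canny_sigma)
        gmax = float(np.hypot(ndimage.sobel(sm, axis=0), ndimage.sobel(sm, axis=1)).max())
        if gmax == 0.0:
            return np.empty((0, 2), dtype=int)
        low, high = low * gmax, high * gmax
    edges = feature.canny(
        img, sigma=config.canny_sigma, low_threshold=low, high_threshold=high
    )
    return np.argwhere(edges)


def _alpha_complex(points_xy: np.ndarray):
    """Delaunay triangles with their circumradii, for alpha-shape filtering."""
    tri = Delaunay(points_xy)
    simplices = tri.simplices
    a = points_xy[simplices[:, 0]]
    b = points_xy[simplices[:, 1]]
    c = points_xy[simplices[:, 2]]
    # circumradius R = abc / (4 * area)
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    area2 = np.abs(cross)  # 2 * triangle area
    with np.errstate(divide="ignore"):
        radius = np.where(area2 > 0, la * lb * lc / (2.0 * area2), np.inf)
    return simplices, radius


def _union_polygons(points_xy, simplices, keep):
    tris = [Polygon(points_xy[simplices[i]]) for i in np.flatnonzero(keep)]
    if not tris:
        return []
    u = unary_union(tris)
    if u.is_empty:
        return []
    if u.geom_type == "Polygon":
        return [u]
    return [g for g in u.geoms if g.geom_type == "Polygon"]


def _candidate_rings(polys) -> list[Polygon]:
    """Closed boundary rings of an alpha-complex union, as filled polygons.

    Both the outer boundary and any holes of the union are candidate
    regions: edge pixels form a thin band around a muscle, whose hole is
    the inner-muscle region itself.
    """
    out = []
    for p in polys:
        out.append(Polygon(p.exterior))
        for ring in p.interiors:
            q = Polygon(ring)
            if q.area > 0:
                out.append(q)
    return out


def close_region_alpha_shape(
    points: np.ndarray,
    alpha: float | None,
    seed: tuple[float, float],
) -> tuple[list[Polygon], bool, float]:
    """Close an edge-point set into candidate regions with an alpha-shape.

    Parameters
    ----------
    points
        ``(n, 2)`` array of (row, col) edge coordinates near one muscle.
    alpha
        Alpha parameter in 1/px; the alpha-disc radius is ``1/alpha``
        (``alpha -> 0`` is the convex-hull limit). ``None`` auto-tunes the
        smallest disc radius that closes a contour around ``seed``.
    seed
        (row, col) tracking point that the closed region must contain.

    Returns
    -------
    candidates
        Filled polygons (in x=col, y=row coordinates) of every closed
        boundary ring of the alpha-complex, innermost rings included.
    closed_by_alpha
        True when the raw pixel-adjacency edge chain did not already
        enclose the seed, i.e. the alpha-shape actually bridged a gap.
    radius
        The alpha-disc radius used.

    Raises
    ------
    SegmentationError
        For fewer than 3 non-collinear points, or when no closed region
        contains the seed at any admissible radius.
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 3:
        raise SegmentationError(f"need >= 3 points, got {len(pts)}")
    pts_xy = pts[:, ::-1]  # (col, row) -> shapely (x, y)
    seed_pt = Point(seed[1], seed[0])
    try:
        simplices, radii = _alpha_complex(pts_xy)
    except QhullError as e:
        raise SegmentationError(f"degenerate (collinear?) edge points: {e}") from e

    finite = radii[np.isfinite(radii)]
    if finite.size == 0:
        raise SegmentationError("all triangles degenerate")

    closed_by_alpha = not _seed_enclosed_by_pixel_chain(pts, seed)

    def encloses(r: float) -> bool:
        polys = _union_polygons(pts_xy, simplices, radii <= r)
        return any(Polygon(p.exterior).contains(seed_pt) for p in polys)

    if alpha is not None:
        r_use = 1.0 / alpha if alpha > 0 else np.inf
        if not encloses(r_use):
            raise SegmentationError(f"no closed region contains seed at radius {r_use:.2f}")
    else:
        # smallest alpha-disc radius whose complex closes around the seed;
        # the enclosing region grows monotonically with the radius
        levels = np.unique(finite)
        if not encloses(levels[-1]):
            raise SegmentationError("no closed region contains seed at any radius")
        lo_i, hi_i = 0, len(levels) - 1
        while lo_i < hi_i:
            mid = (lo_i + hi_i) // 2
            if encloses(levels[mid]):
                hi_i = mid
            else:
                lo_i = mid + 1
        r_use = float(levels[lo_i])

    polys = _union_polygons(pts_xy, simplices, radii <= r_use)
    candidates = [c for c in _candidate_rings(polys) if c.area > 0]
    return candidates, closed_by_alpha, r_use


def _seed_enclosed_by_pixel_chain(points_rc: np.ndarray, seed: tuple[float, float]) -> bool:
    """Is the seed already surrounded by the 8-connected raw edge pixels?

    Flood-fills the complement of the edge pixels from the seed on a local
    window; if the fill leaks to the window border the chain is open.
    """
    return _region_from_chain(points_rc, seed) is not None


def _region_from_chain(points_rc: np.ndarray, seed: tuple[float, float]) -> Polygon | None:
    """Region bounded by an already-closed raw edge chain around the seed.

    The free space containing the seed is flood-filled (4-connected, so
    8-connected edge chains are watertight walls); if it leaks to the
    window border the chain is open and None is returned. The returned
    polygon traces the outside of the bounding edge pixels shrunk by half
    a pixel, i.e. it passes through the edge-pixel centres, which lie on
    the gradient maxima of the true boundary.
    """
    from scipy import ndimage
    from skimage import measure

    rc = np.round(points_rc).astype(int)
    r0, c0 = rc.min(axis=0) - 2
    r1, c1 = rc.max(axis=0) + 3
    h, w = r1 - r0, c1 - c0
    walls = np.zeros((h, w), dtype=bool)
    walls[rc[:, 0] - r0, rc[:, 1] - c0] = True
    sr, sc = int(round(seed[0])) - r0, int(round(seed[1])) - c0
    if not (0 <= sr < h and 0 <= sc < w) or walls[sr, sc]:
        return None
    free, _ = ndimage.label(~walls)
    seed_lab = free[sr, sc]
    border = np.concatenate([free[0], free[-1], free[:, 0], free[:, -1]])
    if seed_lab in border:
        return None
    region = free == seed_lab
    bounded = region | (ndimage.binary_dilation(region) & walls)
    best = None
    for contour in measure.find_contours(bounded.astype(float), 0.5):
        poly = Polygon(np.column_stack([contour[:, 1], contour[:, 0]]))
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.contains(Point(sc, sr)) and (best is None or poly.area > best.area):
            best = poly
    if best is None:
        return None
    # shrink to the wall-pixel centres: a slightly interior boundary keeps
    # boundary-straddling pixels (partial-volume mixtures of muscle and
    # surrounding fat) out of the attenuation and uptake statistics
    best = best.buffer(-0.5)
    if best.is_empty:
        return None
    if best.geom_type == "MultiPolygon":
        best = max(best.geoms, key=lambda g: g.area)
    # back to full-image coordinates
    return affinity.translate(best, xoff=float(c0), yoff=float(r0))


def select_psoas_regions(
    candidates: list[Polygon],
    tracking_point: tuple[float, float],
    previous_area: float | None,
    config: SegmentationConfig,
) -> Polygon | None:
    """Pick one side's region among candidate closed polygons.

    The admissible candidates contain the tracking point and (when a
    previous slice exists) have an area within ``area_ratio_bounds`` of the
    previous area. Among nested admissible candidates the innermost
    (smallest-area) one is returned — the region corresponding to the inner
    muscle rather than any surrounding ring.
    """
    pt = Point(tracking_point[1], tracking_point[0])
    lo, hi = config.area_ratio_bounds
    admissible = []
    for c in candidates:
        if not c.contains(pt):
            continue
        if previous_area is not None:
            ratio = c.area / previous_area
            if not (lo <= ratio <= hi):
                continue
        admissible.append(c)
    if not admissible:
        return None
    return min(admissible, key=lambda c: c.area)


def rasterize_polygon(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centre lies inside the polygon.

    Pixel (r, c) has its centre at (x=c, y=r); containment uses the
    even-odd rule (shapely ``contains`` on simple polygons).
    """
    minx, miny, maxx, maxy = poly.bounds
    r0 = max(int(np.floor(miny)), 0)
    r1 = min(int(np.ceil(maxy)) + 1, shape[0])
    c0 = max(int(np.floor(minx)), 0)
    c1 = min(int(np.ceil(maxx)) + 1, shape[1])
    out = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return out
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.contains_xy(poly, cc.ravel().astype(float), rr.ravel().astype(float))
    out[r0:r1, c0:c1] = inside.reshape(rr.shape)
    return out


# ---------------------------------------------------------------------------
# Whole-stack driver
# ---------------------------------------------------------------------------

@dataclass
class _SideTrack:
    centroid: tuple[float, float]
    area: float | None = None


def segment_stack(ct: VolumeGrid, config: SegmentationConfig) -> list[SliceRegions]:
    """Run equalize -> edges -> alpha-closure -> selection over the range.

    Missing sides are repaired afterwards by copying the nearest selected
    polygon of the same side, up to ``k_missing`` consecutive slices; longer
    runs raise :class:`SegmentationError`.
    """
    config.validate_for(ct)
    seeds = sorted(config.seeds, key=lambda s: s[1])  # left = smaller column
    tracks = {SIDE_LEFT: _SideTrack(tuple(seeds[0])), SIDE_RIGHT: _SideTrack(tuple(seeds[1]))}

    raw: dict[int, dict[int, SideRegion | None]] = {}
    for s in range(config.slice_start, config.slice_stop):
        eq = equalize_slice(ct.data[s], config.body_window)
        edge_pts = detect_edges(eq, config)
        raw[s] = {}
        for side in (SIDE_LEFT, SIDE_RIGHT):
            track = tracks[side]
            region = _segment_side(edge_pts, track, config)
            raw[s][side] = region
            if region is not None:
                track.centroid = region.centroid
                track.area = region.area_px
    return _repair_missing(raw, config)


def _segment_side(edge_pts: np.ndarray, track: _SideTrack, config: SegmentationConfig) -> SideRegion | None:
    """Close and select one side's region on one slice.

    An edge chain that already encloses the tracking point is used
    directly; otherwise the alpha-shape closes the gaps (the fallback the
    method prescribes for not-closed, not-connected edges).
    """
    if len(edge_pts) < 3:
        return None
    d = np.linalg.norm(edge_pts - np.asarray(track.centroid), axis=1)
    local = edge_pts[d <= config.search_radius_px]
    if len(local) < 3:
        return None
    direct = _region_from_chain(local, track.centroid)
    if direct is not None:
        candidates, closed_by_alpha = [direct], False
    else:
        try:
            candidates, closed_by_alpha, _ = close_region_alpha_shape(
                local, config.alpha, track.centroid
            )
        except SegmentationError:
            return None
    poly = select_psoas_regions(candidates, track.centroid, track.area, config)
    if poly is None:
        return None
    return SideRegion(polygon=poly, closed_by_alpha_shape=closed_by_alpha)


def _repair_missing(
    raw: dict[int, dict[int, SideRegion | None]], config: SegmentationConfig
) -> list[SliceRegions]:
    slices = sorted(raw)
    for side in (SIDE_LEFT, SIDE_RIGHT):
        ok = [s for s in slices if raw[s][side] is not None]
        if not ok:
            raise SegmentationError(
                f"side {side}: no slice segmented in [{config.slice_start}, {config.slice_stop})"
            )
        missing = [s for s in slices if raw[s][side] is None]
        run: list[int] = []
        for s in missing + [None]:  # sentinel flushes the last run
            if run and (s is None or s != run[-1] + 1):
                if len(run) > config.k_missing:
                    raise SegmentationError(
                        f"side {side}: {len(run)} consecutive failed slices {run} "
                        f"exceed k_missing={config.k_missing}"
                    )
                run = []
            if s is not None:
                run.append(s)
        for s in missing:
            nearest = min(ok, key=lambda t: abs(t - s))
            src = raw[nearest][side]
            raw[s][side] = SideRegion(
                polygon=src.polygon, closed_by_alpha_shape=src.closed_by_alpha_shape,
                carried_over=True,
            )
            log.warning("side %d slice %d: polygon carried over from slice %d", side, s, nearest)
    return [
        SliceRegions(slice_index=s, left=raw[s][SIDE_LEFT], right=raw[s][SIDE_RIGHT])
        for s in slices
    ]


def build_mask(ct: VolumeGrid, config: SegmentationConfig, grid_id: str = "ct") -> BinaryMask3D:
    """Segment the psoas range of a CT volume into a 3-label mask."""
    regions = segment_stack(ct, config)
    labels = np.zeros(ct.shape, dtype=np.uint8)
    shape2d = ct.shape[1:]
    for sr in regions:
        left = rasterize_polygon(sr.left.polygon, shape2d)
        right = rasterize_polygon(sr.right.polygon, shape2d)
        labels[sr.slice_index][left] = SIDE_LEFT
        labels[sr.slice_index][right & ~left] = SIDE_RIGHT
    _check_sides(labels, shape2d[1])
    return BinaryMask3D(labels=labels, grid_id=grid_id)


def _check_sides(labels: np.ndarray, n_cols: int) -> None:
    mid = (n_cols - 1) / 2.0
    for s in range(labels.shape[0]):
        for side, op in ((SIDE_LEFT, np.less), (SIDE_RIGHT, np.greater)):
            cols = np.nonzero(labels[s] == side)[1]
            if cols.size and not op(cols.mean(), mid):
                log.warning("slice %d: side %d centroid on unexpected side of midline", s, side)


def qc_table(regions: list[SliceRegions]):
    """Per-slice QC rows: slice, side, area_px, closed_by_alpha_shape, carried_over."""
    import pandas as pd

    rows = []
    for sr in regions:
        for name, reg in (("left", sr.left), ("right", sr.right)):
            rows.append(
                {
                    "slice": sr.slice_index,
                    "side": name,
                    "area_px": reg.area_px if reg else np.nan,
                    "closed_by_alpha_shape": bool(reg.closed_by_alpha_shape) if reg else False,
                    "selected": reg is not None,
                    "carried_over": bool(reg.carried_over) if reg else False,
                }
            )
    return pd.DataFrame(rows)
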