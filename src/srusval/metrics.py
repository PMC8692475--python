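"""Quantitative SRUS-vs-CT comparison metrics.

Centerline dilation into ROI masks, overlap percentages (centerline arc
length and track-map area) with a mirrored-ROI null control, skeleton
centerline extraction from track maps, the 4-s.d. diameter proxy, line
intensity profiles with -3 dB peak widths, and counting of superposed
vessel bundles through the elevation slab.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
from scipy.signal import find_peaks
from skimage.morphology import dilation as _gray_dilation
from skimage.morphology import disk, skeletonize

from .coreg import SimilarityTransform3D, _resample_polyline, invert_transform
from .geometry import RasterGeometry
from .phantom import SlabGeometry
from .ulm import RegionLabelMap, TrackMap

logger = logging.getLogger(__name__)

__all__ = [
    "CenterlineSource", "Centerline2D", "DilationTable", "ROIMask",
    "IntensityProfile", "dilate_to_roi", "centerline_recovery",
    "trackmap_recovery", "mirror_roi", "skeleton_centerlines", "diameter_4sd",
    "line_profile", "width_minus_3db", "count_superposed_bundles",
]


class CenterlineSource(str, Enum):
    manual_import = "manual_import"
    skeleton = "skeleton"
    projected_ct = "projected_ct"


@dataclass
class Centerline2D:
    """Ordered 2D polyline (mm) with a vessel label and provenance."""

    points: np.ndarray
    vessel_class: str = "unknown"
    side: str = "unknown"
    source: CenterlineSource = CenterlineSource.manual_import

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 2:
            raise ValueError("centerline must have >= 2 finite 2D points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("centerline points must be finite")

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class DilationTable:
    """(vessel_class, side) -> dilation radius in mm."""

    radii: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for key, r in self.radii.items():
            if r <= 0:
                raise ValueError(f"dilation radius for {key} must be > 0")

    def radius_for(self, vessel_class: str, side: str) -> float:
        try:
            return self.radii[(vessel_class, side)]
        except KeyError:
            raise KeyError(
                f"no dilation radius for ({vessel_class}, {side})") from None


@dataclass
class ROIMask:
    """Binary ROI raster on the SRUS grid, per vessel side."""

    mask: np.ndarray
    grid: RasterGeometry
    side: str = "unknown"
    provenance: str = "original"   # or "mirrored"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid.shape):
            raise ValueError("mask shape must match its grid")


@dataclass
class IntensityProfile:
    """Samples along a line plus detected peaks and their -3 dB widths."""

    positions_mm: np.ndarray
    values: np.ndarray
    peaks: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("profile positions must be strictly increasing")


# ---------------------------------------------------------------------------
# ROI construction and overlap
# ---------------------------------------------------------------------------


def _rasterize_centerline(cl: Centerline2D, grid: RasterGeometry) -> np.ndarray:
    mask = np.zeros(grid.shape, dtype=bool)
    pts = _resample_polyline(cl.points, grid.pixel_size / 3.0)
    idx = grid.pixel_index(pts)
    h, w = grid.shape
    ok = (idx[:, 0] >= 0) & (idx[:, 0] < h) & (idx[:, 1] >= 0) & (idx[:, 1] < w)
    if not ok.all():
        warnings.warn("centerline extends outside the grid; clipped", UserWarning,
                      stacklevel=3)
    idx = idx[ok]
    mask[idx[:, 0], idx[:, 1]] = True
    return mask


def dilate_to_roi(centerlines: list[Centerline2D], table: DilationTable,
                  grid: RasterGeometry, side: str = "unknown") -> ROIMask:
    """Union of disks of each label's radius swept along the centerlines.

    Implemented as morphological dilation of the rasterized centerlines
    with a disk structuring element of the label's radius (in pixels).
    """
    total = np.zeros(grid.shape, dtype=bool)
    for cl in centerlines:
        r_mm = table.radius_for(cl.vessel_class, cl.side)
        r_px = max(int(round(r_mm / grid.pixel_size)), 1)
        base = _rasterize_centerline(cl, grid)
        if base.any():
            total |= _gray_dilation(base, disk(r_px)).astype(bool)
    return ROIMask(mask=total, grid=grid, side=side, provenance="original")


def centerline_recovery(query: list[Centerline2D], roi: ROIMask,
                        resample_step: float | None = None) -> float | None:
    """Percentage of query arc length lying on true ROI pixels.

    Evaluated at a fixed resampling step (default: half a pixel) so the
    result does not depend on vertex density. Returns None (flagged
    undefined) when the total arc length is zero.
    """
    if resample_step is None:
        resample_step = roi.grid.pixel_size / 2.0
    h, w = roi.grid.shape
    n_in = 0
    n_tot = 0
    for cl in query:
        pts = _resample_polyline(cl.points, resample_step)
        idx = roi.grid.pixel_index(pts)
        ok = (idx[:, 0] >= 0) & (idx[:, 0] < h) & (idx[:, 1] >= 0) & (idx[:, 1] < w)
        n_tot += pts.shape[0]
        sel = idx[ok]
        n_in += int(np.count_nonzero(roi.mask[sel[:, 0], sel[:, 1]]))
    if n_tot == 0:
        logger.warning("centerline_recovery: zero total arc length; undefined")
        return None
    return 100.0 * n_in / n_tot


def trackmap_recovery(track_map: TrackMap, roi: ROIMask,
                      region_filter: RegionLabelMap | None = None,
                      region_names: list[str] | None = None) -> float | None:
    """Percentage of nonzero track-map pixels (within the region filter)
    covered by the ROI. Returns None when no nonzero pixels remain."""
    if track_map.grid != roi.grid:
        raise ValueError("track map and ROI must share one grid")
    nonzero = track_map.nonzero_mask()
    if region_filter is not None and region_names is not None:
        nonzero = nonzero & region_filter.mask_for(region_names)
    n_tot = int(np.count_nonzero(nonzero))
    if n_tot == 0:
        logger.warning("trackmap_recovery: no nonzero pixels after filtering; undefined")
        return None
    n_in = int(np.count_nonzero(nonzero & roi.mask))
    return 100.0 * n_in / n_tot


def mirror_roi(roi: ROIMask, axis: str = "axial_center") -> ROIMask:
    """Reflect the ROI about the image's central axial or lateral line.

    ``axial_center`` reflects about the central vertical (axial) line,
    i.e. flips the lateral axis; ``lateral_center`` flips the axial axis.
    """
    if axis == "axial_center":
        mirrored = roi.mask[:, ::-1].copy()
    elif axis == "lateral_center":
        mirrored = roi.mask[::-1, :].copy()
    else:
        raise ValueError(f"axis must be 'axial_center' or 'lateral_center', got {axis!r}")
    return ROIMask(mask=mirrored, grid=roi.grid, side=roi.side, provenance="mirrored")


# ---------------------------------------------------------------------------
# Skeleton centerlines
# ---------------------------------------------------------------------------


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    ii, jj = np.nonzero(skel)
    pix = set(zip(ii.tolist(), jj.tolist()))
    for i, j in pix:
        g.add_node((i, j))
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                if (i + di, j + dj) in pix:
                    g.add_edge((i, j), (i + di, j + dj))
    return g


def _graph_paths(g: nx.Graph) -> list[list[tuple[int, int]]]:
    """Split the skeleton graph into maximal degree-2 paths between
    endpoints/junctions (cycles are returned as closed paths)."""
    paths = []
    specials = [n for n in g.nodes if g.degree[n] != 2]
    visited_edges = set()

    def walk(start, nxt):
        path = [start, nxt]
        while g.degree[path[-1]] == 2 and path[-1] not in specials:
            nbrs = [n for n in g.neighbors(path[-1]) if n != path[-2]]
            if not nbrs:
                break
            path.append(nbrs[0])
            if path[-1] == path[0]:
                break
        return path

    for s in specials:
        for nbr in g.neighbors(s):
            e = frozenset((s, nbr))
            if e in visited_edges:
                continue
            path = walk(s, nbr)
            for a, b in zip(path, path[1:]):
                visited_edges.add(frozenset((a, b)))
            paths.append(path)
    # pure cycles with no special nodes
    for comp in nx.connected_components(g):
        comp_edges = {frozenset(e) for e in g.subgraph(comp).edges}
        if comp_edges and not (comp_edges & visited_edges):
            start = next(iter(comp))
            nbr = next(iter(g.neighbors(start)))
            path = walk(start, nbr)
            for a, b in zip(path, path[1:]):
                visited_edges.add(frozenset((a, b)))
            paths.append(path)
    return [p for p in paths if len(p) >= 2]


def skeleton_centerlines(track_map: TrackMap, min_branch_length: float = 0.2,
                         region_filter: RegionLabelMap | None = None,
                         region_names: list[str] | None = None,
                         side: str = "unknown") -> list[Centerline2D]:
    """Centerlines from the morphological skeleton of the track map.

    Binarizes at intensity > 0 (optionally restricted to the given region
    labels), skeletonizes, decomposes the skeleton into branch paths and
    prunes branches shorter than ``min_branch_length`` (mm); remaining
    paths are returned as mm polylines.
    """
    mask = track_map.nonzero_mask()
    if region_filter is not None and region_names is not None:
        mask = mask & region_filter.mask_for(region_names)
    if not mask.any():
        warnings.warn("empty track map in region; no centerlines", UserWarning,
                      stacklevel=2)
        return []
    skel = skeletonize(mask)
    g = _skeleton_graph(skel)
    out = []
    for path in _graph_paths(g):
        idx = np.array(path, dtype=float)
        pts = track_map.grid.px_to_mm(idx)
        length = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        if length < min_branch_length:
            continue  # short spurs and junction slivers are pruned alike
        if pts.shape[0] >= 2:
            out.append(Centerline2D(points=pts, side=side,
                                    source=CenterlineSource.skeleton))
    if not out:
        warnings.warn("all skeleton branches pruned; no centerlines", UserWarning,
                      stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Diameter and profiles
# ---------------------------------------------------------------------------


def _signed_perpendicular_distances(points: np.ndarray, centerline: np.ndarray) -> np.ndarray:
    """Signed perpendicular distance of each 2D point to its nearest
    centerline segment (sign from the 2D cross product with the tangent)."""
    a = centerline[:-1]
    b = centerline[1:]
    ab = b - a
    denom = np.maximum(np.sum(ab * ab, axis=1), 1e-30)
    out = np.empty(points.shape[0])
    for k, p in enumerate(points):
        t = np.clip(np.sum((p - a) * ab, axis=1) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(proj - p, axis=1)
        i = int(np.argmin(d))
        tang = ab[i]
        rel = p - proj[i]
        sign = np.sign(tang[0] * rel[1] - tang[1] * rel[0]) or 1.0
        out[k] = sign * d[i]
    return out


def diameter_4sd(track_positions: np.ndarray, centerline: Centerline2D,
                 min_positions: int = 10) -> float | None:
    """Vessel diameter proxy: 4 x sample s.d. of the signed perpendicular
    offsets of bubble positions around the centerline. Returns None when
    fewer than ``min_positions`` positions are given."""
    pts = np.atleast_2d(np.asarray(track_positions, dtype=float))
    if pts.shape[0] < min_positions:
        logger.warning("diameter_4sd: %d positions < minimum %d; undefined",
                       pts.shape[0], min_positions)
        return None
    offsets = _signed_perpendicular_distances(pts, centerline.points)
    return float(4.0 * np.std(offsets, ddof=1))


def line_profile(image: np.ndarray, grid: RasterGeometry, p0: np.ndarray,
                 p1: np.ndarray, n_samples: int = 200) -> IntensityProfile:
    """Bilinear intensity samples at equispaced points from p0 to p1 (mm)."""
    from scipy.ndimage import map_coordinates

    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("profile endpoints must differ")
    for p in (p0, p1):
        if not grid.contains(p)[0]:
            raise ValueError(f"profile endpoint {p} outside the image")
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = p0[None, :] * (1 - ts[:, None]) + p1[None, :] * ts[:, None]
    idx = grid.mm_to_px(pts)
    vals = map_coordinates(np.asarray(image, float), idx.T, order=1, mode="nearest")
    positions = ts * np.linalg.norm(p1 - p0)
    return IntensityProfile(positions_mm=positions, values=vals)


def width_minus_3db(profile: IntensityProfile, prominence: float | None = None) -> list[dict]:
    """-3 dB (half-power on linear intensity) width of each profile peak.

    For every detected peak, the width is the distance between the two
    crossings of ``peak_value * 10**(-3/10)``, linearly interpolated
    between samples. A crossing missing on one side (peak at the profile
    boundary) yields a one-sided width flagged ``one_sided``.
    """
    v = profile.values
    x = profile.positions_mm
    if prominence is None:
        prominence = 0.1 * (float(v.max()) - float(v.min()) or 1.0)
    peak_idx, _ = find_peaks(v, prominence=prominence)
    results = []
    ratio = 10.0 ** (-3.0 / 10.0)
    for pi in sorted(peak_idx):
        level = v[pi] * ratio
        left = None
        for k in range(pi, 0, -1):
            if v[k - 1] <= level <= v[k]:
                f = (v[k] - level) / max(v[k] - v[k - 1], 1e-30)
                left = x[k] - f * (x[k] - x[k - 1])
                break
        right = None
        for k in range(pi, len(v) - 1):
            if v[k + 1] <= level <= v[k]:
                f = (v[k] - level) / max(v[k] - v[k + 1], 1e-30)
                right = x[k] + f * (x[k + 1] - x[k])
                break
        one_sided = left is None or right is None
        if left is None and right is None:
            width = None
        elif one_sided:
            half = (x[pi] - left) if right is None else (right - x[pi])
            width = 2.0 * float(half)
        else:
            width = float(right - left)
        results.append({"position_mm": float(x[pi]), "value": float(v[pi]),
                        "width_mm": width, "one_sided": one_sided})
    profile.peaks = results
    return results


# ---------------------------------------------------------------------------
# Superposed bundles
# ---------------------------------------------------------------------------


def count_superposed_bundles(centerlines3d: list[tuple[np.ndarray, dict]],
                             transform: SimilarityTransform3D, slab: SlabGeometry,
                             pixel_mm: np.ndarray, pixel_radius: float,
                             resample_step: float = 0.02) -> int:
    """Number of distinct 3D polylines whose slab-frame course passes
    within ``pixel_radius`` (in-plane) of the pixel location at any
    elevation inside the slab."""
    t_inv = invert_transform(transform)
    pixel_mm = np.asarray(pixel_mm, dtype=float)
    count = 0
    for poly, _label in centerlines3d:
        pts = _resample_polyline(np.asarray(poly, float), resample_step)
        slab_pts = t_inv.apply(pts)
        inside = slab.contains_elevation(slab_pts[:, 2])
        if not inside.any():
            continue
        d = np.linalg.norm(slab_pts[inside, :2] - pixel_mm, axis=1)
        if np.min(d) <= pixel_radius:
            count += 1
    return count
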