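"""Synthetic kidney-like vascular phantom with ground truth.

Generates a branching arterial tree with paired (offset, wider) veins and
straight parallel vasa-recta bundles, simulates microbubble transport along
the tree with pulsatile arterial flow, renders per-frame 2D contrast images
(Gaussian point-spread blobs plus noise), produces smooth periodic tissue
motion fields and speckle frames for motion estimation, and rasterizes a
contrast-cast CT-like volume — everything deterministic for a given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import RasterGeometry

__all__ = [
    "VesselClass", "Side", "FlowSense", "VesselSegment", "KidneyPhantom",
    "PhantomConfig", "SlabGeometry", "BubbleEvent", "FrameStack", "MotionField",
    "SyntheticCT", "generate_kidney_phantom", "sample_bubble_events",
    "generate_motion_field", "render_contrast_frames", "rasterize_ct",
    "generate_speckle_frames", "REGION_LABELS",
]

REGION_LABELS = (
    "background",
    "hilum",
    "segmental_or_larger_arcuate",
    "cortex",
    "outer_medulla",
    "inner_medulla",
)


class VesselClass(str, Enum):
    renal_branch = "renal_branch"
    segmental = "segmental"
    arcuate = "arcuate"
    cortical_radial = "cortical_radial"
    vasa_recta = "vasa_recta"


class Side(str, Enum):
    artery = "artery"
    vein = "vein"


class FlowSense(str, Enum):
    antegrade = "antegrade"
    retrograde = "retrograde"


TREE_CLASSES = (VesselClass.segmental, VesselClass.arcuate, VesselClass.cortical_radial)


@dataclass
class VesselSegment:
    """One labeled vessel: a 3D polyline with a constant tube radius."""

    id: int
    parent_id: int | None
    polyline: np.ndarray        # (N, 3) mm, axes (axial, lateral, elevation)
    radius: float               # mm
    vessel_class: VesselClass
    side: Side
    mean_speed: float           # mm/s
    pulsatility: float          # in [0, 1)
    flow_sense: FlowSense
    pair_id: int | None = None  # paired artery<->vein segment

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[0] < 2 or self.polyline.shape[1] != 3:
            raise ValueError(f"segment {self.id}: polyline must be (N>=2, 3)")
        if self.radius <= 0:
            raise ValueError(f"segment {self.id}: radius must be > 0")
        if not (0 <= self.pulsatility < 1):
            raise ValueError(f"segment {self.id}: pulsatility must be in [0, 1)")

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)))


@dataclass(frozen=True)
class SlabGeometry:
    """Rectangular imaging slab: in-plane extent plus an elevation thickness.

    The slab frame is the canonical (axial, lateral, elevation) frame with
    elevation 0 on the mid-plane; a point is inside the slab when
    ``-thickness/2 <= elevation < thickness/2`` (half-open upper bound).
    """

    in_plane_extent: tuple[float, float] = (15.3, 21.5)   # (axial, lateral) mm
    elevation_thickness: float = 1.8                      # mm

    def __post_init__(self) -> None:
        if self.elevation_thickness <= 0:
            raise ValueError("elevation_thickness must be > 0")

    def contains_elevation(self, e: np.ndarray) -> np.ndarray:
        half = self.elevation_thickness / 2.0
        e = np.asarray(e, dtype=float)
        return (e >= -half) & (e < half)


@dataclass(frozen=True)
class BubbleEvent:
    """One microbubble observation at one frame (ground truth)."""

    frame_index: int
    true_position: tuple[float, float, float]  # mm (axial, lateral, elevation)
    segment_id: int
    amplitude: float
    bubble_id: int = -1


EVENT_COLUMNS = ["frame", "bubble_id", "segment_id", "x_mm", "y_mm", "z_mm", "amplitude"]


@dataclass
class FrameStack:
    """Ordered 2D contrast frames on a common raster."""

    frames: np.ndarray          # (T, H, W) a.u.
    grid: RasterGeometry
    frame_rate: float = 54.0    # Hz

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if self.frames.shape[1:] != tuple(self.grid.shape):
            raise ValueError(
                f"frame shape {self.frames.shape[1:]} != grid shape {self.grid.shape}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class MotionField:
    """Per-frame 2D tissue displacement (axial, lateral) in mm.

    Either stores a dense per-frame array ``disp`` of shape (T, 2, h, w),
    or a separable field ``base`` (2, h, w) with a per-frame ``temporal``
    factor. The raster ``grid`` may be coarser than the image grid;
    sampling interpolates bilinearly with edge clamping.
    """

    grid: RasterGeometry
    smoothness_scale: float
    disp: np.ndarray | None = None        # (T, 2, h, w)
    base: np.ndarray | None = None        # (2, h, w)
    temporal: np.ndarray | None = None    # (T,)

    def __post_init__(self) -> None:
        if (self.disp is None) == (self.base is None):
            raise ValueError("provide exactly one of disp or (base, temporal)")
        if self.base is not None and self.temporal is None:
            raise ValueError("separable field requires temporal factors")

    @property
    def n_frames(self) -> int:
        return len(self.temporal) if self.disp is None else self.disp.shape[0]

    def disp_at(self, frame: int) -> np.ndarray:
        """Displacement raster (2, h, w) for one frame."""
        if self.disp is not None:
            return self.disp[frame]
        return self.base * self.temporal[frame]

    def sample(self, frame: int, pos_mm: np.ndarray) -> np.ndarray:
        """Bilinear displacement at mm positions (N, 2); edges clamped."""
        pos_mm = np.atleast_2d(np.asarray(pos_mm, dtype=float))
        idx = self.grid.mm_to_px(pos_mm)
        d = self.disp_at(frame)
        coords = idx.T  # (2, N)
        out = np.empty_like(pos_mm)
        for c in range(2):
            out[:, c] = ndimage.map_coordinates(d[c], coords, order=1, mode="nearest")
        return out

    def max_magnitude(self) -> float:
        mags = []
        for t in range(self.n_frames):
            d = self.disp_at(t)
            mags.append(float(np.max(np.hypot(d[0], d[1]))))
        return max(mags) if mags else 0.0


@dataclass
class SyntheticCT:
    """3D attenuation volume with isotropic spacing.

    ``voxels`` axes are (axial, lateral, elevation); the center of voxel
    (i, j, k) lies at ``origin + (i+0.5, j+0.5, k+0.5) * spacing``.
    """

    voxels: np.ndarray
    spacing: float = 0.0226  # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    def mm_to_index(self, pos_mm: np.ndarray) -> np.ndarray:
        """Fractional voxel indices for mm positions (..., 3)."""
        return (np.asarray(pos_mm, float) - np.asarray(self.origin)) / self.spacing - 0.5


# ---------------------------------------------------------------------------
# Phantom configuration and generation
# ---------------------------------------------------------------------------

_DEFAULT_RADII = {
    VesselClass.renal_branch: 0.45,
    VesselClass.segmental: 0.28,
    VesselClass.arcuate: 0.16,
    VesselClass.cortical_radial: 0.07,
    VesselClass.vasa_recta: 0.035,
}
_DEFAULT_SPEEDS = {
    VesselClass.renal_branch: 9.0,
    VesselClass.segmental: 7.0,
    VesselClass.arcuate: 5.0,
    VesselClass.cortical_radial: 3.0,
    VesselClass.vasa_recta: 1.5,
}
_DEFAULT_LENGTHS = {
    VesselClass.renal_branch: 2.5,
    VesselClass.segmental: 6.5,
    VesselClass.arcuate: 5.0,
    VesselClass.cortical_radial: 4.0,
    VesselClass.vasa_recta: 5.0,
}


@dataclass
class PhantomConfig:
    """Counts, radii and flow parameters for phantom generation."""

    extent: tuple[tuple[float, float], ...] = ((0.0, 15.3), (0.0, 21.5), (-2.0, 2.0))
    n_segmental: int = 4
    n_arcuate: int = 8
    n_cortical_radial: int = 10
    n_vasa_recta_bundles: int = 2
    bundle_size: int = 4
    bundle_elevation_spacing: float = 0.12   # mm between bundle lines
    radii: dict = field(default_factory=lambda: dict(_DEFAULT_RADII))
    radius_jitter: float = 0.15              # fractional
    vein_radius_factor: float = 1.6          # vein radius / paired artery radius
    vein_offset_factor: float = 2.0          # offset distance / artery radius (1.5-3)
    vein_offset_dir: tuple[float, float, float] = (0.92, 0.0, 0.39)
    speeds: dict = field(default_factory=lambda: dict(_DEFAULT_SPEEDS))
    vein_speed_factor: float = 0.6
    artery_pulsatility: float = 0.5
    cardiac_rate_hz: float = 5.0
    step: float = 0.45                       # polyline step, mm
    direction_jitter: float = 0.18           # rad per step
    elevation_jitter: float = 0.04           # rad per step
    lengths: dict = field(default_factory=lambda: dict(_DEFAULT_LENGTHS))

    def validate(self) -> None:
        size = [hi - lo for lo, hi in self.extent]
        if any(s <= 0 for s in size):
            raise ValueError(f"extent: all axes must have positive size, got {self.extent}")
        for cls, r in self.radii.items():
            if r <= 0:
                raise ValueError(f"radii[{cls}]: radius must be > 0, got {r}")
            if 2 * r >= min(size):
                raise ValueError(
                    f"radii[{cls}]: diameter {2 * r} mm does not fit extent (min size {min(size)} mm)")
        for name in ("n_segmental", "n_arcuate", "n_cortical_radial",
                     "n_vasa_recta_bundles", "bundle_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        if not (1.0 < self.vein_radius_factor):
            raise ValueError("vein_radius_factor: must be > 1 (vein wider than artery)")
        if not (0 <= self.artery_pulsatility < 1):
            raise ValueError("artery_pulsatility: must be in [0, 1)")


@dataclass
class KidneyPhantom:
    """A generated phantom: vessel segments, extent, regions and seed."""

    segments: list[VesselSegment]
    extent: tuple[tuple[float, float], ...]
    seed: int
    config: PhantomConfig | None = None

    def __post_init__(self) -> None:
        self._by_id = {s.id: s for s in self.segments}

    def segment(self, seg_id: int) -> VesselSegment:
        return self._by_id[seg_id]

    def children(self, seg_id: int) -> list[VesselSegment]:
        return [s for s in self.segments if s.parent_id == seg_id]

    def side_segments(self, side: Side) -> list[VesselSegment]:
        return [s for s in self.segments if s.side == side]

    def region_label(self, pos: np.ndarray) -> np.ndarray:
        """Region label codes for in-plane mm positions (N, 2).

        The partition is a function of (axial, lateral) only (constant in
        elevation) and covers the whole extent: a thin hilum strip at low
        lateral, a medulla block at high axial / low lateral split into
        inner and outer bands, a segmental/arcuate band, and cortex for
        the remainder.
        """
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        (a0, a1), (l0, l1), _ = self.extent
        ha, hl = a1 - a0, l1 - l0
        ax = (pos[:, 0] - a0) / ha
        la = (pos[:, 1] - l0) / hl
        labels = np.full(pos.shape[0], REGION_LABELS.index("cortex"), dtype=int)
        seg_band = (la < 0.45)
        labels[seg_band] = REGION_LABELS.index("segmental_or_larger_arcuate")
        medulla = (ax >= 0.6) & (la < 0.55)
        labels[medulla & (la >= 0.28)] = REGION_LABELS.index("outer_medulla")
        labels[medulla & (la < 0.28)] = REGION_LABELS.index("inner_medulla")
        labels[la < 0.05] = REGION_LABELS.index("hilum")
        return labels if pos.shape[0] > 1 else labels

    def validate(self) -> None:
        """Assert all phantom invariants (raises AssertionError on violation)."""
        lo = np.array([e[0] for e in self.extent])
        hi = np.array([e[1] for e in self.extent])
        for s in self.segments:
            assert np.all(s.polyline >= lo - 1e-9) and np.all(s.polyline <= hi + 1e-9), \
                f"segment {s.id} leaves extent"
            if s.parent_id is not None:
                parent = self.segment(s.parent_id)
                d = _point_to_polyline_distance(s.polyline[0], parent.polyline)
                assert d <= parent.radius + 1e-9, \
                    f"segment {s.id} start {d:.3f} mm from parent {parent.id} polyline " \
                    f"(radius {parent.radius:.3f})"
            if s.pair_id is not None and s.side == Side.artery:
                pair = self.segment(s.pair_id)
                assert s.radius < pair.radius, \
                    f"paired artery {s.id} must be narrower than vein {pair.id}"
        for side in Side:
            segs = self.side_segments(side)
            if segs:
                assert _is_connected(segs), f"{side.value} sub-tree is disconnected"


def _point_to_polyline_distance(p: np.ndarray, polyline: np.ndarray) -> float:
    a = polyline[:-1]
    b = polyline[1:]
    ab = b - a
    denom = np.maximum(np.sum(ab * ab, axis=1), 1e-30)
    t = np.clip(np.sum((p - a) * ab, axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(proj - p, axis=1)))


def _nearest_polyline_point(p: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    a = polyline[:-1]
    b = polyline[1:]
    ab = b - a
    denom = np.maximum(np.sum(ab * ab, axis=1), 1e-30)
    t = np.clip(np.sum((p - a) * ab, axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    k = int(np.argmin(np.linalg.norm(proj - p, axis=1)))
    return proj[k]


def _is_connected(segments: list[VesselSegment]) -> bool:
    ids = {s.id for s in segments}
    roots = [s.id for s in segments if s.parent_id is None or s.parent_id not in ids]
    if len(roots) != 1:
        return False
    children: dict[int, list[int]] = {}
    for s in segments:
        if s.parent_id in ids:
            children.setdefault(s.parent_id, []).append(s.id)
    seen = set()
    stack = [roots[0]]
    while stack:
        cur = stack.pop()
        if cur in seen:
            continue
        seen.add(cur)
        stack.extend(children.get(cur, []))
    return seen == ids


def _grow_polyline(rng: np.random.Generator, start: np.ndarray, direction: np.ndarray,
                   length: float, cfg: PhantomConfig, margin: float) -> np.ndarray:
    """Random-walk polyline from ``start``, steered to stay inside the extent."""
    lo = np.array([e[0] for e in cfg.extent]) + margin
    hi = np.array([e[1] for e in cfg.extent]) - margin
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    pts = [np.clip(np.asarray(start, dtype=float), lo, hi)]
    n_steps = max(2, int(round(length / cfg.step)))
    for _ in range(n_steps):
        theta = rng.normal(0.0, cfg.direction_jitter)
        ca, sa = np.cos(theta), np.sin(theta)
        d = np.array([ca * d[0] + sa * d[1], -sa * d[0] + ca * d[1], d[2]])
        d[2] += rng.normal(0.0, cfg.elevation_jitter)
        d[2] *= 0.9  # keep vessels close to the imaging plane
        d /= np.linalg.norm(d)
        p = pts[-1] + d * cfg.step
        # reflect the heading off extent walls
        for c in range(3):
            if p[c] < lo[c] or p[c] > hi[c]:
                d[c] = -d[c]
                p = pts[-1] + d * cfg.step
        pts.append(np.clip(p, lo, hi))
    return np.asarray(pts)


def _jittered_radius(rng: np.random.Generator, cfg: PhantomConfig, cls: VesselClass) -> float:
    base = cfg.radii[cls]
    r = base * (1.0 + cfg.radius_jitter * (2 * rng.random() - 1.0))
    return max(r, 1e-3)


def generate_kidney_phantom(config: PhantomConfig, seed: int) -> KidneyPhantom:
    """Generate a deterministic kidney-like phantom.

    Builds one arterial tree (renal branch -> segmental -> arcuate ->
    cortical radial) fanning from a hilum on the low-lateral side, lays
    the paired venous tree as offset parallel copies with larger radii,
    and attaches vasa-recta bundles (parallel lines stacked in elevation,
    half descending/arterial, half ascending/venous) to the deepest tree
    level present.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9e3779b9]))
    (a0, a1), (l0, l1), (e0, e1) = config.extent
    ha, hl = a1 - a0, l1 - l0
    scale = hl / 21.5  # lengths tuned for the default extent

    arteries: list[VesselSegment] = []

    def add_artery(parent_id, polyline, cls):
        seg = VesselSegment(
            id=len(arteries), parent_id=parent_id, polyline=polyline,
            radius=_jittered_radius(rng, config, cls), vessel_class=cls,
            side=Side.artery, mean_speed=config.speeds[cls],
            pulsatility=config.artery_pulsatility, flow_sense=FlowSense.antegrade)
        arteries.append(seg)
        return seg

    # root renal branch from the hilum, heading +lateral
    hilum = np.array([a0 + 0.5 * ha, l0 + 0.02 * hl, 0.0])
    root = add_artery(None, _grow_polyline(
        rng, hilum, np.array([0.0, 1.0, 0.0]),
        config.lengths[VesselClass.renal_branch] * scale, config, margin=0.1), VesselClass.renal_branch)

    def branch_from(parents: list[VesselSegment], n: int, cls: VesselClass,
                    fan_deg: float) -> list[VesselSegment]:
        out = []
        for i in range(n):
            parent = parents[i % len(parents)]
            k = rng.integers(max(1, parent.polyline.shape[0] // 3), parent.polyline.shape[0])
            start = parent.polyline[k - 1]
            # deterministic fan plus jitter, mostly toward +lateral
            frac = (i + 0.5) / n - 0.5
            ang = np.radians(2 * fan_deg * frac + rng.normal(0, 8.0))
            direction = np.array([np.sin(ang), np.cos(ang), 0.0])
            out.append(add_artery(parent.id, _grow_polyline(
                rng, start, direction, config.lengths[cls] * scale * (0.8 + 0.4 * rng.random()),
                config, margin=0.1), cls))
        return out

    segmental = branch_from([root], config.n_segmental, VesselClass.segmental, fan_deg=65.0)
    arcuate = branch_from(segmental or [root], config.n_arcuate, VesselClass.arcuate, fan_deg=55.0)
    branch_from(arcuate or segmental or [root], config.n_cortical_radial,
                VesselClass.cortical_radial, fan_deg=45.0)

    n_art = len(arteries)
    veins: list[VesselSegment] = []
    off_dir = np.asarray(config.vein_offset_dir, dtype=float)
    off_dir = off_dir / np.linalg.norm(off_dir)
    lo = np.array([a0, l0, e0]) + 0.02
    hi = np.array([a1, l1, e1]) - 0.02
    for art in arteries:
        offset = off_dir * (config.vein_offset_factor * art.radius)
        poly = np.clip(art.polyline + offset, lo, hi)
        vein = VesselSegment(
            id=art.id + n_art,
            parent_id=(art.parent_id + n_art) if art.parent_id is not None else None,
            polyline=poly, radius=art.radius * config.vein_radius_factor,
            vessel_class=art.vessel_class, side=Side.vein,
            mean_speed=art.mean_speed * config.vein_speed_factor,
            pulsatility=0.0, flow_sense=FlowSense.retrograde, pair_id=art.id)
        art.pair_id = vein.id
        veins.append(vein)
    # snap vein starts onto the parent vein polyline so the tree stays connected
    vein_by_id = {v.id: v for v in veins}
    for v in veins:
        if v.parent_id is not None:
            v.polyline = v.polyline.copy()
            v.polyline[0] = _nearest_polyline_point(v.polyline[0], vein_by_id[v.parent_id].polyline)

    segments = arteries + veins
    next_id = 2 * n_art

    # vasa recta bundles: straight parallel lines stacked in elevation,
    # descending (artery) lines attached to the artery tree, ascending (vein)
    # lines to the vein tree, heading into the medulla block (high axial,
    # low lateral).
    attach_pool_a = arcuate or segmental or [root]
    for b in range(config.n_vasa_recta_bundles):
        parent_a = attach_pool_a[b % len(attach_pool_a)]
        parent_v = vein_by_id[parent_a.pair_id]
        start_a = parent_a.polyline[parent_a.polyline.shape[0] // 2]
        target = np.array([a0 + 0.85 * ha, l0 + (0.15 + 0.25 * rng.random()) * hl, 0.0])
        direction = target - start_a
        direction = direction / np.linalg.norm(direction)
        length = config.lengths[VesselClass.vasa_recta] * scale
        n_pts = max(2, int(round(length / config.step)))
        ts = np.linspace(0.0, length, n_pts)
        radius = _jittered_radius(rng, config, VesselClass.vasa_recta)
        for k in range(config.bundle_size):
            elev = (k - (config.bundle_size - 1) / 2.0) * config.bundle_elevation_spacing
            descending = (k % 2 == 0)
            parent = parent_a if descending else parent_v
            start = _nearest_polyline_point(
                start_a if descending else start_a + off_dir * 0.0, parent.polyline)
            base = start[None, :] + ts[:, None] * direction[None, :]
            poly = base.copy()
            poly[1:, 2] += elev  # first point stays on the parent; then stack in elevation
            poly = np.clip(poly, lo, hi)
            seg = VesselSegment(
                id=next_id, parent_id=parent.id, polyline=poly,
                radius=radius if descending else radius * config.vein_radius_factor,
                vessel_class=VesselClass.vasa_recta,
                side=Side.artery if descending else Side.vein,
                mean_speed=config.speeds[VesselClass.vasa_recta]
                * (1.0 if descending else config.vein_speed_factor),
                pulsatility=config.artery_pulsatility * 0.4 if descending else 0.0,
                flow_sense=FlowSense.antegrade if descending else FlowSense.retrograde)
            segments.append(seg)
            next_id += 1
        # pair descending with the following ascending line where possible
        bundle = segments[-config.bundle_size:]
        for i in range(0, len(bundle) - 1, 2):
            bundle[i].pair_id = bundle[i + 1].id
            bundle[i + 1].pair_id = bundle[i].id

    phantom = KidneyPhantom(segments=segments, extent=config.extent, seed=int(seed),
                            config=config)
    phantom.validate()
    return phantom


# ---------------------------------------------------------------------------
# Microbubble transport
# ---------------------------------------------------------------------------


@dataclass
class _Path:
    """A concatenated centerline a bubble travels, with per-point metadata.

    The single artery-leaf -> vein-leaf connecting edge stands in for the
    below-resolution capillary bed: bubbles advance along it but emit no
    events there (``capillary`` flags that edge).
    """

    points: np.ndarray       # (M, 3)
    arclength: np.ndarray    # (M,) cumulative, mm
    segment_ids: np.ndarray  # (M,) id of the segment owning each vertex
    speeds: np.ndarray       # (M,) mean speed at each vertex, mm/s
    pulsatilities: np.ndarray
    radii: np.ndarray
    capillary: np.ndarray    # (M-1,) bool per edge

    @property
    def total_length(self) -> float:
        return float(self.arclength[-1])

    def transit_frames(self, frame_rate: float) -> float:
        ds = np.diff(self.arclength)
        v = 0.5 * (self.speeds[:-1] + self.speeds[1:])
        return float(np.sum(ds / np.maximum(v, 1e-9)) * frame_rate)


def _build_paths(phantom: KidneyPhantom, rng: np.random.Generator, n_paths: int) -> list[_Path]:
    arteries = [s for s in phantom.segments if s.side == Side.artery]
    art_ids = {s.id for s in arteries}
    children: dict[int, list[VesselSegment]] = {}
    for s in arteries:
        if s.parent_id in art_ids:
            children.setdefault(s.parent_id, []).append(s)
    roots = [s for s in arteries if s.parent_id is None or s.parent_id not in art_ids]
    by_id = {s.id: s for s in phantom.segments}

    def junction_param(child: VesselSegment, parent: VesselSegment) -> int:
        d = np.linalg.norm(parent.polyline - child.polyline[0], axis=1)
        return int(np.argmin(d))

    paths = []
    for _ in range(n_paths):
        pieces: list[tuple[VesselSegment, np.ndarray]] = []
        seg = roots[0]
        start_idx = 0
        # descend the artery tree
        while True:
            kids = children.get(seg.id, [])
            if kids:
                w = np.array([k.radius ** 2 for k in kids])
                stop_w = 0.3 * seg.radius ** 2 if seg.vessel_class != VesselClass.renal_branch else 0.0
                total = w.sum() + stop_w
                u = rng.random() * total
                if u >= w.sum():
                    pieces.append((seg, seg.polyline[start_idx:]))
                    break
                child = kids[int(np.searchsorted(np.cumsum(w), u, side="right"))]
                j = junction_param(child, seg)
                pieces.append((seg, seg.polyline[start_idx:max(j, start_idx) + 1]))
                seg, start_idx = child, 0
            else:
                pieces.append((seg, seg.polyline[start_idx:]))
                break
        # jump to the paired vein and ascend to the vein root
        leaf = seg
        if leaf.pair_id is not None:
            vseg = by_id[leaf.pair_id]
            while True:
                if vseg is by_id[leaf.pair_id]:
                    vpts = vseg.polyline[::-1]
                else:
                    vpts = vseg.polyline[:stop_idx + 1][::-1]
                pieces.append((vseg, vpts))
                if vseg.parent_id is None or vseg.parent_id not in by_id \
                        or by_id[vseg.parent_id].side != Side.vein:
                    break
                parent = by_id[vseg.parent_id]
                stop_idx = junction_param(vseg, parent)
                vseg = parent
        # concatenate, remembering where the artery->vein jump happens
        pts, sids, speeds, puls, radii = [], [], [], [], []
        n_points = 0
        jump_vertex = None
        prev_side = None
        for s, p in pieces:
            if p.shape[0] < 1:
                continue
            if pts and np.allclose(p[0], pts[-1][-1], atol=1e-9):
                p = p[1:]
            if p.shape[0] == 0:
                continue
            if prev_side == Side.artery and s.side == Side.vein:
                jump_vertex = n_points - 1
            pts.append(p)
            sids.append(np.full(p.shape[0], s.id))
            speeds.append(np.full(p.shape[0], s.mean_speed))
            puls.append(np.full(p.shape[0], s.pulsatility))
            radii.append(np.full(p.shape[0], s.radius))
            n_points += p.shape[0]
            prev_side = s.side
        points = np.concatenate(pts, axis=0)
        if points.shape[0] < 2:
            continue
        seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
        arclength = np.concatenate([[0.0], np.cumsum(seglen)])
        capillary = np.zeros(points.shape[0] - 1, dtype=bool)
        if jump_vertex is not None and 0 <= jump_vertex < capillary.shape[0]:
            capillary[jump_vertex] = True
        paths.append(_Path(points, arclength,
                           np.concatenate(sids).astype(int),
                           np.concatenate(speeds), np.concatenate(puls),
                           np.concatenate(radii), capillary))
    return paths


def _path_state(path: _Path, s: float) -> tuple[np.ndarray, np.ndarray, int, float, float, float, bool]:
    """State at arclength s: point, tangent, segment id, speed, pulsatility,
    radius, on-capillary flag. Edges are attributed to their second vertex
    (a child's first vertex lies on the parent, so the edge leaving it
    belongs to the child)."""
    al = path.arclength
    i = int(np.clip(np.searchsorted(al, s, side="right") - 1, 0, len(al) - 2))
    t = (s - al[i]) / max(al[i + 1] - al[i], 1e-12)
    p = path.points[i] * (1 - t) + path.points[i + 1] * t
    tang = path.points[i + 1] - path.points[i]
    n = np.linalg.norm(tang)
    tang = tang / n if n > 0 else np.array([0.0, 1.0, 0.0])
    j = i + 1
    return p, tang, int(path.segment_ids[j]), float(path.speeds[j]), \
        float(path.pulsatilities[j]), float(path.radii[j]), bool(path.capillary[i])


def _tube_offset(tangent: np.ndarray, rho: float, theta: float, radius: float) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(tangent, ref)) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    n1 = np.cross(tangent, ref)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(tangent, n1)
    return rho * radius * (np.cos(theta) * n1 + np.sin(theta) * n2)


def sample_bubble_events(phantom: KidneyPhantom, concentration: float, duration: float,
                         frame_rate: float, seed: int,
                         cardiac_rate_hz: float | None = None,
                         n_path_pool: int = 128) -> pd.DataFrame:
    """Simulate microbubble transport through the phantom.

    Bubbles enter at the arterial root (Poisson arrivals), advect along a
    randomly drawn root-to-leaf-to-vein-root path at the local mean speed
    modulated by ``1 + pulsatility * sin(2*pi*cardiac_rate*t)``, keep a
    fixed lateral offset within the tube for their whole lifetime, and die
    when they leave the tree. The arrival rate is calibrated so the
    expected number of concurrent bubbles per frame equals
    ``concentration``; the initial population is drawn from the stationary
    distribution so the process starts in steady state.

    Returns a DataFrame with columns
    ``frame, bubble_id, segment_id, x_mm, y_mm, z_mm, amplitude``.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    n_frames = int(round(duration * frame_rate))
    empty = pd.DataFrame({c: pd.Series(dtype=(int if c in ("frame", "bubble_id", "segment_id")
                                              else float)) for c in EVENT_COLUMNS})
    if concentration == 0 or n_frames == 0:
        return empty

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5eed]))
    if cardiac_rate_hz is None:
        cardiac_rate_hz = phantom.config.cardiac_rate_hz if phantom.config else 5.0
    paths = _build_paths(phantom, rng, n_path_pool)
    if not paths:
        return empty
    transit = np.array([p.transit_frames(frame_rate) for p in paths])
    mean_transit = float(np.mean(transit))
    arrival_rate = concentration / mean_transit  # bubbles per frame

    dt = 1.0 / frame_rate
    records: list[tuple] = []
    bubble_id = 0

    def simulate(path: _Path, s0: float, frame0: int, bid: int) -> None:
        rho = 0.85 * np.sqrt(rng.random())  # margin keeps offsets inside the tube
                                            # even on jittered junction edges
        theta = rng.random() * 2 * np.pi
        amplitude = float(np.exp(rng.normal(0.0, 0.25)))
        s = s0
        f = frame0
        while f < n_frames and s < path.total_length:
            p, tang, sid, speed, puls, radius, on_capillary = _path_state(path, s)
            if not on_capillary:
                pos = p + _tube_offset(tang, rho, theta, radius)
                records.append((f, bid, sid, pos[0], pos[1], pos[2], amplitude))
            t = f * dt
            v = speed * (1.0 + puls * np.sin(2 * np.pi * cardiac_rate_hz * t))
            s += max(v, 0.0) * dt
            f += 1

    # stationary initial population: count ~ Poisson(concentration),
    # path drawn length-biased, progress uniform in transit time
    n0 = rng.poisson(concentration)
    probs = transit / transit.sum()
    for _ in range(n0):
        k = int(rng.choice(len(paths), p=probs))
        path = paths[k]
        frac = rng.random()
        # map uniform transit-time fraction to arclength
        ds = np.diff(path.arclength)
        v = 0.5 * (path.speeds[:-1] + path.speeds[1:])
        tcum = np.concatenate([[0.0], np.cumsum(ds / np.maximum(v, 1e-9))])
        s0 = float(np.interp(frac * tcum[-1], tcum, path.arclength))
        simulate(path, s0, 0, bubble_id)
        bubble_id += 1

    for f in range(n_frames):
        for _ in range(rng.poisson(arrival_rate)):
            k = int(rng.integers(len(paths)))
            simulate(paths[k], 0.0, f, bubble_id)
            bubble_id += 1

    if not records:
        return empty
    df = pd.DataFrame.from_records(records, columns=EVENT_COLUMNS)
    df = df.sort_values(["frame", "bubble_id"], kind="stable").reset_index(drop=True)
    df.attrs["frame_rate"] = frame_rate
    df.attrs["n_frames"] = n_frames
    return df


# ---------------------------------------------------------------------------
# Motion fields and frame rendering
# ---------------------------------------------------------------------------


def generate_motion_field(grid: RasterGeometry, n_frames: int, amplitude: float,
                          period: int, smoothness_scale: float, seed: int) -> MotionField:
    """Smooth, periodic, divergence-free-ish random tissue motion.

    The field is separable: a spatially smooth random base pattern times a
    sinusoid of the given frame period. The base is normalized so the
    displacement magnitude never exceeds ``amplitude`` and the discrete
    spatial gradient never exceeds ``amplitude / smoothness_scale``.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if period <= 0:
        raise ValueError("period must be > 0")
    if smoothness_scale <= 0:
        raise ValueError("smoothness_scale must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x307]))
    h, w = grid.shape
    temporal = np.sin(2 * np.pi * np.arange(n_frames) / period)
    if amplitude == 0:
        base = np.zeros((2, h, w))
        return MotionField(grid=grid, smoothness_scale=smoothness_scale,
                           base=base, temporal=temporal)
    sigma_px = max(smoothness_scale / grid.pixel_size, 1.0)
    base = np.stack([ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma_px)
                     for _ in range(2)])
    mag = np.hypot(base[0], base[1])
    max_mag = float(mag.max()) or 1.0
    grads = np.concatenate([np.gradient(base[c]) for c in range(2)])
    max_grad = float(np.max(np.abs(grads))) / grid.pixel_size or 1.0
    scale = min(amplitude / max_mag, (amplitude / smoothness_scale) / max(max_grad, 1e-12))
    base *= scale
    return MotionField(grid=grid, smoothness_scale=smoothness_scale,
                       base=base, temporal=temporal)


def render_contrast_frames(events: pd.DataFrame, slab: SlabGeometry, grid: RasterGeometry,
                           psf_sigma: float, noise_level: float,
                           motion: MotionField | None, seed: int,
                           frame_rate: float = 54.0,
                           n_frames: int | None = None) -> tuple[FrameStack, pd.DataFrame]:
    """Render contrast frames from bubble events.

    Each event whose elevation lies inside the slab and whose in-plane
    position lies inside the raster contributes an isotropic Gaussian blob
    of width ``psf_sigma`` (mm) centered at its in-plane position displaced
    by the motion field; i.i.d. Gaussian noise of the stated level is
    added. Returns the stack and the motion-free ground-truth in-plane
    positions of the rendered events.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    if n_frames is None:
        n_frames = int(events.attrs.get("n_frames", 0)) or \
            (int(events["frame"].max()) + 1 if len(events) else 1)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xf4a3e]))
    h, w = grid.shape
    frames = np.zeros((n_frames, h, w), dtype=np.float32)
    gt_rows = []
    if len(events):
        inplane = events[["x_mm", "y_mm"]].to_numpy(float)
        in_slab = slab.contains_elevation(events["z_mm"].to_numpy(float))
        in_grid = grid.contains(inplane)
        keep = in_slab & in_grid
        ev = events.loc[keep]
        half = int(np.ceil(4 * psf_sigma / grid.pixel_size))
        win = np.arange(-half, half + 1)
        for row in ev.itertuples(index=False):
            f = int(row.frame)
            if f >= n_frames:
                continue
            pos = np.array([row.x_mm, row.y_mm])
            drawn = pos.copy()
            if motion is not None:
                drawn = pos + motion.sample(f, pos)[0]
            ci, cj = grid.mm_to_px(drawn)
            i0, j0 = int(round(ci)), int(round(cj))
            ii = i0 + win
            jj = j0 + win
            mi = (ii >= 0) & (ii < h)
            mj = (jj >= 0) & (jj < w)
            if not mi.any() or not mj.any():
                continue
            ax = grid.origin[0] + (ii[mi] + 0.5) * grid.pixel_size
            la = grid.origin[1] + (jj[mj] + 0.5) * grid.pixel_size
            da = ax - drawn[0]
            dl = la - drawn[1]
            blob = row.amplitude * np.exp(-(da[:, None] ** 2 + dl[None, :] ** 2)
                                          / (2 * psf_sigma ** 2))
            frames[f][np.ix_(ii[mi], jj[mj])] += blob.astype(np.float32)
            gt_rows.append((f, int(row.bubble_id), int(row.segment_id),
                            row.x_mm, row.y_mm, row.amplitude))
    if noise_level > 0:
        frames += rng.normal(0.0, noise_level, size=frames.shape).astype(np.float32)
    gt = pd.DataFrame.from_records(
        gt_rows, columns=["frame", "bubble_id", "segment_id", "x_mm", "y_mm", "amplitude"])
    stack = FrameStack(frames=frames, grid=grid, frame_rate=frame_rate)
    return stack, gt


def generate_speckle_frames(grid: RasterGeometry, motion: MotionField | None,
                            n_frames: int, seed: int,
                            correlation_px: float = 2.0) -> FrameStack:
    """B-mode-like speckle frames: spatially correlated Rayleigh texture
    advected by the motion field (for motion-estimation testing)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xb40de]))
    h, w = grid.shape
    re = ndimage.gaussian_filter(rng.standard_normal((h, w)), correlation_px)
    im = ndimage.gaussian_filter(rng.standard_normal((h, w)), correlation_px)
    base = np.hypot(re, im)
    base /= base.std()
    frames = np.empty((n_frames, h, w), dtype=np.float32)
    ii, jj = np.mgrid[0:h, 0:w].astype(float)
    for t in range(n_frames):
        if motion is None:
            frames[t] = base
            continue
        d = motion.disp_at(t)
        # tissue displaced by d: frame(x) = base(x - d(x))
        coords = np.stack([ii - d[0] / grid.pixel_size, jj - d[1] / grid.pixel_size])
        frames[t] = ndimage.map_coordinates(base, coords, order=3, mode="reflect")
    return FrameStack(frames=frames, grid=grid)


# ---------------------------------------------------------------------------
# Synthetic CT rasterization
# ---------------------------------------------------------------------------


def rasterize_ct(phantom: KidneyPhantom, spacing: float, noise_level: float, seed: int,
                 contrast_level: float = 1.0, background_level: float = 0.0) -> SyntheticCT:
    """Voxelize the phantom's vessel tubes into a CT-like volume.

    A voxel gets the contrast intensity when its center lies within the
    tube radius of any segment polyline; everything else is background.
    Gaussian noise of the stated level is added on top.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    radii = [s.radius for s in phantom.segments]
    if radii and spacing > min(radii):
        warnings.warn(
            f"CT spacing {spacing} mm exceeds the smallest vessel radius "
            f"{min(radii):.4f} mm; thin vessels may voxelize broken or not at all",
            UserWarning, stacklevel=2)
    if not phantom.segments:
        warnings.warn("phantom has no segments; returning background-only volume",
                      UserWarning, stacklevel=2)
    lo = np.array([e[0] for e in phantom.extent])
    hi = np.array([e[1] for e in phantom.extent])
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    mask = np.zeros(tuple(shape), dtype=bool)

    for seg in phantom.segments:
        r = seg.radius
        for a, b in zip(seg.polyline[:-1], seg.polyline[1:]):
            lo_mm = np.minimum(a, b) - r
            hi_mm = np.maximum(a, b) + r
            i0 = np.maximum(np.floor((lo_mm - lo) / spacing - 0.5).astype(int), 0)
            i1 = np.minimum(np.ceil((hi_mm - lo) / spacing + 0.5).astype(int) + 1, shape)
            if np.any(i0 >= i1):
                continue
            grids = np.meshgrid(*[lo[c] + (np.arange(i0[c], i1[c]) + 0.5) * spacing
                                  for c in range(3)], indexing="ij")
            pts = np.stack(grids, axis=-1)
            ab = b - a
            denom = max(float(ab @ ab), 1e-30)
            t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            d2 = np.sum((pts - proj) ** 2, axis=-1)
            sub = mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
            sub |= d2 <= r * r
            mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] = sub

    vol = np.where(mask, np.float32(contrast_level), np.float32(background_level))
    if noise_level > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xc7]))
        vol = vol + rng.normal(0.0, noise_level, size=vol.shape).astype(np.float32)
    return SyntheticCT(voxels=vol, spacing=spacing, origin=tuple(lo))
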