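"""Super-resolution ultrasound processing chain.

Bubble localization (threshold + intensity-weighted centroid), block-matching
speckle-tracking motion estimation, motion compensation, Kalman-gated track
linking with optimal bipartite assignment, super-resolution track-map
rendering, flow-direction artery/vein separation, and track statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import match_template

from .geometry import RasterGeometry, direction_deg, wrap_angle_deg
from .phantom import FrameStack, MotionField

logger = logging.getLogger(__name__)

__all__ = [
    "Detection", "TrackingParams", "Track", "TrackMap", "Subregion",
    "RegionLabelMap", "localize_bubbles", "estimate_motion",
    "compensate_detections", "link_tracks", "render_track_maps",
    "separate_by_flow", "track_statistics",
]


@dataclass
class Detection:
    """One localized bubble in one frame; position in mm (axial, lateral)."""

    frame_index: int
    position: np.ndarray
    amplitude: float
    compensated: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class TrackingParams:
    """Linking gates and Kalman noise for the constant-velocity tracker."""

    max_link_distance: float = 278.0   # micrometres
    min_track_frames: int = 3
    process_noise: float = 1e-4        # mm^2, acceleration-driven state noise
    measurement_noise: float = 1e-4    # mm^2, localization variance

    def __post_init__(self) -> None:
        if self.max_link_distance <= 0:
            raise ValueError("max_link_distance must be > 0")
        if self.min_track_frames < 2:
            raise ValueError("min_track_frames must be >= 2")

    @property
    def gate_mm(self) -> float:
        return self.max_link_distance / 1000.0


@dataclass
class Track:
    """An ordered microbubble trajectory over strictly consecutive frames."""

    detections: list[Detection]
    frame_rate: float = 54.0

    def __post_init__(self) -> None:
        frames = [d.frame_index for d in self.detections]
        if len(frames) < 2:
            raise ValueError("a track needs at least 2 detections")
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly consecutive")

    @property
    def positions(self) -> np.ndarray:
        return np.array([d.position for d in self.detections])

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame_index for d in self.detections])

    @property
    def n_links(self) -> int:
        return len(self.detections) - 1

    @property
    def link_vectors(self) -> np.ndarray:
        return np.diff(self.positions, axis=0)

    @property
    def link_lengths_um(self) -> np.ndarray:
        return np.linalg.norm(self.link_vectors, axis=1) * 1000.0

    @property
    def path_length_um(self) -> float:
        return float(self.link_lengths_um.sum())

    @property
    def velocities(self) -> np.ndarray:
        """Per-link velocity vectors, mm/s."""
        return self.link_vectors * self.frame_rate

    @property
    def speeds(self) -> np.ndarray:
        return np.linalg.norm(self.velocities, axis=1)

    @property
    def mean_direction_deg(self) -> float:
        v = self.link_vectors.sum(axis=0)
        return float(direction_deg(v[0], v[1]))


@dataclass
class TrackMap:
    """Super-resolution rasters of track counts, flow direction and speed."""

    intensity: np.ndarray            # bubble-track counts per pixel
    direction: np.ndarray            # degrees in (-180, 180], NaN where empty
    speed: np.ndarray                # mm/s, NaN where empty
    grid: RasterGeometry
    display_dynamic_range_db: float = 40.0

    def __post_init__(self) -> None:
        if not (self.intensity.shape == self.direction.shape == self.speed.shape):
            raise ValueError("intensity/direction/speed shapes must match")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")

    def nonzero_mask(self) -> np.ndarray:
        return self.intensity > 0


@dataclass
class Subregion:
    """A labeled sub-area with a known local arterial flow direction."""

    mask: np.ndarray
    arterial_reference_direction_deg: float


@dataclass
class RegionLabelMap:
    """Region labels over the SRUS raster plus flow-reference subregions."""

    labels: np.ndarray                      # int codes into label_names
    label_names: tuple[str, ...]
    subregions: list[Subregion]
    grid: RasterGeometry

    def label_code(self, name: str) -> int:
        return self.label_names.index(name)

    def mask_for(self, names: list[str]) -> np.ndarray:
        codes = [self.label_code(n) for n in names]
        return np.isin(self.labels, codes)

    def subregion_at(self, pos_mm: np.ndarray) -> int | None:
        """Index of the subregion containing an mm position, or None."""
        idx = self.grid.pixel_index(np.asarray(pos_mm))
        h, w = self.grid.shape
        i, j = int(idx[0]), int(idx[1])
        if not (0 <= i < h and 0 <= j < w):
            return None
        for k, sub in enumerate(self.subregions):
            if sub.mask[i, j]:
                return k
        return None


# ---------------------------------------------------------------------------
# Localization
# ---------------------------------------------------------------------------


def localize_bubbles(frame: np.ndarray, grid: RasterGeometry,
                     threshold: float = 0.5, absolute: bool = False,
                     frame_index: int = 0) -> list[Detection]:
    """Threshold + connected-component intensity-weighted centroid detection.

    ``threshold`` is a fraction of the frame maximum by default, or an
    absolute amplitude when ``absolute=True``. Sub-pixel centroids are
    returned in mm. An all-zero (or all-below-threshold) frame yields an
    empty list.
    """
    frame = np.asarray(frame, dtype=float)
    fmax = float(frame.max()) if frame.size else 0.0
    thr = threshold if absolute else threshold * fmax
    if absolute and fmax > 0 and threshold > fmax:
        warnings.warn(f"threshold {threshold} exceeds frame max {fmax}",
                      UserWarning, stacklevel=2)
    if fmax <= 0:
        return []
    mask = frame >= thr
    if not mask.any():
        return []
    labels, n = ndimage.label(mask)
    detections = []
    # weight by the above-threshold excess: continuous at the mask boundary,
    # which removes the truncation bias of a hard-masked centroid
    excess = np.where(mask, frame - thr, 0.0)
    coms = ndimage.center_of_mass(excess, labels, range(1, n + 1))
    sums = ndimage.sum_labels(np.where(mask, frame, 0.0), labels, range(1, n + 1))
    for (ci, cj), amp in zip(coms, sums):
        pos = grid.px_to_mm(np.array([ci, cj]))
        detections.append(Detection(frame_index=frame_index, position=pos,
                                    amplitude=float(amp)))
    return detections


# ---------------------------------------------------------------------------
# Motion estimation / compensation
# ---------------------------------------------------------------------------


def _ncc_peak(ref_patch: np.ndarray, window: np.ndarray) -> tuple[float, float, float]:
    """Normalized cross-correlation of a patch over a search window.

    Returns (di, dj, peak_value) with parabolic sub-pixel refinement;
    displacements are offsets of the patch inside the window relative to
    its centered location.
    """
    ph, pw = ref_patch.shape
    wh, ww = window.shape
    nh, nw = wh - ph + 1, ww - pw + 1
    if ref_patch.std() < 1e-12:
        return 0.0, 0.0, -np.inf
    scores = match_template(window, ref_patch, pad_input=False)
    assert scores.shape == (nh, nw)
    k = np.unravel_index(np.argmax(scores), scores.shape)
    peak = scores[k]
    if not np.isfinite(peak):
        return 0.0, 0.0, -np.inf
    off = (nh - 1) / 2.0
    if peak > 1.0 - 1e-9:  # exact match: integer alignment, no refinement
        return float(k[0]) - off, float(k[1]) - (nw - 1) / 2.0, float(peak)

    def parabolic(sm1, s0, sp1):
        denom = sm1 - 2 * s0 + sp1
        if abs(denom) < 1e-12:
            return 0.0
        return float(np.clip(0.5 * (sm1 - sp1) / denom, -0.5, 0.5))

    di, dj = float(k[0]), float(k[1])
    if 0 < k[0] < nh - 1 and np.isfinite(scores[k[0] - 1, k[1]]) and np.isfinite(scores[k[0] + 1, k[1]]):
        di += parabolic(scores[k[0] - 1, k[1]], peak, scores[k[0] + 1, k[1]])
    if 0 < k[1] < nw - 1 and np.isfinite(scores[k[0], k[1] - 1]) and np.isfinite(scores[k[0], k[1] + 1]):
        dj += parabolic(scores[k[0], k[1] - 1], peak, scores[k[0], k[1] + 1])
    return di - off, dj - (nw - 1) / 2.0, float(peak)


def _inpaint_nan(a: np.ndarray) -> np.ndarray:
    """Fill NaNs from valid neighbors (nearest-valid)."""
    if not np.isnan(a).any():
        return a
    if np.isnan(a).all():
        return np.zeros_like(a)
    mask = np.isnan(a)
    idx = ndimage.distance_transform_edt(mask, return_distances=False, return_indices=True)
    return a[tuple(idx)]


def estimate_motion(bmode_frames: FrameStack, reference_index: int = 0,
                    block_size: int = 16, search_radius: int = 6,
                    block_stride: int | None = None,
                    smoothness_scale: float = 2.0,
                    min_correlation: float = 0.3,
                    min_texture_std: float = 1e-6) -> MotionField:
    """Block-matching speckle tracking against a reference frame.

    For each block center, the reference patch is matched inside a search
    window of the moving frame by normalized cross-correlation with
    parabolic sub-pixel peak interpolation. Flat-texture or low-correlation
    blocks are marked invalid and inpainted from neighbors. The per-frame
    displacement rasters live on the coarse block-center grid (mm units);
    sampling interpolates to arbitrary positions.
    """
    frames = bmode_frames.frames
    grid = bmode_frames.grid
    t_total, h, w = frames.shape
    if not (0 <= reference_index < t_total):
        raise ValueError(f"reference_index {reference_index} out of range")
    if block_size >= min(h, w):
        raise ValueError("block_size must be smaller than the frame")
    stride = block_stride or max(block_size // 2, 1)
    half = block_size // 2
    centers_i = np.arange(half + search_radius, h - half - search_radius, stride)
    centers_j = np.arange(half + search_radius, w - half - search_radius, stride)
    if len(centers_i) == 0 or len(centers_j) == 0:
        raise ValueError("frame too small for block_size + search_radius")
    ref = frames[reference_index].astype(float)

    disp = np.zeros((t_total, 2, len(centers_i), len(centers_j)), dtype=np.float32)
    for t in range(t_total):
        if t == reference_index:
            continue
        mov = frames[t].astype(float)
        di = np.full((len(centers_i), len(centers_j)), np.nan)
        dj = np.full_like(di, np.nan)
        for a, ci in enumerate(centers_i):
            for b, cj in enumerate(centers_j):
                patch = ref[ci - half:ci + half, cj - half:cj + half]
                if patch.std() < min_texture_std:
                    continue
                window = mov[ci - half - search_radius:ci + half + search_radius,
                             cj - half - search_radius:cj + half + search_radius]
                oi, oj, score = _ncc_peak(patch, window)
                if score < min_correlation:
                    continue
                di[a, b] = oi
                dj[a, b] = oj
        di = _inpaint_nan(di)
        dj = _inpaint_nan(dj)
        if smoothness_scale > 0:
            sig = smoothness_scale / (grid.pixel_size * stride)
            di = ndimage.gaussian_filter(di, sig)
            dj = ndimage.gaussian_filter(dj, sig)
        disp[t, 0] = di * grid.pixel_size
        disp[t, 1] = dj * grid.pixel_size

    coarse = RasterGeometry(
        shape=(len(centers_i), len(centers_j)),
        pixel_size=stride * grid.pixel_size,
        origin=(grid.origin[0] + (centers_i[0] - stride / 2 + 0.5) * grid.pixel_size,
                grid.origin[1] + (centers_j[0] - stride / 2 + 0.5) * grid.pixel_size))
    return MotionField(grid=coarse, smoothness_scale=smoothness_scale, disp=disp)


def compensate_detections(detections: list[Detection], motion: MotionField) -> list[Detection]:
    """Shift each detection back by the local displacement estimate."""
    out = []
    for det in detections:
        d = motion.sample(det.frame_index, det.position[None, :])[0]
        out.append(Detection(frame_index=det.frame_index,
                             position=det.position - d,
                             amplitude=det.amplitude, compensated=True))
    return out


# ---------------------------------------------------------------------------
# Kalman-gated track linking
# ---------------------------------------------------------------------------


class _KalmanTrack:
    """Constant-velocity Kalman state over (axial, lateral)."""

    F = None  # set lazily

    def __init__(self, det: Detection, params: TrackingParams):
        self.dets = [det]
        self.x = np.array([det.position[0], det.position[1], 0.0, 0.0])
        q, r = params.process_noise, params.measurement_noise
        self.P = np.diag([r, r, 25 * params.gate_mm ** 2, 25 * params.gate_mm ** 2])
        self.Q = q * np.diag([0.25, 0.25, 1.0, 1.0])
        self.R = r * np.eye(2)
        self.H = np.zeros((2, 4))
        self.H[0, 0] = self.H[1, 1] = 1.0
        self.Fm = np.eye(4)
        self.Fm[0, 2] = self.Fm[1, 3] = 1.0  # dt = 1 frame

    def predict(self) -> np.ndarray:
        self.x = self.Fm @ self.x
        self.P = self.Fm @ self.P @ self.Fm.T + self.Q
        return self.x[:2]

    def update(self, det: Detection) -> None:
        z = det.position
        y = z - self.H @ self.x
        s = self.H @ self.P @ self.H.T + self.R
        k = self.P @ self.H.T @ np.linalg.inv(s)
        self.x = self.x + k @ y
        self.P = (np.eye(4) - k @ self.H) @ self.P
        self.dets.append(det)


def link_tracks(detections_by_frame: dict[int, list[Detection]] | list[list[Detection]],
                params: TrackingParams, frame_rate: float = 54.0) -> list[Track]:
    """Link per-frame detections into tracks.

    Per frame, every active track predicts its next position with a
    constant-velocity Kalman filter; predicted positions are matched to
    detections by globally optimal bipartite assignment on Euclidean
    distance, rejecting any pair whose detection lies farther than the
    linking gate from the track's last detection. Unassigned detections
    seed new candidate tracks; unmatched tracks are closed (no coasting —
    track frames must be consecutive). Closed tracks shorter than
    ``min_track_frames`` are discarded.
    """
    if isinstance(detections_by_frame, dict):
        items = sorted(detections_by_frame.items())
    else:
        items = list(enumerate(detections_by_frame))
    gate = params.gate_mm
    active: list[_KalmanTrack] = []
    finished: list[_KalmanTrack] = []
    prev_frame: int | None = None
    BIG = 1e9

    def close_all():
        finished.extend(active)
        active.clear()

    for frame, dets in items:
        if prev_frame is not None and frame != prev_frame + 1:
            close_all()
        prev_frame = frame
        if not active:
            active.extend(_KalmanTrack(d, params) for d in dets)
            continue
        preds = np.array([t.predict() for t in active])
        if dets:
            dpos = np.array([d.position for d in dets])
            cost = np.linalg.norm(preds[:, None, :] - dpos[None, :, :], axis=2)
            last = np.array([t.dets[-1].position for t in active])
            link_len = np.linalg.norm(last[:, None, :] - dpos[None, :, :], axis=2)
            infeasible = link_len > gate
            cost = np.where(infeasible, BIG, cost)
            rows, cols = linear_sum_assignment(cost)
            matched_tracks, matched_dets = set(), set()
            for r, c in zip(rows, cols):
                if cost[r, c] >= BIG:
                    continue
                active[r].update(dets[c])
                matched_tracks.add(r)
                matched_dets.add(c)
        else:
            matched_tracks, matched_dets = set(), set()
        next_active = [t for i, t in enumerate(active) if i in matched_tracks]
        finished.extend(t for i, t in enumerate(active) if i not in matched_tracks)
        for c, d in enumerate(dets):
            if c not in matched_dets:
                next_active.append(_KalmanTrack(d, params))
        active = next_active
    close_all()

    tracks = []
    n_short = 0
    for kt in finished:
        if len(kt.dets) < params.min_track_frames:
            n_short += 1
            continue
        tr = Track(detections=kt.dets, frame_rate=frame_rate)
        assert np.all(tr.link_lengths_um <= params.max_link_distance + 1e-6), \
            "gate invariant violated: emitted link exceeds max_link_distance"
        tracks.append(tr)
    logger.info("link_tracks: kept %d tracks, discarded %d below %d frames",
                len(tracks), n_short, params.min_track_frames)
    return tracks


# ---------------------------------------------------------------------------
# Track-map rendering
# ---------------------------------------------------------------------------


def _link_pixels(p0: np.ndarray, p1: np.ndarray, grid: RasterGeometry) -> np.ndarray:
    """Integer pixel indices traversed by segment p0->p1 (dense sampling)."""
    length = np.linalg.norm(p1 - p0)
    n = max(int(np.ceil(length / (grid.pixel_size / 3.0))) + 1, 2)
    ts = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] * (1 - ts[:, None]) + p1[None, :] * ts[:, None]
    idx = grid.pixel_index(pts)
    h, w = grid.shape
    ok = (idx[:, 0] >= 0) & (idx[:, 0] < h) & (idx[:, 1] >= 0) & (idx[:, 1] < w)
    idx = idx[ok]
    if idx.shape[0] == 0:
        return idx
    keep = np.ones(idx.shape[0], dtype=bool)
    keep[1:] = np.any(idx[1:] != idx[:-1], axis=1)
    return idx[keep]


def render_track_maps(tracks: list[Track], grid: RasterGeometry,
                      display_dynamic_range_db: float = 40.0) -> TrackMap:
    """Rasterize tracks into intensity / direction / speed maps.

    Intensity counts distinct track traversals per pixel. Direction is the
    circular (vector) mean of traversing link directions; speed the mean
    link speed; both NaN where no track passes. Tracks reaching outside
    the extent are clipped and counted partially.
    """
    h, w = grid.shape
    intensity = np.zeros((h, w), dtype=np.int64)
    vec_ax = np.zeros((h, w))
    vec_la = np.zeros((h, w))
    speed_sum = np.zeros((h, w))
    n_contrib = np.zeros((h, w), dtype=np.int64)
    for tr in tracks:
        pos = tr.positions
        speeds = tr.speeds
        track_pixels: set[tuple[int, int]] = set()
        for k in range(tr.n_links):
            idx = _link_pixels(pos[k], pos[k + 1], grid)
            if idx.shape[0] == 0:
                continue
            v = pos[k + 1] - pos[k]
            nv = np.linalg.norm(v)
            u = v / nv if nv > 0 else np.zeros(2)
            for i, j in idx:
                track_pixels.add((i, j))
                vec_ax[i, j] += u[0]
                vec_la[i, j] += u[1]
                speed_sum[i, j] += speeds[k]
                n_contrib[i, j] += 1
        for i, j in track_pixels:
            intensity[i, j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = direction_deg(vec_ax, vec_la)
        direction[n_contrib == 0] = np.nan
        speed = np.where(n_contrib > 0, speed_sum / np.maximum(n_contrib, 1), np.nan)
    return TrackMap(intensity=intensity, direction=direction, speed=speed, grid=grid,
                    display_dynamic_range_db=display_dynamic_range_db)


# ---------------------------------------------------------------------------
# Flow separation and statistics
# ---------------------------------------------------------------------------


def separate_by_flow(tracks: list[Track], regions: RegionLabelMap) -> tuple[list[Track], list[Track]]:
    """Partition tracks into (artery, vein) by local arterial flow direction.

    Each track is assigned to the subregion where the majority of its
    detections fall; it is an artery track when the angle between its mean
    direction and that subregion's arterial reference direction is < 90
    degrees, a vein track otherwise. No track is dropped; tracks with no
    resolvable subregion fall back to the nearest subregion center.
    """
    arteries: list[Track] = []
    veins: list[Track] = []
    centers = []
    for sub in regions.subregions:
        ii, jj = np.nonzero(sub.mask)
        centers.append(regions.grid.px_to_mm(
            np.array([ii.mean(), jj.mean()])) if len(ii) else np.array([np.inf, np.inf]))
    for tr in tracks:
        votes: dict[int, int] = {}
        for det in tr.detections:
            k = regions.subregion_at(det.position)
            if k is not None:
                votes[k] = votes.get(k, 0) + 1
        if votes:
            best = max(votes, key=lambda k: (votes[k], -k))
            if len(votes) > 1:
                logger.debug("track spans %d subregions; majority -> %d", len(votes), best)
        else:
            mean_pos = tr.positions.mean(axis=0)
            dists = [np.linalg.norm(mean_pos - c) for c in centers]
            best = int(np.argmin(dists)) if centers else None
            logger.debug("track outside all subregions; nearest -> %s", best)
        if best is None:
            veins.append(tr)
            continue
        ref = regions.subregions[best].arterial_reference_direction_deg
        dang = abs(wrap_angle_deg(tr.mean_direction_deg - ref))
        (arteries if dang < 90.0 else veins).append(tr)
    return arteries, veins


def track_statistics(tracks: list[Track]) -> dict:
    """Summary statistics: counts, links, median path length, speed quantiles."""
    if not tracks:
        return {"n_tracks": 0, "n_links": 0, "median_path_length_um": None,
                "speed_quantiles_mm_s": None, "undefined": True}
    lengths = np.array([t.path_length_um for t in tracks])
    speeds = np.concatenate([t.speeds for t in tracks])
    return {
        "n_tracks": len(tracks),
        "n_links": int(sum(t.n_links for t in tracks)),
        "median_path_length_um": float(np.median(lengths)),
        "speed_quantiles_mm_s": {
            "q25": float(np.quantile(speeds, 0.25)),
            "q50": float(np.quantile(speeds, 0.50)),
            "q75": float(np.quantile(speeds, 0.75)),
        },
        "undefined": False,
    }
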