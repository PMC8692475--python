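"""2D-slab to 3D-volume similarity co-registration.

A similarity transform (rotation + isotropic scale + translation) maps
slab-frame coordinates (axial, lateral, elevation) to volume coordinates:
``x' = s * R @ x + t``. Fitting from landmark pairs uses the closed-form
least-squares solution via the cross-covariance SVD. Slab MIPs sample the
volume with trilinear interpolation along the elevation segment of each
in-plane pixel; centerline projection maps volume polylines back to the
slab with the inverse transform, splitting them where they exit the slab.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import RasterGeometry
from .phantom import SlabGeometry, SyntheticCT

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityTransform3D", "SlabGeometry", "LandmarkPair", "fit_similarity",
    "invert_transform", "slab_mip", "project_centerlines_to_plane",
]


@dataclass(frozen=True)
class SimilarityTransform3D:
    """x' = scale * R @ x + t with R in SO(3), scale > 0, t in mm."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if np.max(np.abs(r.T @ r - np.eye(3))) > 1e-9:
            raise ValueError("rotation must be orthonormal (R^T R = I within 1e-9)")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "SimilarityTransform3D":
        return cls(rotation=np.eye(3), scale=1.0, translation=np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.scale * pts @ self.rotation.T + self.translation

    def compose(self, other: "SimilarityTransform3D") -> "SimilarityTransform3D":
        """self after other: (self o other)(x) = self(other(x))."""
        return SimilarityTransform3D(
            rotation=self.rotation @ other.rotation,
            scale=self.scale * other.scale,
            translation=self.scale * self.rotation @ other.translation + self.translation)

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.ravel().tolist(),
                "scale": float(self.scale),
                "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform3D":
        return cls(rotation=np.asarray(d["rotation"], float).reshape(3, 3),
                   scale=float(d["scale"]),
                   translation=np.asarray(d["translation"], float))


@dataclass(frozen=True)
class LandmarkPair:
    """Corresponding points: slab frame (elevation 0 for in-plane) <-> volume."""

    point_slab: tuple[float, float, float]
    point_volume: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.point_slab)) and np.all(np.isfinite(self.point_volume))):
            raise ValueError("landmark coordinates must be finite")


def fit_similarity(pairs: list[LandmarkPair]) -> tuple[SimilarityTransform3D, float]:
    """Closed-form least-squares similarity fit (Umeyama).

    Returns the transform mapping slab points to volume points and the RMS
    residual in mm. Requires at least three non-collinear pairs.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 landmark pairs, got {len(pairs)}")
    src = np.array([p.point_slab for p in pairs], dtype=float)
    dst = np.array([p.point_volume for p in pairs], dtype=float)
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    cs = src - mu_s
    cd = dst - mu_d
    var_s = float((cs ** 2).sum() / len(pairs))
    if var_s < 1e-24:
        raise ValueError("degenerate landmarks: all source points coincide")
    # collinearity check: rank of centered source cloud
    sv = np.linalg.svd(cs, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate landmarks: source points are collinear")
    cov = cd.T @ cs / len(pairs)
    u, d, vt = np.linalg.svd(cov)
    s_mat = np.eye(3)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        s_mat[2, 2] = -1.0
    rot = u @ s_mat @ vt
    scale = float(np.trace(np.diag(d) @ s_mat) / var_s)
    if scale <= 0:
        raise ValueError("degenerate landmarks: non-positive fitted scale")
    trans = mu_d - scale * rot @ mu_s
    transform = SimilarityTransform3D(rotation=rot, scale=scale, translation=trans)
    resid = transform.apply(src) - dst
    rms = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    return transform, rms


def invert_transform(t: SimilarityTransform3D) -> SimilarityTransform3D:
    """Inverse similarity: x = R^T (x' - t) / s."""
    rot_inv = t.rotation.T
    scale_inv = 1.0 / t.scale
    return SimilarityTransform3D(rotation=rot_inv, scale=scale_inv,
                                 translation=-scale_inv * rot_inv @ t.translation)


def slab_mip(volume: SyntheticCT, transform: SimilarityTransform3D, slab: SlabGeometry,
             grid: RasterGeometry, step: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Maximum intensity projection of the volume through the slab.

    For each in-plane pixel center, samples the volume (trilinear) along
    the elevation segment of length ``elevation_thickness`` mapped through
    the transform, and takes the maximum. Samples outside the volume never
    win (treated as -inf); pixels whose samples all fall outside are
    marked invalid. Returns (mip, valid_mask).
    """
    if step is None:
        step = volume.spacing / 2.0
    if step > volume.spacing:
        raise ValueError("step must be <= voxel spacing")
    half = slab.elevation_thickness / 2.0
    n_e = max(int(np.ceil(slab.elevation_thickness / step)) + 1, 2)
    elevations = np.linspace(-half, half, n_e, endpoint=False) + \
        slab.elevation_thickness / (2 * n_e)
    ax, la = grid.grid_mm()
    aa, ll = np.meshgrid(ax, la, indexing="ij")
    h, w = grid.shape
    mip = np.full((h, w), -np.inf)
    any_inside = np.zeros((h, w), dtype=bool)
    shape = np.array(volume.voxels.shape, dtype=float)
    for e in elevations:
        pts = np.stack([aa.ravel(), ll.ravel(), np.full(aa.size, e)], axis=1)
        vol_pts = transform.apply(pts)
        idx = volume.mm_to_index(vol_pts)
        inside = np.all((idx >= 0.0) & (idx <= shape - 1.0), axis=1)
        vals = ndimage.map_coordinates(volume.voxels.astype(float), idx.T,
                                       order=1, mode="constant", cval=0.0)
        vals = np.where(inside, vals, -np.inf).reshape(h, w)
        mip = np.maximum(mip, vals)
        any_inside |= inside.reshape(h, w)
    if not any_inside.any():
        raise ValueError("slab lies entirely outside the volume")
    mip = np.where(any_inside, mip, np.nan)
    return mip, any_inside


def project_centerlines_to_plane(
        centerlines: list[tuple[np.ndarray, dict]],
        t_inv: SimilarityTransform3D,
        slab: SlabGeometry,
        resample_step: float | None = 0.05) -> list[tuple[np.ndarray, dict]]:
    """Project labeled 3D polylines (volume frame) onto the slab plane.

    Each polyline is resampled, mapped to the slab frame with the inverse
    transform, gated on elevation (half-open: -t/2 <= e < t/2) and split
    into in-slab runs; the elevation coordinate is then dropped. Labels
    are carried through. Polylines entirely outside the slab contribute
    nothing (logged).
    """
    out: list[tuple[np.ndarray, dict]] = []
    for poly, label in centerlines:
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 3 or poly.shape[0] < 2:
            raise ValueError("each centerline must be an (N>=2, 3) polyline")
        pts = poly if resample_step is None else _resample_polyline(poly, resample_step)
        slab_pts = t_inv.apply(pts)
        inside = slab.contains_elevation(slab_pts[:, 2])
        if not inside.any():
            logger.info("centerline %s entirely outside the slab", label)
            continue
        # split into consecutive in-slab runs
        edges = np.flatnonzero(np.diff(inside.astype(int)))
        starts = [0] if inside[0] else []
        starts += [int(e) + 1 for e in edges if inside[e + 1]]
        ends = [int(e) + 1 for e in edges if inside[e]]
        if inside[-1]:
            ends.append(len(inside))
        for s0, s1 in zip(starts, ends):
            run = slab_pts[s0:s1, :2]
            if run.shape[0] >= 2:
                out.append((run, dict(label)))
    return out


def _resample_polyline(poly: np.ndarray, step: float) -> np.ndarray:
    seglen = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total <= 0:
        return poly.copy()
    n = max(int(np.ceil(total / step)) + 1, 2)
    s = np.linspace(0.0, total, n)
    cols = [np.interp(s, arclen, poly[:, c]) for c in range(poly.shape[1])]
    return np.stack(cols, axis=1)
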