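"""File interchange: TIFF stacks with JSON sidecars, NIfTI volumes,
CSV detections/tracks/landmarks, JSON phantoms, transforms and centerlines.

All metadata required to interpret an array (pixel size, frame rate,
origin, spacing) is mandatory on import; nothing is ever guessed.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .coreg import SimilarityTransform3D
from .geometry import RasterGeometry
from .phantom import (FlowSense, FrameStack, KidneyPhantom, Side, SyntheticCT,
                      VesselClass, VesselSegment)

PHANTOM_SCHEMA_VERSION = 1

__all__ = [
    "save_frame_stack", "load_frame_stack", "save_ct_nifti", "load_ct_nifti",
    "save_ct_tiff", "load_ct_tiff", "save_phantom_json", "load_phantom_json",
    "save_events_csv", "load_events_csv", "save_tracks_csv",
    "save_transform_json", "load_transform_json", "save_centerlines_json",
    "load_centerlines_json", "load_landmarks_csv", "save_trackmap_tiff",
    "load_trackmap_tiff",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


# -- frame stacks -----------------------------------------------------------


def save_frame_stack(stack: FrameStack, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    meta = {
        "pixel_size_mm": stack.grid.pixel_size,
        "origin_mm": list(stack.grid.origin),
        "frame_rate_hz": stack.frame_rate,
        "shape": list(stack.frames.shape),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def load_frame_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("pixel_size_mm", "frame_rate_hz"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing required key {key!r}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if "shape" in meta and tuple(meta["shape"]) != frames.shape:
        raise ValueError(
            f"sidecar shape {tuple(meta['shape'])} does not match TIFF shape {frames.shape}")
    grid = RasterGeometry(shape=frames.shape[1:], pixel_size=float(meta["pixel_size_mm"]),
                          origin=tuple(meta.get("origin_mm", (0.0, 0.0))))
    return FrameStack(frames=frames, grid=grid, frame_rate=float(meta["frame_rate_hz"]))


# -- CT volumes -------------------------------------------------------------


def save_ct_nifti(ct: SyntheticCT, path: str | Path) -> None:
    affine = np.diag([ct.spacing] * 3 + [1.0])
    affine[:3, 3] = np.asarray(ct.origin) + 0.5 * ct.spacing  # voxel-center origin
    nib.save(nib.Nifti1Image(ct.voxels.astype(np.float32), affine), str(path))


def load_ct_nifti(path: str | Path) -> SyntheticCT:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"volume {path} has no positive voxel spacing in its header")
    if max(zooms) - min(zooms) > 1e-6:
        raise ValueError(f"volume {path} is not isotropic: spacings {zooms}")
    affine = img.affine
    origin = affine[:3, 3] - 0.5 * zooms[0]
    return SyntheticCT(voxels=np.asarray(img.dataobj, dtype=np.float32),
                       spacing=float(zooms[0]), origin=tuple(float(o) for o in origin))


def save_ct_tiff(ct: SyntheticCT, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, ct.voxels, photometric="minisblack")
    meta = {"spacing_mm": ct.spacing, "origin_mm": list(ct.origin),
            "shape": list(ct.voxels.shape)}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def load_ct_tiff(path: str | Path) -> SyntheticCT:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "spacing_mm" not in meta:
        raise ValueError(f"sidecar {sidecar} missing required key 'spacing_mm'")
    voxels = tifffile.imread(path)
    return SyntheticCT(voxels=voxels, spacing=float(meta["spacing_mm"]),
                       origin=tuple(meta.get("origin_mm", (0.0, 0.0, 0.0))))


# -- phantom ----------------------------------------------------------------


def save_phantom_json(phantom: KidneyPhantom, path: str | Path) -> None:
    doc = {
        "schema_version": PHANTOM_SCHEMA_VERSION,
        "seed": phantom.seed,
        "extent_mm": [list(e) for e in phantom.extent],
        "segments": [
            {
                "id": s.id,
                "parent_id": s.parent_id,
                "polyline_mm": s.polyline.tolist(),
                "radius_mm": s.radius,
                "vessel_class": s.vessel_class.value,
                "side": s.side.value,
                "mean_speed_mm_s": s.mean_speed,
                "pulsatility": s.pulsatility,
                "flow_sense": s.flow_sense.value,
                "pair_id": s.pair_id,
            }
            for s in phantom.segments
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_phantom_json(path: str | Path) -> KidneyPhantom:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != PHANTOM_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported phantom schema version {doc.get('schema_version')!r}")
    segments = [
        VesselSegment(
            id=d["id"], parent_id=d["parent_id"],
            polyline=np.asarray(d["polyline_mm"], float), radius=d["radius_mm"],
            vessel_class=VesselClass(d["vessel_class"]), side=Side(d["side"]),
            mean_speed=d["mean_speed_mm_s"], pulsatility=d["pulsatility"],
            flow_sense=FlowSense(d["flow_sense"]), pair_id=d.get("pair_id"))
        for d in doc["segments"]
    ]
    return KidneyPhantom(segments=segments,
                         extent=tuple(tuple(e) for e in doc["extent_mm"]),
                         seed=int(doc["seed"]))


# -- events / tracks --------------------------------------------------------


def save_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def load_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"frame", "x_mm", "y_mm", "z_mm", "bubble_id", "segment_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events CSV {path} missing columns {sorted(missing)}")
    return df


def save_tracks_csv(tracks, path: str | Path) -> None:
    rows = []
    for tid, tr in enumerate(tracks):
        for det in tr.detections:
            rows.append({"track_id": tid, "frame": det.frame_index,
                         "x_mm": det.position[0], "y_mm": det.position[1],
                         "amplitude": det.amplitude})
    pd.DataFrame(rows, columns=["track_id", "frame", "x_mm", "y_mm", "amplitude"]) \
        .to_csv(path, index=False)


# -- transforms / landmarks / centerlines -----------------------------------


def save_transform_json(transform: SimilarityTransform3D, path: str | Path) -> None:
    Path(path).write_text(json.dumps(transform.to_dict(), indent=2))


def load_transform_json(path: str | Path) -> SimilarityTransform3D:
    return SimilarityTransform3D.from_dict(json.loads(Path(path).read_text()))


def load_landmarks_csv(path: str | Path):
    from .coreg import LandmarkPair

    df = pd.read_csv(path)
    required = {"slab_x", "slab_y", "slab_z", "vol_x", "vol_y", "vol_z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmarks CSV {path} missing columns {sorted(missing)}")
    return [LandmarkPair(point_slab=(r.slab_x, r.slab_y, r.slab_z),
                         point_volume=(r.vol_x, r.vol_y, r.vol_z))
            for r in df.itertuples(index=False)]


def save_centerlines_json(centerlines: list[tuple[np.ndarray, dict]],
                          path: str | Path) -> None:
    doc = [{"points_mm": np.asarray(p, float).tolist(), "label": lab}
           for p, lab in centerlines]
    Path(path).write_text(json.dumps(doc, indent=1))


def load_centerlines_json(path: str | Path) -> list[tuple[np.ndarray, dict]]:
    doc = json.loads(Path(path).read_text())
    return [(np.asarray(d["points_mm"], float), dict(d.get("label", {}))) for d in doc]


# -- track maps -------------------------------------------------------------


def save_trackmap_tiff(track_map, path: str | Path) -> None:
    path = Path(path)
    stack = np.stack([track_map.intensity.astype(np.float32),
                      track_map.direction.astype(np.float32),
                      track_map.speed.astype(np.float32)])
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {"channels": ["intensity", "direction_deg", "speed_mm_s"],
            "pixel_size_mm": track_map.grid.pixel_size,
            "origin_mm": list(track_map.grid.origin),
            "display_dynamic_range_db": track_map.display_dynamic_range_db}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def load_trackmap_tiff(path: str | Path):
    from .ulm import TrackMap

    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "pixel_size_mm" not in meta:
        raise ValueError(f"sidecar {sidecar} missing required key 'pixel_size_mm'")
    stack = tifffile.imread(path)
    grid = RasterGeometry(shape=stack.shape[1:], pixel_size=float(meta["pixel_size_mm"]),
                          origin=tuple(meta.get("origin_mm", (0.0, 0.0))))
    return TrackMap(intensity=stack[0].astype(np.int64), direction=stack[1].astype(float),
                    speed=stack[2].astype(float), grid=grid,
                    display_dynamic_range_db=float(meta.get("display_dynamic_range_db", 40.0)))
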