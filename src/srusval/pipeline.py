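"""End-to-end experiment orchestration.

phantom -> contrast frames / CT -> localization -> (motion compensation) ->
tracking -> track maps -> co-registration -> overlap / diameter metrics,
with a run manifest (config snapshot, seeds, checksums) and a JSON report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .coreg import SimilarityTransform3D, invert_transform, project_centerlines_to_plane, slab_mip
from .geometry import RasterGeometry, direction_deg
from .metrics import (Centerline2D, CenterlineSource, DilationTable,
                      centerline_recovery, diameter_4sd, dilate_to_roi, mirror_roi,
                      skeleton_centerlines, trackmap_recovery)
from .phantom import (KidneyPhantom, PhantomConfig, Side, SlabGeometry,
                      generate_kidney_phantom, generate_motion_field,
                      generate_speckle_frames, rasterize_ct, render_contrast_frames,
                      sample_bubble_events, REGION_LABELS)
from .ulm import (RegionLabelMap, Subregion, TrackingParams, compensate_detections,
                  estimate_motion, link_tracks, localize_bubbles, render_track_maps,
                  separate_by_flow, track_statistics)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "import_real_data",
           "build_region_map", "phantom_centerlines_3d", "dilation_table_from_phantom"]


@dataclass
class RunConfig:
    """All pipeline parameters. Defaults marked 'artifact default' are
    choices of this implementation, not reported acquisition values."""

    seed: int = 1
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    # acquisition
    frame_rate_hz: float = 54.0            # reported acquisition frame rate
    duration_s: float = 5.0                # artifact default
    concentration: float = 4.0             # bubbles/frame in steady state; artifact default
    contrast_pixel_mm: float = 0.1         # artifact default
    psf_sigma_mm: float = 0.15             # artifact default
    noise_level: float = 0.02              # artifact default
    slab: SlabGeometry = field(default_factory=SlabGeometry)
    # motion
    motion_amplitude_mm: float = 0.0       # artifact default (never quantified in vivo)
    motion_period_frames: int = 30
    motion_smoothness_mm: float = 3.0
    estimate_motion_flag: bool = True
    motion_block_size: int = 16
    motion_search_radius: int = 6
    # localization
    localization_threshold: float = 0.5    # fraction of frame max; artifact default
    localization_min_amplitude: float = 0.15
    # tracking
    tracking: TrackingParams = field(default_factory=TrackingParams)
    # SRUS rendering
    srus_pixel_mm: float = 0.025           # ~wavelength/10 at 6 MHz; artifact default
    # CT
    ct_spacing_mm: float = 0.05            # artifact default (nominal modality value 0.0226)
    ct_noise_level: float = 0.02
    render_ct: bool = True
    # co-registration
    transform: SimilarityTransform3D = field(default_factory=SimilarityTransform3D.identity)
    # metrics
    dilation_extra_px: float = 3.0         # added to true radius, in SRUS pixels
    min_branch_length_mm: float = 0.3
    region_names: tuple[str, ...] = ("segmental_or_larger_arcuate", "cortex")
    mirror_axis: str = "axial_center"
    region_blocks: tuple[int, int] = (3, 3)

    def to_dict(self) -> dict:
        def conv(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                if isinstance(v, SimilarityTransform3D):
                    return v.to_dict()
                return {k: conv(getattr(v, k)) for k in
                        (f.name for f in dataclasses.fields(v))}
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (tuple, list)):
                return [conv(x) for x in v]
            if isinstance(v, dict):
                return {str(getattr(k, "value", k)): conv(x) for k, x in v.items()}
            return v
        return conv(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            pc = dict(d["phantom"])
            for key in ("radii", "speeds", "lengths"):
                if key in pc:
                    pc[key] = {k: float(v) for k, v in pc[key].items()}
            if "extent" in pc:
                pc["extent"] = tuple(tuple(e) for e in pc["extent"])
            d["phantom"] = PhantomConfig(**pc)
        if "tracking" in d and isinstance(d["tracking"], dict):
            d["tracking"] = TrackingParams(**d["tracking"])
        if "slab" in d and isinstance(d["slab"], dict):
            s = d["slab"]
            d["slab"] = SlabGeometry(in_plane_extent=tuple(s["in_plane_extent"]),
                                     elevation_thickness=float(s["elevation_thickness"]))
        if "transform" in d and isinstance(d["transform"], dict):
            d["transform"] = SimilarityTransform3D.from_dict(d["transform"])
        for key in ("region_names", "region_blocks"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class RunManifest:
    config: dict
    seed: int
    software_version: str
    stage_checksums: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)

    def record(self, stage: str, *arrays) -> None:
        h = hashlib.sha256()
        for a in arrays:
            h.update(np.ascontiguousarray(np.asarray(a)).tobytes())
        self.stage_checksums[stage] = h.hexdigest()
        self.timestamps[stage] = time.time()

    def to_dict(self) -> dict:
        return {"config": self.config, "seed": self.seed,
                "software_version": self.software_version,
                "stage_checksums": self.stage_checksums,
                "timestamps": self.timestamps}


# ---------------------------------------------------------------------------
# Ground-truth adapters
# ---------------------------------------------------------------------------


def phantom_centerlines_3d(phantom: KidneyPhantom) -> list[tuple[np.ndarray, dict]]:
    """Phantom segments as labeled 3D polylines (volume = slab frame here)."""
    return [(s.polyline.copy(),
             {"segment_id": s.id, "vessel_class": s.vessel_class.value,
              "side": s.side.value})
            for s in phantom.segments]


def dilation_table_from_phantom(phantom: KidneyPhantom, extra_mm: float) -> DilationTable:
    """Per (class, side) dilation radius = max true radius of the group + extra."""
    radii: dict[tuple[str, str], float] = {}
    for s in phantom.segments:
        key = (s.vessel_class.value, s.side.value)
        radii[key] = max(radii.get(key, 0.0), s.radius + extra_mm)
    return DilationTable(radii=radii)


def build_region_map(phantom: KidneyPhantom, grid: RasterGeometry,
                     blocks: tuple[int, int] = (3, 3)) -> RegionLabelMap:
    """Region labels from the phantom partition plus flow-reference subregions.

    The raster is split into a block grid; each block becomes a subregion
    whose arterial reference direction is the mean ground-truth artery
    tangent (antegrade flow direction) of artery polyline samples falling
    inside it, falling back to the global artery mean where a block holds
    no artery.
    """
    h, w = grid.shape
    ax, la = grid.grid_mm()
    aa, ll = np.meshgrid(ax, la, indexing="ij")
    pts = np.stack([aa.ravel(), ll.ravel()], axis=1)
    labels = phantom.region_label(pts).reshape(h, w)

    # sample artery flow vectors
    samples = []
    for s in phantom.side_segments(Side.artery):
        poly = s.polyline
        tang = np.diff(poly, axis=0)
        mids = 0.5 * (poly[:-1] + poly[1:])
        for m, t in zip(mids, tang):
            n = np.linalg.norm(t[:2])
            if n > 0:
                samples.append((m[0], m[1], t[0] / n, t[1] / n))
    samples = np.array(samples) if samples else np.zeros((0, 4))
    global_vec = samples[:, 2:].mean(axis=0) if len(samples) else np.array([0.0, 1.0])

    subregions = []
    bi = np.linspace(0, h, blocks[0] + 1).astype(int)
    bj = np.linspace(0, w, blocks[1] + 1).astype(int)
    for a in range(blocks[0]):
        for b in range(blocks[1]):
            mask = np.zeros((h, w), dtype=bool)
            mask[bi[a]:bi[a + 1], bj[b]:bj[b + 1]] = True
            if len(samples):
                lo = grid.px_to_mm(np.array([bi[a], bj[b]], float) - 0.5)
                hi = grid.px_to_mm(np.array([bi[a + 1], bj[b + 1]], float) - 0.5)
                sel = (samples[:, 0] >= lo[0]) & (samples[:, 0] < hi[0]) & \
                      (samples[:, 1] >= lo[1]) & (samples[:, 1] < hi[1])
                vec = samples[sel, 2:].mean(axis=0) if sel.any() else global_vec
            else:
                vec = global_vec
            ref = float(direction_deg(vec[0], vec[1]))
            subregions.append(Subregion(mask=mask, arterial_reference_direction_deg=ref))
    return RegionLabelMap(labels=labels, label_names=REGION_LABELS,
                          subregions=subregions, grid=grid)


def _positions_near_centerline(positions: np.ndarray, centerline: np.ndarray,
                               radius: float) -> np.ndarray:
    a = centerline[:-1]
    b = centerline[1:]
    ab = b - a
    denom = np.maximum(np.sum(ab * ab, axis=1), 1e-30)
    keep = []
    for p in positions:
        t = np.clip(np.sum((p - a) * ab, axis=1) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        if np.min(np.linalg.norm(proj - p, axis=1)) <= radius:
            keep.append(p)
    return np.array(keep) if keep else np.zeros((0, 2))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the manifest of
    completed stages."""

    def __init__(self, stage: str, manifest: RunManifest, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> tuple[RunManifest, dict]:
    """Execute the full experiment; returns (manifest, report)."""
    from . import __version__

    manifest = RunManifest(config=config.to_dict(), seed=config.seed,
                           software_version=__version__)
    stage = "init"
    try:
        stage = "phantom"
        phantom = generate_kidney_phantom(config.phantom, config.seed)
        manifest.record(stage, *[s.polyline for s in phantom.segments])

        stage = "bubble_events"
        events = sample_bubble_events(phantom, config.concentration, config.duration_s,
                                      config.frame_rate_hz, config.seed)
        manifest.record(stage, events.to_numpy(float) if len(events) else np.zeros(1))

        stage = "motion"
        ext = config.slab.in_plane_extent
        frame_grid = RasterGeometry(
            shape=(int(round(ext[0] / config.contrast_pixel_mm)),
                   int(round(ext[1] / config.contrast_pixel_mm))),
            pixel_size=config.contrast_pixel_mm)
        n_frames = int(round(config.duration_s * config.frame_rate_hz))
        motion = None
        if config.motion_amplitude_mm > 0:
            motion = generate_motion_field(frame_grid, n_frames,
                                           config.motion_amplitude_mm,
                                           config.motion_period_frames,
                                           config.motion_smoothness_mm, config.seed)
            manifest.record(stage, motion.base, motion.temporal)

        stage = "render_frames"
        stack, gt = render_contrast_frames(events, config.slab, frame_grid,
                                           config.psf_sigma_mm, config.noise_level,
                                           motion, config.seed,
                                           frame_rate=config.frame_rate_hz,
                                           n_frames=n_frames)
        manifest.record(stage, stack.frames)

        stage = "localize"
        detections_by_frame = []
        for f in range(stack.n_frames):
            frame = stack.frames[f]
            if float(frame.max()) < config.localization_min_amplitude:
                detections_by_frame.append([])
                continue
            detections_by_frame.append(localize_bubbles(
                frame, frame_grid, threshold=config.localization_threshold,
                frame_index=f))
        n_dets = sum(len(d) for d in detections_by_frame)
        logger.info("localized %d detections over %d frames (%.2f/frame)",
                    n_dets, stack.n_frames, n_dets / max(stack.n_frames, 1))
        manifest.record(stage, np.array([len(d) for d in detections_by_frame]))

        stage = "motion_compensation"
        if motion is not None and config.estimate_motion_flag:
            bmode = generate_speckle_frames(frame_grid, motion, stack.n_frames,
                                            config.seed)
            est = estimate_motion(bmode, reference_index=0,
                                  block_size=config.motion_block_size,
                                  search_radius=config.motion_search_radius,
                                  smoothness_scale=config.motion_smoothness_mm)
            detections_by_frame = [
                compensate_detections(dets, est) if dets else []
                for dets in detections_by_frame]
            manifest.record(stage, est.disp)

        stage = "tracking"
        tracks = link_tracks(detections_by_frame, config.tracking,
                             frame_rate=config.frame_rate_hz)
        manifest.record(stage, np.array([t.n_links for t in tracks])
                        if tracks else np.zeros(1))

        stage = "regions"
        srus_grid = RasterGeometry(
            shape=(int(round(ext[0] / config.srus_pixel_mm)),
                   int(round(ext[1] / config.srus_pixel_mm))),
            pixel_size=config.srus_pixel_mm)
        regions = build_region_map(phantom, srus_grid, config.region_blocks)

        stage = "flow_separation"
        artery_tracks, vein_tracks = separate_by_flow(tracks, regions)

        stage = "track_maps"
        maps = {"artery": render_track_maps(artery_tracks, srus_grid),
                "vein": render_track_maps(vein_tracks, srus_grid)}
        manifest.record(stage, maps["artery"].intensity, maps["vein"].intensity)

        stage = "ct"
        ct = None
        if config.render_ct:
            ct = rasterize_ct(phantom, config.ct_spacing_mm, config.ct_noise_level,
                              config.seed)
            manifest.record(stage, ct.voxels)

        stage = "coregistration"
        centerlines3d = [(config.transform.apply(p), lab)
                         for p, lab in phantom_centerlines_3d(phantom)]
        t_inv = invert_transform(config.transform)
        projected = project_centerlines_to_plane(centerlines3d, t_inv, config.slab)
        mip = None
        if ct is not None:
            mip, _valid = slab_mip(ct, config.transform, config.slab, srus_grid,
                                   step=config.ct_spacing_mm / 2)

        stage = "metrics"
        table = dilation_table_from_phantom(
            phantom, extra_mm=config.dilation_extra_px * config.srus_pixel_mm)
        report_rows = {}
        rois = {}
        for side in ("artery", "vein"):
            cls_proj = [Centerline2D(points=p, vessel_class=lab["vessel_class"],
                                     side=lab["side"], source=CenterlineSource.projected_ct)
                        for p, lab in projected if lab["side"] == side]
            roi = dilate_to_roi(cls_proj, table, srus_grid, side=side)
            rois[side] = roi
            mirrored = mirror_roi(roi, config.mirror_axis)
            skel = skeleton_centerlines(maps[side], config.min_branch_length_mm,
                                        regions, list(config.region_names), side=side) \
                if maps[side].nonzero_mask().any() else []
            side_tracks = artery_tracks if side == "artery" else vein_tracks
            stats = track_statistics(side_tracks)
            report_rows[side] = {
                "centerline_recovery_pct": centerline_recovery(skel, roi) if skel else None,
                "centerline_recovery_mirrored_pct":
                    centerline_recovery(skel, mirrored) if skel else None,
                "trackmap_recovery_pct": trackmap_recovery(
                    maps[side], roi, regions, list(config.region_names)),
                "trackmap_recovery_mirrored_pct": trackmap_recovery(
                    maps[side], mirrored, regions, list(config.region_names)),
                "n_tracks": stats["n_tracks"],
                "n_links": stats["n_links"],
                "median_track_length_um": stats["median_path_length_um"],
                "diameters_mm": _example_diameters(side_tracks, projected, side, table),
            }
        report = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "seed": config.seed,
            "n_detections": n_dets,
            "n_tracks_total": len(tracks),
            "sides": report_rows,
        }
        manifest.record(stage, np.array([hash(json.dumps(report, sort_keys=True, default=str))]))

        if outdir is not None:
            stage = "outputs"
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            sio.save_phantom_json(phantom, outdir / "phantom.json")
            sio.save_events_csv(events, outdir / "events.csv")
            sio.save_frame_stack(stack, outdir / "frames.tiff")
            sio.save_tracks_csv(tracks, outdir / "tracks.csv")
            for side, m in maps.items():
                sio.save_trackmap_tiff(m, outdir / f"trackmap_{side}.tiff")
            if ct is not None:
                sio.save_ct_nifti(ct, outdir / "ct.nii.gz")
            sio.save_transform_json(config.transform, outdir / "transform.json")
            (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
            (outdir / "manifest.json").write_text(
                json.dumps(manifest.to_dict(), indent=2, default=str))
            _report_csv(report, outdir / "report.csv")
        return manifest, report
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, manifest, exc) from exc


def _example_diameters(tracks, projected, side: str, table: DilationTable,
                       max_vessels: int = 3) -> list[float]:
    """4-s.d. diameters for the longest projected centerlines of one side,
    using track detections within a capture radius of 2x the dilation radius."""
    if not tracks:
        return []
    positions = np.concatenate([t.positions for t in tracks], axis=0)
    cls = [(p, lab) for p, lab in projected if lab["side"] == side]
    cls.sort(key=lambda c: -float(np.sum(np.linalg.norm(np.diff(c[0], axis=0), axis=1))))
    out = []
    for p, lab in cls[:max_vessels]:
        radius = 2.0 * table.radius_for(lab["vessel_class"], lab["side"])
        near = _positions_near_centerline(positions, p, radius)
        if near.shape[0] >= 10:
            d = diameter_4sd(near, Centerline2D(points=p, vessel_class=lab["vessel_class"],
                                                side=side,
                                                source=CenterlineSource.projected_ct))
            if d is not None:
                out.append(d)
    return out


def _report_csv(report: dict, path: Path) -> None:
    rows = []
    for side, r in report["sides"].items():
        row = {"side": side}
        row.update({k: v for k, v in r.items() if not isinstance(v, (list, dict))})
        row["diameters_mm"] = ";".join(f"{d:.4f}" for d in r.get("diameters_mm", []))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Real-data import
# ---------------------------------------------------------------------------


def import_real_data(frames_path: str | Path | None = None,
                     ct_path: str | Path | None = None,
                     centerlines_path: str | Path | None = None,
                     transform_path: str | Path | None = None) -> dict:
    """Load externally produced inputs into validated internal types.

    Units are normalized to mm and 0-based indices; any missing pixel-size
    or spacing metadata is a hard error (never guessed).
    """
    out: dict = {}
    if frames_path is not None:
        out["frames"] = sio.load_frame_stack(frames_path)
    if ct_path is not None:
        p = Path(ct_path)
        if p.suffix in (".nii", ".gz") or str(p).endswith(".nii.gz"):
            out["ct"] = sio.load_ct_nifti(p)
        else:
            out["ct"] = sio.load_ct_tiff(p)
    if centerlines_path is not None:
        out["centerlines"] = sio.load_centerlines_json(centerlines_path)
    if transform_path is not None:
        out["transform"] = sio.load_transform_json(transform_path)
    return out
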