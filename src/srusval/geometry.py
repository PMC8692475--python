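"""Coordinate conventions shared across the package.

Physical coordinates are right-handed millimetres. The slab frame is
(axial, lateral, elevation); 2D rasters are indexed ``[row, col]`` with
``row`` running along axial (depth) and ``col`` along lateral. Pixel and
voxel centers sit at ``origin + (index + 0.5) * spacing``; interval
membership (slab gating, raster extents) is half-open on the upper side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RasterGeometry", "wrap_angle_deg", "direction_deg"]


@dataclass(frozen=True)
class RasterGeometry:
    """Geometry of a 2D raster: shape, pixel size and physical origin.

    ``origin`` is the physical coordinate (axial, lateral) of the raster's
    corner; the center of pixel ``(i, j)`` lies at
    ``origin + (i + 0.5, j + 0.5) * pixel_size``.
    """

    shape: tuple[int, int]
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if len(self.shape) != 2 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be two positive ints, got {self.shape}")

    @property
    def extent(self) -> tuple[float, float]:
        """Physical (axial, lateral) size of the raster in mm."""
        return (self.shape[0] * self.pixel_size, self.shape[1] * self.pixel_size)

    def px_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (fractional) pixel indices ``(..., 2)`` to mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + (idx + 0.5) * self.pixel_size

    def mm_to_px(self, pos: np.ndarray) -> np.ndarray:
        """Map mm coordinates ``(..., 2)`` to fractional pixel indices."""
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin)) / self.pixel_size - 0.5

    def contains(self, pos: np.ndarray) -> np.ndarray:
        """Half-open membership test for mm positions ``(..., 2)``."""
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        lo = np.asarray(self.origin)
        hi = lo + np.asarray(self.extent)
        ok = np.all((pos >= lo) & (pos < hi), axis=-1)
        return ok

    def pixel_index(self, pos: np.ndarray) -> np.ndarray:
        """Integer pixel index containing each mm position (no bounds check)."""
        return np.floor((np.asarray(pos, dtype=float) - np.asarray(self.origin))
                        / self.pixel_size).astype(int)

    def grid_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinate arrays (axial_mm[H], lateral_mm[W])."""
        ax = self.origin[0] + (np.arange(self.shape[0]) + 0.5) * self.pixel_size
        la = self.origin[1] + (np.arange(self.shape[1]) + 0.5) * self.pixel_size
        return ax, la


def wrap_angle_deg(angle: np.ndarray) -> np.ndarray:
    """Wrap angles in degrees to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped


def direction_deg(d_axial: np.ndarray, d_lateral: np.ndarray) -> np.ndarray:
    """Flow direction in degrees: 0 deg = +lateral, counter-clockwise,
    range (-180, 180]."""
    ang = np.degrees(np.arctan2(np.asarray(d_axial, float), np.asarray(d_lateral, float)))
    return wrap_angle_deg(ang)
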