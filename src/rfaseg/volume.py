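"""Core spatial containers: scalar image volumes, seed points, binary masks.

Conventions
-----------
* Arrays are indexed ``[i, j, k]`` along the (x, y, z) world axes.
* Volumes are axis-aligned (no direction cosines); the world position of the
  center of voxel ``(i, j, k)`` is ``origin + index * spacing`` (0-based
  indices, spacing in mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InvalidParameterError, OutOfBoundsError

__all__ = ["ImageVolume", "SeedPoint", "SegmentationMask"]


@dataclass
class ImageVolume:
    """A 3D scalar image with anisotropic voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar intensities (HU-like units for CT).
    spacing : sequence of 3 floats
        Per-axis voxel size in mm; strictly positive.
    origin : sequence of 3 floats
        World position (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise InvalidParameterError(
                f"volume must be 3D, got shape {self.values.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidParameterError(
                f"spacing must be 3 strictly positive values, got {self.spacing}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def world_to_voxel(self, point: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinate of a world-space point (mm)."""
        return (np.asarray(point, dtype=float) - self.origin) / self.spacing

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        """World position (mm) of a (possibly fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * self.spacing

    def contains_world(self, point: np.ndarray) -> bool:
        """True when the point falls inside the voxel-center bounding box."""
        v = self.world_to_voxel(point)
        return bool(np.all(v >= 0) and np.all(v <= np.array(self.shape) - 1))

    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class SeedPoint:
    """A user-supplied point, in world mm or 0-based voxel coordinates."""

    position: tuple[float, float, float]
    frame: str = "world"

    def __post_init__(self) -> None:
        self.position = tuple(float(p) for p in self.position)
        if self.frame not in ("world", "voxel"):
            raise InvalidParameterError(
                f"frame must be 'world' or 'voxel', got {self.frame!r}"
            )

    def to_world(self, volume: ImageVolume) -> np.ndarray:
        """World-space position of the seed, validated against the volume."""
        if self.frame == "world":
            p = np.asarray(self.position, dtype=float)
        else:
            idx = np.asarray(self.position, dtype=float)
            if np.any(idx < 0) or np.any(idx > np.array(volume.shape) - 1):
                raise OutOfBoundsError(
                    f"voxel seed {self.position} outside grid of shape {volume.shape}"
                )
            p = volume.voxel_to_world(idx)
        if not volume.contains_world(p):
            raise OutOfBoundsError(
                "seed at ({:.2f}, {:.2f}, {:.2f}) mm is out-of-bounds".format(*p)
            )
        return p


class SegmentationMask:
    """A binary 3D mask aligned to a reference :class:`ImageVolume` grid."""

    def __init__(self, grid, spacing, origin=(0.0, 0.0, 0.0)):
        self.grid = np.asarray(grid).astype(bool)
        if self.grid.ndim != 3:
            raise InvalidParameterError(f"mask must be 3D, got {self.grid.shape}")
        self.spacing = tuple(float(s) for s in spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidParameterError(f"bad spacing {spacing}")
        self.origin = tuple(float(o) for o in origin)

    @property
    def voxel_count(self) -> int:
        return int(self.grid.sum())

    @property
    def volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return self.voxel_count * sx * sy * sz

    def check_compatible(self, other: "SegmentationMask") -> None:
        """Raise GeometryError unless both masks share grid shape and spacing."""
        if self.grid.shape != other.grid.shape:
            raise GeometryError(
                f"mask shapes differ: {self.grid.shape} vs {other.grid.shape}"
            )
        if not np.allclose(self.spacing, other.spacing):
            raise GeometryError(
                f"mask spacings differ: {self.spacing} vs {other.spacing}"
            )
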