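"""Closed surfaces from cuts, and voxelization of surfaces and contours.

The per-ray boundary points of a cut, connected by the template
triangulation, form a closed (watertight) triangle mesh by construction.
The mesh is turned into a solid binary mask slice-by-slice: the mesh is
sectioned with each axial voxel-center plane, the resulting closed
cross-section polygons are tested against in-plane voxel centers, and a
voxel is set when its center lies inside.  The same even-odd fill rule
voxelizes manual slice contours, which are then merged by union into a 3D
reference mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
import trimesh
from shapely.geometry import Polygon

from .errors import (
    ContourFormatError,
    IncompleteCutError,
    VoxelizationError,
)
from .graphcut import CutResult
from .template import RayTemplate
from .volume import ImageVolume, SeedPoint, SegmentationMask

__all__ = [
    "SliceContour",
    "SliceContourSet",
    "cut_to_surface",
    "voxelize_surface",
    "voxelize_contours",
]


@dataclass
class SliceContour:
    """One closed polygon on one slice.

    ``points`` is an (n, 2) array of (x, y) coordinates; ``frame`` selects
    whether they are world mm or 0-based pixel coordinates of the reference
    slice grid.  The polygon must be explicitly closed (first point equals
    last) and non-self-intersecting; orientation is irrelevant.
    """

    slice_index: int
    points: np.ndarray
    frame: str = "pixel"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ContourFormatError(
                f"contour points must be (n, 2), got {self.points.shape}"
            )
        if len(self.points) < 4 or not np.allclose(
            self.points[0], self.points[-1]
        ):
            raise ContourFormatError(
                "contour must be closed: first point must equal last point"
            )
        if self.frame not in ("pixel", "world"):
            raise ContourFormatError(f"unknown contour frame {self.frame!r}")
        if not Polygon(self.points[:-1]).is_valid:
            raise ContourFormatError("contour polygon is self-intersecting")


SliceContourSet = list  # a list of SliceContour


def cut_to_surface(
    cut: CutResult, template: RayTemplate, seed: SeedPoint | None = None
) -> trimesh.Trimesh:
    """Closed triangle mesh through the per-ray boundary points of a cut.

    Vertices are the cut's boundary points, faces the template
    triangulation, so the result is watertight by construction (sphere
    topology, V − E + F = 2).
    """
    pts = np.asarray(cut.boundary_points, dtype=float)
    if pts.shape != (template.n_rays, 3) or not np.all(np.isfinite(pts)):
        raise IncompleteCutError(
            "cut is missing boundary points for some template ray"
        )
    mesh = trimesh.Trimesh(
        vertices=pts, faces=template.faces.copy(), process=False
    )
    return mesh


def _section_segments(mesh: trimesh.Trimesh, z: float) -> np.ndarray:
    """(m, 2, 2) xy line segments of the mesh cross-section at height z."""
    segs = trimesh.intersections.mesh_plane(
        mesh, plane_normal=[0.0, 0.0, 1.0], plane_origin=[0.0, 0.0, z]
    )
    if len(segs) == 0:
        return np.empty((0, 2, 2))
    return np.asarray(segs)[:, :, :2]


def _points_inside_segments(segs: np.ndarray, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) inside test against a closed segment soup.

    Counts crossings of the horizontal ray from each point towards +x with
    every segment, using the half-open vertex rule of PNPOLY so shared
    segment endpoints are counted exactly once.
    """
    if len(segs) == 0:
        return np.zeros(px.shape, dtype=bool)
    x1, y1 = segs[:, 0, 0][:, None], segs[:, 0, 1][:, None]
    x2, y2 = segs[:, 1, 0][:, None], segs[:, 1, 1][:, None]
    py = py[None, :]
    px = px[None, :]
    straddle = (y1 > py) != (y2 > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
    crossings = np.logical_and(straddle, xint > px)
    return crossings.sum(axis=0) % 2 == 1


def voxelize_surface(
    mesh: trimesh.Trimesh, reference: ImageVolume
) -> SegmentationMask:
    """Solid binary mask of a watertight mesh on the reference grid.

    A voxel is set when its center lies strictly inside the closed surface
    (even-odd rule applied slice-wise along z).
    """
    if not mesh.is_watertight:
        raise VoxelizationError("surface mesh is not watertight")
    nx, ny, nz = reference.shape
    ox, oy, oz = reference.origin
    sx, sy, sz = reference.spacing
    grid = np.zeros(reference.shape, dtype=bool)

    lo = mesh.bounds[0]
    hi = mesh.bounds[1]
    k_lo = max(int(np.ceil((lo[2] - oz) / sz)), 0)
    k_hi = min(int(np.floor((hi[2] - oz) / sz)), nz - 1)
    i_lo = max(int(np.floor((lo[0] - ox) / sx)), 0)
    i_hi = min(int(np.ceil((hi[0] - ox) / sx)), nx - 1)
    j_lo = max(int(np.floor((lo[1] - oy) / sy)), 0)
    j_hi = min(int(np.ceil((hi[1] - oy) / sy)), ny - 1)
    if k_hi < k_lo or i_hi < i_lo or j_hi < j_lo:
        warnings.warn("mesh lies outside the reference grid; mask is empty")
        return SegmentationMask(grid, reference.spacing, reference.origin)

    xs = ox + sx * np.arange(i_lo, i_hi + 1)
    ys = oy + sy * np.arange(j_lo, j_hi + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    xf, yf = X.ravel(), Y.ravel()

    for k in range(k_lo, k_hi + 1):
        z = oz + sz * k
        segs = _section_segments(mesh, z)
        inside = _points_inside_segments(segs, xf, yf).reshape(X.shape)
        grid[i_lo : i_hi + 1, j_lo : j_hi + 1, k] |= inside

    if not grid.any():
        warnings.warn("voxelized surface produced an empty mask")
    return SegmentationMask(grid, reference.spacing, reference.origin)


def voxelize_contours(
    contours: SliceContourSet, reference: ImageVolume
) -> SegmentationMask:
    """Fill per-slice closed polygons and merge them into one 3D mask."""
    nx, ny, nz = reference.shape
    ox, oy, _ = reference.origin
    sx, sy, _ = reference.spacing
    grid = np.zeros(reference.shape, dtype=bool)
    xs = ox + sx * np.arange(nx)
    ys = oy + sy * np.arange(ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    xf, yf = X.ravel(), Y.ravel()

    for contour in contours:
        k = int(contour.slice_index)
        if not 0 <= k < nz:
            raise ContourFormatError(
                f"contour slice index {k} outside grid of {nz} slices"
            )
        pts = contour.points
        if contour.frame == "pixel":
            pts = np.column_stack([ox + sx * pts[:, 0], oy + sy * pts[:, 1]])
        poly = Polygon(pts[:-1])
        inside = shapely.contains_xy(poly, xf, yf).reshape(X.shape)
        grid[:, :, k] |= inside
    return SegmentationMask(grid, reference.spacing, reference.origin)
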