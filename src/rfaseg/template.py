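"""Spherical ray templates from recursively refined polyhedra.

Rays are sent from the seed point towards the surface points of a polyhedron
approximating the unit sphere.  The polyhedron starts as a regular icosahedron
(12 vertices, 20 faces) and is refined by centroid insertion: at each level
the centroid of every face of the current spherical Delaunay triangulation
(the convex hull) is projected onto the unit sphere and added as a new
vertex, and the enlarged point set is re-triangulated.  Every triangulation
of a sphere with V vertices has F = 2V − 4 faces, so one refinement maps
``V -> V + F = 3V - 4``, producing the vertex sequence 12, 32, 92, 272,
812, 2432 and the face sequence 20, 60, 180, 540, 1620, 4860 for levels
0..5.

The triangulation's edges double as the ray-adjacency relation used for the
smoothness (inter-edge) construction of the segmentation graph, so they must
all span comparable angular scales — the Δr bound applies per edge.
Re-triangulating after every insertion keeps the direction set quasi-uniform
(nearest-neighbor angular distances within a factor 1.4 at every level),
whereas keeping the raw subdivision combinatorics would retain the coarse
63° icosahedron edges alongside ever finer ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import InvalidParameterError

__all__ = ["RayTemplate", "build_ray_template", "template_mesh", "VERTEX_COUNTS"]

#: Vertex count per subdivision level (icosahedron + kis refinements).
VERTEX_COUNTS = (12, 32, 92, 272, 812, 2432)

MAX_LEVEL = len(VERTEX_COUNTS) - 1


@dataclass(frozen=True)
class RayTemplate:
    """Unit ray directions plus the triangulation that links them.

    Attributes
    ----------
    level : int
        Subdivision depth (0 = icosahedron).
    directions : ndarray, shape (n_rays, 3)
        Unit vectors from the seed towards each polyhedron surface point.
    faces : ndarray, shape (n_faces, 3)
        Triangles over direction indices, wound outward.
    adjacency : frozenset of (int, int)
        Unordered index pairs — the edges of the triangulation.
    """

    level: int
    directions: np.ndarray
    faces: np.ndarray
    adjacency: frozenset = field(repr=False)

    @property
    def n_rays(self) -> int:
        return len(self.directions)

    def adjacency_pairs(self) -> np.ndarray:
        """Edges as a sorted (n_edges, 2) integer array (deterministic order)."""
        return np.array(sorted(self.adjacency), dtype=np.int64).reshape(-1, 2)


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Canonical golden-ratio icosahedron, vertices on the unit sphere."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=np.int64,
    )
    return verts, faces


def _insert_centroids(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Add each face centroid, projected onto the unit sphere."""
    centroids = verts[faces].mean(axis=1)
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    return np.concatenate([verts, centroids])


def _hull_triangulation(verts: np.ndarray) -> np.ndarray:
    """Spherical Delaunay triangulation (convex hull), wound outward."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(verts)
    faces = hull.simplices.astype(np.int64)
    # orient every face so its normal points away from the origin
    tri = verts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    centroids = tri.mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, centroids) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    # deterministic ordering: roll smallest index first, then sort rows
    roll = np.argmin(faces, axis=1)
    faces = np.stack(
        [faces[np.arange(len(faces)), (roll + k) % 3] for k in range(3)], axis=1
    )
    order = np.lexsort((faces[:, 2], faces[:, 1], faces[:, 0]))
    return faces[order]


def _edges_of(faces: np.ndarray) -> frozenset:
    pairs = set()
    for a, b, c in faces:
        pairs.add((min(a, b), max(a, b)))
        pairs.add((min(b, c), max(b, c)))
        pairs.add((min(c, a), max(c, a)))
    return frozenset((int(i), int(j)) for i, j in pairs)


def build_ray_template(level: int) -> RayTemplate:
    """Build the ray template for a subdivision level.

    Parameters
    ----------
    level : int
        Refinement depth in ``0..5``, giving 12, 32, 92, 272, 812 or 2432
        ray directions respectively.
    """
    if not isinstance(level, (int, np.integer)) or isinstance(level, bool):
        raise InvalidParameterError(f"level must be an integer, got {level!r}")
    if not 0 <= level <= MAX_LEVEL:
        raise InvalidParameterError(
            f"level {level} unsupported; levels 0..{MAX_LEVEL} give "
            f"{VERTEX_COUNTS} ray directions"
        )
    verts, faces = _icosahedron()
    for _ in range(level):
        verts = _insert_centroids(verts, faces)
        faces = _hull_triangulation(verts)
    assert len(verts) == VERTEX_COUNTS[level]
    if level == 0:
        faces = _hull_triangulation(verts)
    return RayTemplate(
        level=int(level),
        directions=verts,
        faces=faces,
        adjacency=_edges_of(faces),
    )


def template_mesh(template: RayTemplate) -> trimesh.Trimesh:
    """The template as a watertight unit-sphere triangle mesh (for export)."""
    mesh = trimesh.Trimesh(
        vertices=template.directions.copy(),
        faces=template.faces.copy(),
        process=False,
    )
    return mesh
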