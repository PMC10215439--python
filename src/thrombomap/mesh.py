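"""Triangulated surface meshes with per-vertex outward normals.

All coordinates are in millimetres and live in a single consistent frame;
no implicit rescaling is ever applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurfaceMesh"]

_NORMAL_TOL = 1e-6


@dataclass
class SurfaceMesh:
    """A triangulated surface.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex coordinates in mm.
    faces : (M, 3) int array
        Triangle vertex indices with consistent (outward) winding.
    normals : (N, 3) float array, optional
        Outward unit vertex normals. If omitted they are computed as the
        area-weighted average of incident face normals.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None
    point_data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (M, 3) array")
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face indices out of range")
        if self.normals is None:
            self.normals = self._vertex_normals()
        else:
            self.normals = np.ascontiguousarray(self.normals, dtype=float)
            if self.normals.shape != self.vertices.shape:
                raise ValueError("normals must match vertices in shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-4):
                raise ValueError("vertex normals must be unit vectors")

    # -- derived geometry ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_cross(self) -> np.ndarray:
        """Un-normalised face normals (cross products, magnitude = 2*area)."""
        tri = self.vertices[self.faces]
        return np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_cross(), axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas: one third of each incident face area."""
        areas = np.zeros(self.n_vertices)
        fa = self.face_areas() / 3.0
        for k in range(3):
            np.add.at(areas, self.faces[:, k], fa)
        return areas

    def _vertex_normals(self) -> np.ndarray:
        cross = self.face_cross()  # area-weighted by construction
        acc = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(acc, self.faces[:, k], cross)
        norms = np.linalg.norm(acc, axis=1)
        degenerate = norms < _NORMAL_TOL
        norms[degenerate] = 1.0
        acc /= norms[:, None]
        # isolated / degenerate vertices get an arbitrary unit vector
        acc[degenerate] = np.array([0.0, 0.0, 1.0])
        return acc

    def signed_volume(self) -> float:
        """Signed enclosed volume (divergence theorem); positive for
        outward-wound closed surfaces. Meaningful only for closed meshes."""
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))) / 6.0

    def validate(self, min_face_area: float = 1e-12) -> None:
        """Raise ValueError on degenerate faces or non-unit normals."""
        if self.n_faces and self.face_areas().min() < min_face_area:
            raise ValueError("mesh contains degenerate (zero-area) faces")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=_NORMAL_TOL * 10):
            raise ValueError("vertex normals are not unit length")

    def submesh(self, vertex_mask: np.ndarray) -> tuple["SurfaceMesh", np.ndarray]:
        """Restrict to faces whose three vertices are all selected.

        Returns the submesh and the original indices of its vertices.
        Vertex normals are carried over, not recomputed, so per-vertex
        quantities computed on the submesh match the full-mesh values.
        """
        vertex_mask = np.asarray(vertex_mask, dtype=bool)
        keep = np.flatnonzero(vertex_mask)
        remap = -np.ones(self.n_vertices, dtype=np.int64)
        remap[keep] = np.arange(len(keep))
        face_ok = vertex_mask[self.faces].all(axis=1)
        sub = SurfaceMesh(
            vertices=self.vertices[keep],
            faces=remap[self.faces[face_ok]],
            normals=self.normals[keep],
        )
        return sub, keep
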