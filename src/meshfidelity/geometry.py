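"""Core geometric types shared across the pipeline.

Coordinate convention (used everywhere): meshes and voxel volumes live in a
common metric (mm) frame. A volume's origin is its lower corner; the center
of voxel (i, j, k) sits at ``origin + (i + 1/2) * spacing``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateConfigurationError(ValueError):
    """Raised when a geometric input is too degenerate to operate on."""


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (rotation + translation, no scale)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.linalg.norm(self.rotation.T @ self.rotation - np.eye(3))
        if err > 1e-8:
            raise ValueError(f"rotation is not orthonormal (||R^T R - I|| = {err:.3g})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def rotation_angle_rad(self) -> float:
        """Angle of the rotation about its axis, in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass
class TriangleMesh:
    """Indexed triangle surface with vertex coordinates in mm."""

    vertices: np.ndarray
    faces: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.vertices) and len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")

    # ---- basic quantities -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(n_faces, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def face_areas(self) -> np.ndarray:
        tri = self.triangles()
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def face_normals(self) -> np.ndarray:
        tri = self.triangles()
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        norm[norm == 0] = 1.0
        return cross / norm[:, None]

    def area(self) -> float:
        return float(self.face_areas().sum())

    def volume(self) -> float:
        """Signed enclosed volume (positive for outward-oriented closed meshes)."""
        tri = self.triangles()
        return float(np.einsum("ij,ij->i", tri[:, 0],
                               np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def bbox_diagonal(self) -> float:
        lo, hi = self.bounds()
        return float(np.linalg.norm(hi - lo))

    # ---- topology ---------------------------------------------------------
    def _edges(self) -> np.ndarray:
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def euler_characteristic(self) -> int:
        edges = np.sort(self._edges(), axis=1)
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + self.n_faces

    def is_watertight(self) -> bool:
        """True when every edge is shared by exactly two faces of opposite orientation."""
        if self.n_faces == 0:
            return False
        directed = self._edges()
        und = np.sort(directed, axis=1)
        _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
        if not np.all(counts == 2):
            return False
        # opposite orientation: each undirected edge appears once in each direction
        forward = directed[:, 0] < directed[:, 1]
        n_forward = np.bincount(inv, weights=forward.astype(float))
        return bool(np.all(n_forward == 1))

    # ---- transforms / copies ----------------------------------------------
    def transformed(self, rt: RigidTransform, provenance: str | None = None) -> "TriangleMesh":
        return TriangleMesh(rt.apply(self.vertices), self.faces.copy(),
                            provenance if provenance is not None else self.provenance)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.provenance)

    def submesh(self, face_mask: np.ndarray, provenance: str | None = None) -> "TriangleMesh":
        """Mesh restricted to the masked faces, with unused vertices dropped."""
        faces = self.faces[face_mask]
        used, new_faces = np.unique(faces, return_inverse=True)
        return TriangleMesh(self.vertices[used], new_faces.reshape(-1, 3),
                            provenance if provenance is not None else self.provenance)

    def sample_surface(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Area-weighted uniform random points on the surface."""
        areas = self.face_areas()
        total = areas.sum()
        if total <= 0:
            raise DegenerateConfigurationError("mesh has zero surface area")
        idx = rng.choice(self.n_faces, size=n, p=areas / total)
        tri = self.triangles()[idx]
        r1 = np.sqrt(rng.random(n))
        r2 = rng.random(n)
        u = 1.0 - r1
        v = r1 * (1.0 - r2)
        w = r1 * r2
        return u[:, None] * tri[:, 0] + v[:, None] * tri[:, 1] + w[:, None] * tri[:, 2]
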