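"""Threshold segmentation of voxel volumes and STL mesh I/O.

The segmentation threshold is the display window level L: the exported
surface is the iso-surface of the HU field at iso-value L (the window width
only affects on-screen contrast, not the surface). Only the largest connected
component is kept, suppressing noise-speckle shells.
"""
from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure

from .geometry import TriangleMesh
from .phantom import VoxelVolume, _largest_component

DEFAULT_LEVELS = tuple(range(1425, 2626, 100))   # 13 levels


class EmptySegmentationError(ValueError):
    """Raised when an iso-level produces no surface."""


class StlFormatError(ValueError):
    """Raised for unreadable STL files; carries the failing byte offset."""

    def __init__(self, message: str, byte_offset: int | None = None):
        if byte_offset is not None:
            message = f"{message} (at byte {byte_offset})"
        super().__init__(message)
        self.byte_offset = byte_offset


class EmptyCropError(ValueError):
    """Raised when a crop region removes every face of a mesh."""


@dataclass(frozen=True)
class ThresholdSweep:
    """Ordered HU iso-levels to segment at (default: 1425..2625 step 100)."""

    levels: tuple[float, ...] = DEFAULT_LEVELS
    window_width: float = 2500.0

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise ValueError("sweep needs at least one level")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")


@dataclass(frozen=True)
class CropRegion:
    """Axis-aligned box or z-extruded polygon, in the common mm frame."""

    shape: str = "box"
    lo: tuple[float, float, float] | None = None     # box corners
    hi: tuple[float, float, float] | None = None
    polygon_xy: tuple[tuple[float, float], ...] | None = None
    z_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.shape == "box":
            if self.lo is None or self.hi is None:
                raise ValueError("box region needs lo and hi corners")
            if not np.all(np.asarray(self.hi) > np.asarray(self.lo)):
                raise ValueError("box region must have positive volume")
        elif self.shape == "extruded-polygon":
            if self.polygon_xy is None or len(self.polygon_xy) < 3:
                raise ValueError("polygon region needs >= 3 vertices")
            if self.z_range is None or self.z_range[1] <= self.z_range[0]:
                raise ValueError("polygon region needs a positive z range")
        else:
            raise ValueError(f"unknown crop shape {self.shape!r}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        if self.shape == "box":
            lo = np.asarray(self.lo)
            hi = np.asarray(self.hi)
            return np.all((points >= lo) & (points <= hi), axis=1)
        inside_z = ((points[:, 2] >= self.z_range[0])
                    & (points[:, 2] <= self.z_range[1]))
        return inside_z & _points_in_polygon(points[:, :2],
                                             np.asarray(self.polygon_xy))


def _points_in_polygon(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd rule point-in-polygon test, vectorised over points."""
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < np.where(crosses, xint, np.inf))
    return inside


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_mesh(vol: VoxelVolume, level: float,
                 provenance: str = "") -> TriangleMesh:
    """Iso-surface of the HU field at ``level`` in mm coordinates.

    Vertices are edge-interpolated, scaled by spacing and offset by the
    volume origin (voxel centers at origin + (i + 1/2) * spacing). The largest
    connected component is kept and degenerate faces removed.
    """
    vmin, vmax = vol.value_range()
    if not (vmin < level < vmax):
        raise EmptySegmentationError(
            f"iso-level {level} outside volume value range [{vmin:.1f}, {vmax:.1f}]")
    verts, faces, _, _ = measure.marching_cubes(
        vol.values, level=level, spacing=tuple(vol.spacing_mm))
    if len(faces) == 0:
        raise EmptySegmentationError(f"iso-level {level} produced no faces")
    verts = verts + vol.origin_mm + 0.5 * vol.spacing_mm
    mesh = TriangleMesh(verts, faces, provenance=provenance)
    mesh = _largest_component(mesh)
    mesh = _drop_degenerate(mesh)
    if mesh.volume() < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1], mesh.provenance)
    return mesh


def _drop_degenerate(mesh: TriangleMesh) -> TriangleMesh:
    ok = mesh.face_areas() > 0
    if ok.all():
        return mesh
    return mesh.submesh(ok)


def enclosed_volume(mesh: TriangleMesh) -> float:
    return abs(mesh.volume())


# ---------------------------------------------------------------------------
# Cropping
# ---------------------------------------------------------------------------

def crop(meshes: list[TriangleMesh], region: CropRegion) -> list[TriangleMesh]:
    """Apply one region simultaneously to co-registered meshes.

    A face survives when its centroid lies inside the region. Open boundaries
    are permitted afterwards.
    """
    out = []
    for mesh in meshes:
        keep = region.contains(mesh.face_centroids())
        if not keep.any():
            name = mesh.provenance or f"mesh #{len(out)}"
            raise EmptyCropError(f"crop region removes every face of {name}")
        out.append(mesh.submesh(keep))
    return out


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------

def write_stl(mesh: TriangleMesh, path: str | Path, binary: bool = True) -> None:
    """Write STL with outward (counter-clockwise from outside) winding."""
    path = Path(path)
    tri = mesh.triangles().astype("<f4")
    normals = mesh.face_normals().astype("<f4")
    if binary:
        with open(path, "wb") as fh:
            fh.write(b"meshfidelity".ljust(80, b"\x00"))
            fh.write(struct.pack("<I", mesh.n_faces))
            rec = np.zeros(mesh.n_faces,
                           dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)),
                                  ("attr", "<u2")])
            rec["n"] = normals
            rec["v"] = tri
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("solid meshfidelity\n")
            for nrm, t in zip(normals, tri):
                fh.write(f"  facet normal {nrm[0]:.9e} {nrm[1]:.9e} {nrm[2]:.9e}\n")
                fh.write("    outer loop\n")
                for v in t:
                    fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid meshfidelity\n")


def read_stl(path: str | Path, provenance: str = "") -> TriangleMesh:
    """Read binary or ASCII STL (auto-detected); welds exactly equal vertices."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 15:
        raise StlFormatError(f"{path.name}: file too short to be STL", len(raw))
    is_ascii = raw.lstrip()[:5] == b"solid"
    if is_ascii and len(raw) >= 84:
        # "solid" header does not guarantee ASCII; check binary size consistency
        (n,) = struct.unpack_from("<I", raw, 80)
        if len(raw) == 84 + 50 * n:
            is_ascii = False
    tri = _read_stl_ascii(raw, path.name) if is_ascii else _read_stl_binary(raw, path.name)
    if len(tri) == 0:
        raise StlFormatError(f"{path.name}: STL contains no triangles")
    soup = tri.reshape(-1, 3)
    verts, inverse = np.unique(soup, axis=0, return_inverse=True)
    return TriangleMesh(verts, inverse.reshape(-1, 3),
                        provenance=provenance or path.stem)


def _read_stl_binary(raw: bytes, name: str) -> np.ndarray:
    if len(raw) < 84:
        raise StlFormatError(f"{name}: binary STL header truncated", len(raw))
    (n,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * n
    if len(raw) < expected:
        raise StlFormatError(
            f"{name}: binary STL truncated, {n} triangles declared", len(raw))
    rec = np.frombuffer(raw, dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)),
                                    ("attr", "<u2")], count=n, offset=84)
    return rec["v"].astype(np.float64)


def _read_stl_ascii(raw: bytes, name: str) -> np.ndarray:
    coords: list[float] = []
    offset = 0
    for line in raw.splitlines(keepends=True):
        stripped = line.strip()
        if stripped.startswith(b"vertex"):
            parts = stripped.split()
            if len(parts) != 4:
                raise StlFormatError(f"{name}: malformed vertex line", offset)
            try:
                coords.extend(float(p) for p in parts[1:])
            except ValueError:
                raise StlFormatError(f"{name}: non-numeric vertex", offset) from None
        offset += len(line)
    if len(coords) % 9:
        raise StlFormatError(f"{name}: vertex count not a multiple of 3", offset)
    return np.array(coords, dtype=np.float64).reshape(-1, 3, 3)
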