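"""Synthetic dental-arch phantom and CT-like forward model.

Generates a watertight ground-truth surface (a parametric arch of blended
tooth bumps on a gingiva band) and simulates device-specific scans of it:
partial-volume occupancy, isotropic Gaussian blur, additive noise and an
affine HU calibration. No projection physics — the forward model is
occupancy + blur + noise + calibration only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .geometry import TriangleMesh

HU_SCALE_MIN = -1000.0
HU_SCALE_MAX = 7000.0


class InvalidSpecError(ValueError):
    """Raised for degenerate phantom or device parameters."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic stone-model case."""

    case_id: str = "case01"
    arch_kind: str = "maxilla"
    n_teeth: int = 6
    arch_radius_mm: float = 7.0
    tooth_height_mm: float = 3.5
    gingiva_band_mm: float = 4.0
    rng_seed: int = 0
    surface_resolution_mm: float = 0.18

    def __post_init__(self) -> None:
        if self.arch_kind not in ("maxilla", "mandible"):
            raise InvalidSpecError(f"unknown arch_kind {self.arch_kind!r}")
        if self.n_teeth < 1:
            raise InvalidSpecError("n_teeth must be >= 1")
        for name in ("arch_radius_mm", "tooth_height_mm", "gingiva_band_mm",
                     "surface_resolution_mm"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")


@dataclass(frozen=True)
class DeviceModel:
    """Forward-model parameters emulating one scanner configuration.

    Values are surrogates chosen to produce plausible blur/noise behaviour;
    they are not measurements of any physical device.
    """

    device_id: str
    hu_air: float = -1000.0
    hu_stone: float = 6000.0
    psf_sigma_mm: float = 0.2
    noise_sd_hu: float = 50.0
    hu_gain: float = 1.0
    hu_offset: float = 0.0
    voxel_mm: float = 0.150

    def __post_init__(self) -> None:
        if self.hu_stone <= self.hu_air:
            raise InvalidSpecError("hu_stone must exceed hu_air")
        if self.psf_sigma_mm < 0 or self.noise_sd_hu < 0:
            raise InvalidSpecError("psf_sigma_mm and noise_sd_hu must be >= 0")
        if self.voxel_mm <= 0:
            raise InvalidSpecError("voxel_mm must be positive")


def device_presets(voxel_mm: float = 0.150) -> dict[str, DeviceModel]:
    """Three built-in scanner surrogates.

    The two "planmeca"-like presets share identical physics and differ only in
    the noise realisation drawn at scan time; the "newtom"-like preset has
    lower blur and noise. Air/stone HU put the ideal mid-level at 2500 HU.
    """
    return {
        "Planmeca80": DeviceModel("Planmeca80", psf_sigma_mm=0.30,
                                  noise_sd_hu=80.0, voxel_mm=voxel_mm),
        "Planmeca90": DeviceModel("Planmeca90", psf_sigma_mm=0.30,
                                  noise_sd_hu=80.0, voxel_mm=voxel_mm),
        "NewtomVG": DeviceModel("NewtomVG", psf_sigma_mm=0.15,
                                noise_sd_hu=40.0, voxel_mm=voxel_mm),
    }


@dataclass
class VoxelVolume:
    """3-D scalar grid of HU values with spacing and lower-corner origin."""

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing must be strictly positive")

    def value_range(self) -> tuple[float, float]:
        return float(self.values.min()), float(self.values.max())


# ---------------------------------------------------------------------------
# Ground-truth surface
# ---------------------------------------------------------------------------

def _arch_points(spec: PhantomSpec, t: np.ndarray) -> np.ndarray:
    """Points on the arch centerline for parameter t in [-1, 1] (xy plane)."""
    # slightly elliptical arc spanning ~200 degrees, open toward -y
    half_angle = np.deg2rad(100.0)
    ang = t * half_angle + np.pi / 2.0
    a = spec.arch_radius_mm
    b = 0.85 * spec.arch_radius_mm
    return np.column_stack([a * np.cos(ang), b * np.sin(ang)])


def _implicit_field(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Smooth inside-positive field whose zero level set is the phantom surface."""
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_teeth
    base_h = spec.gingiva_band_mm
    base_r = 1.6

    # dense polyline approximation of the centerline for distance queries
    t_dense = np.linspace(-1.0, 1.0, 81)
    line = _arch_points(spec, t_dense)

    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    dxy = np.full(len(pts), np.inf)
    for seg_a, seg_b in zip(line[:-1], line[1:]):
        ab = seg_b - seg_a
        denom = float(ab @ ab)
        s = np.clip(((x - seg_a[0]) * ab[0] + (y - seg_a[1]) * ab[1]) / denom, 0.0, 1.0)
        px = seg_a[0] + s * ab[0]
        py = seg_a[1] + s * ab[1]
        dxy = np.minimum(dxy, np.hypot(x - px, y - py))

    # gingiva band: rounded extrusion of the centerline over z in [0, base_h]
    dz = np.maximum(0.0, np.abs(z - base_h / 2.0) - (base_h / 2.0 - base_r))
    f_parts = [base_r - np.sqrt(dxy ** 2 + dz ** 2)]

    # tooth bumps: tapered vertical capsules spaced along the arch, jittered
    t_teeth = np.linspace(-0.82, 0.82, n) if n > 1 else np.array([0.0])
    jit = rng.uniform(-0.02, 0.02, size=n) if n > 1 else np.zeros(1)
    heights = spec.tooth_height_mm * rng.uniform(0.85, 1.0, size=n)
    radii = 1.35 * rng.uniform(0.9, 1.05, size=n)
    centers = _arch_points(spec, np.clip(t_teeth + jit, -1, 1))
    for i in range(n):
        cx, cy = centers[i]
        z0 = base_h - 0.8
        z1 = base_h + heights[i]
        s = np.clip((z - z0) / (z1 - z0), 0.0, 1.0)
        r_of_s = radii[i] * (1.0 - 0.55 * s)       # taper toward the tip
        over = np.maximum(0.0, z - z1) + np.maximum(0.0, z0 - z)
        rad = np.hypot(x - cx, y - cy)
        f_parts.append(r_of_s - np.sqrt(rad ** 2 + over ** 2))

    # smooth union keeps the surface C^1 and genus 0
    k = 0.35
    stacked = np.stack(f_parts)
    m = stacked.max(axis=0)
    return m + k * np.log(np.exp((stacked - m) / k).sum(axis=0))


def generate_ground_truth(spec: PhantomSpec) -> TriangleMesh:
    """Watertight arch surface with tooth-like protrusions; deterministic per spec."""
    res = spec.surface_resolution_mm
    pad = 1.2
    r = spec.arch_radius_mm + 2.5
    lo = np.array([-r - pad, -0.9 * r - pad, -pad])
    hi = np.array([r + pad, r + pad, spec.gingiva_band_mm + spec.tooth_height_mm + pad])
    shape = np.maximum(np.ceil((hi - lo) / res).astype(int), 4)
    axes = [lo[d] + (np.arange(shape[d]) + 0.5) * res for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    field = _implicit_field(spec, grid).reshape(shape)
    if field.max() <= 0:
        raise InvalidSpecError("phantom parameters produce an empty solid")
    verts, faces, _, _ = measure.marching_cubes(field, level=0.0,
                                               spacing=(res, res, res))
    verts = verts + lo + 0.5 * res
    mesh = TriangleMesh(verts, faces, provenance=f"{spec.case_id}:ground_truth")
    mesh = _largest_component(mesh)
    if mesh.volume() < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1], mesh.provenance)
    return mesh


def _largest_component(mesh: TriangleMesh) -> TriangleMesh:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)),
                     shape=(mesh.n_vertices, mesh.n_vertices))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp <= 1:
        return mesh
    face_labels = labels[f[:, 0]]
    counts = np.bincount(face_labels, minlength=n_comp)
    return mesh.submesh(face_labels == int(np.argmax(counts)))


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _occupancy(mesh: TriangleMesh, origin: np.ndarray, shape: np.ndarray,
               voxel: float, subsamples: int = 4) -> np.ndarray:
    """Fraction of each voxel inside the (watertight) mesh.

    Parity fill along z: triangles are rasterised onto a ``subsamples``-times
    finer grid of (x, y) ray columns; crossings are paired into inside
    intervals whose overlap with each voxel's z extent is computed exactly.
    """
    nx, ny, nz = (int(s) for s in shape)
    ns = subsamples
    sub = voxel / ns
    # column centers (supersampled in x and y)
    z_edges = origin[2] + np.arange(nz + 1) * voxel

    tri = mesh.triangles()
    crossings_col: list[np.ndarray] = []
    crossings_z: list[np.ndarray] = []
    for a, b, c in tri:
        xy_min = np.minimum(np.minimum(a[:2], b[:2]), c[:2])
        xy_max = np.maximum(np.maximum(a[:2], b[:2]), c[:2])
        i0 = max(0, int(np.floor((xy_min[0] - origin[0]) / sub - 0.5)))
        i1 = min(nx * ns - 1, int(np.ceil((xy_max[0] - origin[0]) / sub - 0.5)))
        j0 = max(0, int(np.floor((xy_min[1] - origin[1]) / sub - 0.5)))
        j1 = min(ny * ns - 1, int(np.ceil((xy_max[1] - origin[1]) / sub - 0.5)))
        if i1 < i0 or j1 < j0:
            continue
        ii = np.arange(i0, i1 + 1)
        jj = np.arange(j0, j1 + 1)
        gx = origin[0] + (ii + 0.5) * sub
        gy = origin[1] + (jj + 0.5) * sub
        px, py = np.meshgrid(gx, gy, indexing="ij")
        # barycentric in xy
        v0 = (b[:2] - a[:2])
        v1 = (c[:2] - a[:2])
        den = v0[0] * v1[1] - v0[1] * v1[0]
        if den == 0:
            continue
        qx = px - a[0]
        qy = py - a[1]
        u = (qx * v1[1] - qy * v1[0]) / den
        v = (qy * v0[0] - qx * v0[1]) / den
        hit = (u >= 0) & (v >= 0) & (u + v <= 1)
        if not hit.any():
            continue
        zc = a[2] + u[hit] * (b[2] - a[2]) + v[hit] * (c[2] - a[2])
        gi, gj = np.meshgrid(ii, jj, indexing="ij")
        crossings_col.append((gi[hit] * ny * ns + gj[hit]).astype(np.int64))
        crossings_z.append(zc)

    occ_sub = np.zeros((nx * ns * ny * ns, nz))
    if crossings_col:
        col = np.concatenate(crossings_col)
        zc = np.concatenate(crossings_z)
        order = np.lexsort((zc, col))
        col, zc = col[order], zc[order]
        # pair consecutive crossings within each column into intervals
        first = np.ones(len(col), dtype=bool)
        first[1:] = col[1:] != col[:-1]
        rank = np.arange(len(col)) - np.maximum.accumulate(
            np.where(first, np.arange(len(col)), 0))
        starts = rank % 2 == 0
        # drop unpaired trailing crossings (degenerate grazing hits)
        last_of_col = np.ones(len(col), dtype=bool)
        last_of_col[:-1] = col[1:] != col[:-1]
        valid_start = starts & ~last_of_col
        za = zc[valid_start]
        zb = zc[np.flatnonzero(valid_start) + 1]
        cols_iv = col[valid_start]
        ka = np.clip(np.searchsorted(z_edges, za, side="right") - 1, 0, nz - 1)
        kb = np.clip(np.searchsorted(z_edges, zb, side="right") - 1, 0, nz - 1)
        same = ka == kb
        np.add.at(occ_sub, (cols_iv[same], ka[same]), (zb[same] - za[same]) / voxel)
        diff = ~same
        np.add.at(occ_sub, (cols_iv[diff], ka[diff]),
                  (z_edges[ka[diff] + 1] - za[diff]) / voxel)
        np.add.at(occ_sub, (cols_iv[diff], kb[diff]),
                  (zb[diff] - z_edges[kb[diff]]) / voxel)
        # full interior voxels via a +1/-1 delta then cumulative sum
        delta = np.zeros((nx * ns * ny * ns, nz + 1))
        np.add.at(delta, (cols_iv[diff], ka[diff] + 1), 1.0)
        np.add.at(delta, (cols_iv[diff], kb[diff]), -1.0)
        occ_sub += np.cumsum(delta[:, :-1], axis=1)

    occ = occ_sub.reshape(nx, ns, ny, ns, nz).mean(axis=(1, 3))
    return np.clip(occ, 0.0, 1.0)


def voxelize(mesh: TriangleMesh, device: DeviceModel, seed: int = 0) -> VoxelVolume:
    """Simulated scan of ``mesh`` on ``device``; deterministic given the seed."""
    if not mesh.is_watertight():
        raise ValueError("voxelize requires a watertight mesh")
    voxel = device.voxel_mm
    pad = max(3.0 * device.psf_sigma_mm, voxel)
    lo, hi = mesh.bounds()
    origin = lo - pad
    shape = np.ceil((hi - lo + 2 * pad) / voxel).astype(int)

    occ = _occupancy(mesh, origin, shape, voxel)
    hu = device.hu_air + occ * (device.hu_stone - device.hu_air)
    if device.psf_sigma_mm > 0:
        hu = ndimage.gaussian_filter(hu, sigma=device.psf_sigma_mm / voxel,
                                     mode="nearest")
    if device.noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, device.noise_sd_hu, size=hu.shape)
    hu = device.hu_gain * hu + device.hu_offset
    hu = np.clip(hu, HU_SCALE_MIN, HU_SCALE_MAX)
    return VoxelVolume(hu, np.full(3, voxel), origin)
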