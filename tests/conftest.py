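"""Shared fixtures: all test geometry is generated programmatically."""
from __future__ import annotations

import numpy as np
import pytest

from meshfidelity.geometry import TriangleMesh
from meshfidelity.phantom import (DeviceModel, PhantomSpec, VoxelVolume,
                                  generate_ground_truth, voxelize)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(case_id="fix", n_teeth=3, arch_radius_mm=5.0,
                       tooth_height_mm=3.0, gingiva_band_mm=3.5,
                       rng_seed=11, surface_resolution_mm=0.25)


@pytest.fixture(scope="session")
def ground_truth(small_spec) -> TriangleMesh:
    return generate_ground_truth(small_spec)


@pytest.fixture(scope="session")
def ideal_device() -> DeviceModel:
    """Sharp, noiseless, uncalibrated scanner."""
    return DeviceModel("ideal", psf_sigma_mm=0.0, noise_sd_hu=0.0,
                       voxel_mm=0.4)


@pytest.fixture(scope="session")
def ideal_volume(ground_truth, ideal_device) -> VoxelVolume:
    return voxelize(ground_truth, ideal_device, seed=0)


@pytest.fixture(scope="session")
def blurred_volume(ground_truth) -> VoxelVolume:
    dev = DeviceModel("blurred", psf_sigma_mm=0.25, noise_sd_hu=0.0,
                      voxel_mm=0.4)
    return voxelize(ground_truth, dev, seed=0)


def make_sphere_volume(radius: float = 5.0, voxel: float = 0.25,
                       inside: float = 1000.0, outside: float = -1000.0,
                       pad: float = 1.5) -> VoxelVolume:
    """Sharp two-valued sphere volume (analytic ground truth for extraction)."""
    half = radius + pad
    n = int(np.ceil(2 * half / voxel))
    coords = -half + (np.arange(n) + 0.5) * voxel
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
    r = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    # two-valued away from the boundary; boundary voxels carry the partial
    # volume fraction (a plain binary field would give marching cubes a
    # staircase surface with ~9% excess area)
    occ = np.clip((radius - r) / voxel + 0.5, 0.0, 1.0)
    values = outside + occ * (inside - outside)
    return VoxelVolume(values, np.full(3, voxel), np.full(3, -half))


def make_tiny_mesh(n_target: int = 120, seed: int = 0) -> TriangleMesh:
    """Small closed mesh (~n_target faces) for brute-force oracle tests."""
    rng = np.random.default_rng(seed)
    # deformed octahedron subdivided once: 32 faces; subdivide more if needed
    verts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                      [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
    faces = np.array([[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
                      [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]])
    while len(faces) * 4 <= n_target:
        verts, faces = _subdivide(verts, faces)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    verts = verts * (1.0 + 0.2 * rng.standard_normal((len(verts), 1)))
    return TriangleMesh(verts, faces, provenance=f"tiny{seed}")


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    verts = list(map(tuple, verts))
    index = {v: i for i, v in enumerate(verts)}

    def midpoint(i, j):
        v = tuple((np.array(verts[i]) + np.array(verts[j])) / 2.0)
        if v not in index:
            index[v] = len(verts)
            verts.append(v)
        return index[v]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
    return np.array(verts), np.array(new_faces)
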