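"""Two-stage rigid registration: coarse correspondence fit, then ICP.

The fine stage samples points on the moving surface (area-weighted, seeded),
pairs each with its exact closest point on the fixed surface, and solves the
rigid least-squares update until the sampled RMS stops improving. Pairs beyond
10x the current median pair distance are dropped per iteration as a simple
outlier guard.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._spatial import SurfaceQuery
from .geometry import DegenerateConfigurationError, RigidTransform, TriangleMesh


class RegistrationFailureError(RuntimeError):
    """Raised when meshes do not overlap enough to register."""


@dataclass(frozen=True)
class ICPConfig:
    n_sample_pairs: int = 50_000
    max_iterations: int = 50
    convergence_tol_mm: float = 1e-6
    rng_seed: int = 0
    outlier_median_factor: float = 10.0
    guard_radius_factor: float = 0.25   # x fixed-mesh bbox diagonal

    def __post_init__(self) -> None:
        if self.n_sample_pairs < 1:
            raise ValueError("n_sample_pairs must be >= 1")
        if self.convergence_tol_mm <= 0:
            raise ValueError("convergence_tol_mm must be positive")


def kabsch(src: np.ndarray, dst: np.ndarray,
           weights: np.ndarray | None = None) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit mapping src points onto dst (no scaling).

    Returns the transform and the residual RMS. SVD-based with the usual
    determinant sign fix to exclude reflections.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 3)
    dst = np.asarray(dst, dtype=float).reshape(-1, 3)
    if len(src) != len(dst) or len(src) < 3:
        raise DegenerateConfigurationError("need >= 3 corresponding point pairs")
    if weights is None:
        weights = np.ones(len(src))
    w = weights / weights.sum()
    mu_s = w @ src
    mu_d = w @ dst
    s = src - mu_s
    d = dst - mu_d
    h = (s * w[:, None]).T @ d
    u, sing, vt = np.linalg.svd(h)
    if sing[1] < 1e-12 * max(sing[0], 1e-300):
        raise DegenerateConfigurationError(
            "correspondence points are collinear or coincident")
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, sign])
    rot = vt.T @ diag @ u.T
    trans = mu_d - rot @ mu_s
    rt = RigidTransform(rot, trans)
    resid = rt.apply(src) - dst
    rms = float(np.sqrt((w * np.einsum("ij,ij->i", resid, resid)).sum()))
    return rt, rms


def coarse_register(src_points: np.ndarray,
                    dst_points: np.ndarray) -> tuple[RigidTransform, float]:
    """Rough alignment from >= 3 hand-picked (or landmark) point pairs."""
    return kabsch(src_points, dst_points)


def icp_register(moving: TriangleMesh, fixed: TriangleMesh,
                 cfg: ICPConfig = ICPConfig(),
                 initial: RigidTransform | None = None,
                 query: SurfaceQuery | None = None,
                 ) -> tuple[RigidTransform, float]:
    """Fine registration of ``moving`` onto ``fixed``.

    Returns the cumulative transform (including ``initial``) and the final
    sampled RMS in mm. The sampled RMS is non-increasing across accepted
    iterations; an update that would increase it terminates the loop. A
    prebuilt ``SurfaceQuery`` over ``fixed`` may be supplied to avoid
    rebuilding the acceleration tree in sweeps.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    if query is None:
        query = SurfaceQuery(fixed)
    elif query.mesh is not fixed:
        raise ValueError("query was built over a different fixed mesh")
    samples = moving.sample_surface(cfg.n_sample_pairs, rng)

    total = initial if initial is not None else RigidTransform.identity()
    current = total.apply(samples)

    d0, _ = query.query(current)
    guard = cfg.guard_radius_factor * fixed.bbox_diagonal()
    if np.min(d0) > guard:
        raise RegistrationFailureError(
            f"meshes do not overlap: nearest pair {np.min(d0):.3g} mm "
            f"exceeds guard radius {guard:.3g} mm")

    prev_rms = float(np.sqrt(np.mean(d0 ** 2)))
    for _ in range(cfg.max_iterations):
        dists, closest = query.query(current)
        med = np.median(dists)
        keep = dists <= cfg.outlier_median_factor * max(med, 1e-300)
        if keep.sum() < 3:
            break
        step, _ = kabsch(current[keep], closest[keep])
        candidate_total = step.compose(total)
        candidate_points = candidate_total.apply(samples)
        d_new, _ = query.query(candidate_points)
        rms = float(np.sqrt(np.mean(d_new ** 2)))
        if rms > prev_rms:
            break  # enforce monotone non-increasing RMS
        total = candidate_total
        current = candidate_points
        improved = prev_rms - rms
        prev_rms = rms
        if improved < cfg.convergence_tol_mm:
            break
    return total, prev_rms


def random_rigid_perturbation(rng: np.random.Generator,
                              angle_deg_range: tuple[float, float] = (1.0, 5.0),
                              translation_mm_range: tuple[float, float] = (0.5, 2.0),
                              about: np.ndarray | None = None) -> RigidTransform:
    """Random rigid motion: axis uniform on the sphere, angle and per-axis
    translation magnitude uniform in the given ranges, random signs.

    ``about`` rotates around that point instead of the origin (keeps the
    perturbed mesh near the original for far-from-origin geometry).
    """
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(*angle_deg_range))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    trans = (rng.uniform(*translation_mm_range, size=3)
             * rng.choice([-1.0, 1.0], size=3))
    rt = RigidTransform(rot, trans)
    if about is not None:
        about = np.asarray(about, dtype=float)
        shift_out = RigidTransform(np.eye(3), -about)
        shift_back = RigidTransform(np.eye(3), about)
        rt = shift_back.compose(rt.compose(shift_out))
    return rt


def software_self_test(mesh: TriangleMesh, n_trials: int, seed: int = 0,
                       icp: ICPConfig | None = None,
                       n_landmarks: int = 4) -> tuple[float, float]:
    """Clone-perturb-register accuracy check of the registration stack.

    Each trial clones the mesh, applies a random rigid motion, registers the
    clone back (coarse fit on landmark vertices, then ICP) and measures the
    mean face-centroid deviation from the original. Returns (mean, SD) of the
    per-trial mean deviations.
    """
    from .metrics import face_deviations  # local import avoids a cycle

    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    icp = icp or ICPConfig(n_sample_pairs=5000, rng_seed=seed)
    # well-spread landmark vertices stand in for operator-picked points
    extremes = [int(np.argmin(mesh.vertices[:, d])) for d in range(3)]
    extremes += [int(np.argmax(mesh.vertices[:, d])) for d in range(3)]
    landmarks = np.unique(extremes)[:max(3, n_landmarks)]
    center = mesh.vertices.mean(axis=0)

    means = []
    for _ in range(n_trials):
        perturb = random_rigid_perturbation(rng, about=center)
        clone = mesh.transformed(perturb, provenance="clone")
        rough, _ = coarse_register(clone.vertices[landmarks],
                                   mesh.vertices[landmarks])
        total, _ = icp_register(clone, mesh, icp, initial=rough)
        registered = clone.transformed(total)
        sample = face_deviations(registered, mesh)
        means.append(float(np.mean(sample.distances)))
    means_arr = np.asarray(means)
    sd = float(means_arr.std(ddof=1)) if n_trials > 1 else 0.0
    return float(means_arr.mean()), sd
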