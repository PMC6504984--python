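import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_tiny_mesh
from meshfidelity._spatial import SurfaceQuery
from meshfidelity.geometry import TriangleMesh
from meshfidelity.metrics import (DeviationSample, deviation_map,
                                  face_deviations, summarize,
                                  write_deviation_ply)


def oracle_point_to_triangle(p, tri):
    """Independent formulation: min over the plane projection (if interior)
    and the three edge segments."""
    a, b, c = tri
    n = np.cross(b - a, c - a)
    best = np.inf
    nn = n @ n
    if nn > 0:
        proj = p - ((p - a) @ n / nn) * n
        # barycentric test of the projection
        m = np.column_stack([b - a, c - a])
        uv, *_ = np.linalg.lstsq(m, proj - a, rcond=None)
        if uv[0] >= -1e-14 and uv[1] >= -1e-14 and uv.sum() <= 1 + 1e-14:
            best = np.linalg.norm(p - proj)
    for s, e in ((a, b), (b, c), (c, a)):
        d = e - s
        t = np.clip((p - s) @ d / (d @ d), 0.0, 1.0)
        best = min(best, np.linalg.norm(p - (s + t * d)))
    return best


def oracle_all_triangles(points, mesh):
    tris = mesh.triangles()
    return np.array([min(oracle_point_to_triangle(p, t) for t in tris)
                     for p in points])


class TestFaceDeviations:
    def test_identical_meshes_zero(self):
        mesh = make_tiny_mesh(128)
        sample = face_deviations(mesh, mesh)
        assert len(sample) == mesh.n_faces
        assert np.all(sample.distances < 1e-14)

    def test_unit_square_closed_form(self):
        reference = TriangleMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float),
            np.array([[0, 1, 2], [1, 3, 2]]))
        test = TriangleMesh(
            np.array([[0.4, 0.4, 0.25], [0.6, 0.4, 0.25], [0.5, 0.6, 0.25]]),
            np.array([[0, 1, 2]]))
        sample = face_deviations(test, reference)
        assert sample.distances[0] == pytest.approx(0.25, abs=1e-14)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_all_triangles_oracle(self, seed):
        reference = make_tiny_mesh(128, seed=seed)
        test = make_tiny_mesh(32, seed=seed + 100)
        sample = face_deviations(test, reference)
        expected = oracle_all_triangles(test.face_centroids(), reference)
        np.testing.assert_allclose(sample.distances, expected, atol=1e-12)

    def test_empty_reference_rejected(self):
        mesh = make_tiny_mesh(32)
        empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError, match="reference"):
            face_deviations(mesh, empty)

    def test_order_matches_faces(self):
        reference = make_tiny_mesh(512, seed=1)
        test = make_tiny_mesh(128, seed=2)
        sample = face_deviations(test, reference)
        sub = test.submesh(np.arange(test.n_faces) % 2 == 0)
        sub_sample = face_deviations(sub, reference)
        np.testing.assert_allclose(sub_sample.distances,
                                   sample.distances[::2], atol=1e-12)


class TestSummarize:
    def test_published_row_newtom(self):
        # median 0.045, IQR 0.063 -> DI 2.835, printed 2.8
        sample = DeviationSample([0.010, 0.020, 0.045, 0.083, 0.090])
        s = summarize(sample)
        assert s.median_mm == pytest.approx(0.045)
        assert s.iqr_mm == pytest.approx(0.063)
        assert s.di == pytest.approx(2.835)
        assert round(s.di, 1) == 2.8

    def test_published_row_planmeca(self):
        # median 0.051, IQR 0.062 -> DI 3.162, printed 3.2
        sample = DeviationSample([0.010, 0.020, 0.051, 0.082, 0.090])
        s = summarize(sample)
        assert s.di == pytest.approx(3.162)
        assert round(s.di, 1) == 3.2

    def test_constant_sample(self):
        s = summarize(DeviationSample([0.05] * 10))
        assert s.median_mm == 0.05
        assert s.iqr_mm == 0.0
        assert s.di == 0.0
        assert s.sd_mm == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            summarize(DeviationSample([]))

    def test_negative_distances_rejected(self):
        with pytest.raises(ValueError):
            DeviationSample([-0.1, 0.2])

    def test_di_formula_invariant(self):
        rng = np.random.default_rng(0)
        s = summarize(DeviationSample(rng.exponential(0.05, size=500)))
        assert s.di == s.median_mm * s.iqr_mm * 1000.0
        assert s.p95_mm >= s.median_mm

    @given(st.floats(0.1, 10.0), st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_di_scales_quadratically(self, c, seed):
        rng = np.random.default_rng(seed)
        d = rng.exponential(0.05, size=200)
        s1 = summarize(DeviationSample(d))
        s2 = summarize(DeviationSample(c * d))
        assert s2.di == pytest.approx(c * c * s1.di, rel=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.exponential(0.05, size=101)
        s1 = summarize(DeviationSample(d))
        s2 = summarize(DeviationSample(rng.permutation(d)))
        # order statistics are exactly invariant; mean/SD only to summation
        # round-off
        assert (s1.median_mm, s1.iqr_mm, s1.di, s1.p95_mm) == \
            (s2.median_mm, s2.iqr_mm, s2.di, s2.p95_mm)
        assert s2.mean_mm == pytest.approx(s1.mean_mm, rel=1e-12)
        assert s2.sd_mm == pytest.approx(s1.sd_mm, rel=1e-10)

    def test_p95_ignores_outlier_magnitude(self):
        # 5% extreme outliers injected: the 95% bound trims them, so their
        # magnitude does not matter
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 0.1, size=960)
        small = summarize(DeviationSample(np.r_[base, np.full(50, 10.0)]))
        large = summarize(DeviationSample(np.r_[base, np.full(50, 1e6)]))
        assert small.p95_mm == large.p95_mm
        assert small.p95_mm < 0.11


class TestDeviationMap:
    def test_map_matches_faces(self):
        mesh = make_tiny_mesh(128)
        sample = face_deviations(mesh, make_tiny_mesh(128, seed=9))
        m = deviation_map(mesh, sample)
        assert len(m) == mesh.n_faces
        assert m.max() == sample.distances.max()

    def test_identical_meshes_zero_map(self):
        mesh = make_tiny_mesh(32)
        m = deviation_map(mesh, face_deviations(mesh, mesh))
        assert np.all(m < 1e-14)

    def test_length_mismatch_rejected(self):
        mesh = make_tiny_mesh(32)
        with pytest.raises(ValueError, match="faces"):
            deviation_map(mesh, DeviationSample(np.zeros(3)))

    def test_ply_export(self, tmp_path):
        mesh = make_tiny_mesh(32)
        sample = face_deviations(mesh, make_tiny_mesh(32, seed=5))
        path = tmp_path / "map.ply"
        write_deviation_ply(mesh, sample, path)
        text = path.read_text()
        assert text.startswith("ply")
        assert f"element face {mesh.n_faces}" in text


class TestSurfaceQuery:
    def test_closest_points_lie_on_surface(self):
        mesh = make_tiny_mesh(128, seed=4)
        query = SurfaceQuery(mesh)
        pts = np.random.default_rng(0).normal(size=(50, 3)) * 2
        dists, closest = query.query(pts)
        expected = oracle_all_triangles(pts, mesh)
        np.testing.assert_allclose(dists, expected, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(pts - closest, axis=1),
                                   dists, atol=1e-12)
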