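"""Deviation distributions between a registered test mesh and a reference.

Per-face absolute distances (face centroid to exact closest point on the
reference surface) and their summary statistics: median, IQR, the
Dissimilarity Index ``median * IQR * 1000``, the 95% bound, mean and SD.

Quantile rule: linear interpolation between order statistics (numpy default);
median and IQR depend on this choice at small n, so it is fixed here.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._spatial import SurfaceQuery
from .geometry import TriangleMesh


@dataclass
class DeviationSample:
    """Absolute per-face distances in mm, in face order."""

    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float).reshape(-1)
        if len(self.distances) and self.distances.min() < 0:
            raise ValueError("deviations must be non-negative")

    def __len__(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class DeviationSummary:
    median_mm: float
    iqr_mm: float
    di: float
    p95_mm: float
    mean_mm: float
    sd_mm: float
    n_faces: int

    @classmethod
    def from_sample(cls, sample: DeviationSample) -> "DeviationSummary":
        return summarize(sample)


def face_deviations(test: TriangleMesh, reference: TriangleMesh,
                    query: SurfaceQuery | None = None) -> DeviationSample:
    """Distance from every test-face centroid to the reference surface.

    Meshes must already be registered into one frame. Passing a prebuilt
    ``SurfaceQuery`` over the reference avoids rebuilding the tree in sweeps.
    """
    if reference.n_faces == 0:
        raise ValueError("reference mesh is empty")
    if test.n_faces == 0:
        raise ValueError("test mesh is empty")
    if query is None:
        query = SurfaceQuery(reference)
    elif query.mesh is not reference:
        raise ValueError("query was built over a different reference mesh")
    dists, _ = query.query(test.face_centroids())
    return DeviationSample(dists)


def summarize(sample: DeviationSample) -> DeviationSummary:
    """The per-pair summary statistics, with DI = median * IQR * 1000."""
    if len(sample) == 0:
        raise ValueError("cannot summarize an empty deviation sample")
    d = sample.distances
    median = float(np.quantile(d, 0.5))
    q25, q75 = np.quantile(d, [0.25, 0.75])
    iqr = float(q75 - q25)
    return DeviationSummary(
        median_mm=median,
        iqr_mm=iqr,
        di=median * iqr * 1000.0,
        p95_mm=float(np.quantile(d, 0.95)),
        mean_mm=float(d.mean()),
        sd_mm=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        n_faces=len(d),
    )


def deviation_map(test: TriangleMesh, sample: DeviationSample) -> np.ndarray:
    """Per-face scalar field of distances, aligned with ``test.faces``."""
    if len(sample) != test.n_faces:
        raise ValueError(
            f"sample has {len(sample)} distances for {test.n_faces} faces")
    return sample.distances.copy()


def write_deviation_ply(test: TriangleMesh, sample: DeviationSample,
                        path) -> None:
    """ASCII PLY export with a per-face 'quality' channel holding distances."""
    values = deviation_map(test, sample)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {test.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {test.n_faces}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("property float quality\n")
        fh.write("end_header\n")
        for v in test.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f, q in zip(test.faces, values):
            fh.write(f"3 {f[0]} {f[1]} {f[2]} {q:.6f}\n")
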