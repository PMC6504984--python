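"""Per-case pipeline orchestration and study-level descriptive tables.

For every device volume: extract a mesh at each sweep level, co-register the
whole group to a hub mesh (the mid-sweep extraction, as the most complete),
crop all meshes simultaneously with one region, register each cropped mesh to
the reference surface, summarise its deviations, and pick the best threshold
by minimum Dissimilarity Index (ties break toward the lower HU).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._spatial import SurfaceQuery
from .geometry import TriangleMesh
from .meshing import CropRegion, ThresholdSweep, crop, extract_mesh
from .metrics import DeviationSummary, face_deviations, summarize
from .phantom import VoxelVolume
from .registration import ICPConfig, icp_register

log = logging.getLogger(__name__)


class SweepStageError(RuntimeError):
    """Pipeline failure annotated with (case, device, level) context."""


@dataclass
class SweepResult:
    case_id: str
    device_id: str
    per_threshold: dict[float, DeviationSummary]
    best_threshold: float
    best_summary: DeviationSummary

    def __post_init__(self) -> None:
        best_di = self.per_threshold[self.best_threshold].di
        if any(s.di < best_di for s in self.per_threshold.values()):
            raise ValueError("best_threshold does not attain the minimum DI")


def _select_best(per_threshold: dict[float, DeviationSummary]) -> float:
    # min DI; ties toward the lower HU (dict iteration follows insertion order
    # of the strictly increasing sweep levels)
    best_level, best_di = None, np.inf
    for level, summary in per_threshold.items():
        if summary.di < best_di:
            best_level, best_di = level, summary.di
    return best_level


def run_case(reference: TriangleMesh, volumes: dict[str, VoxelVolume],
             sweep: ThresholdSweep, crop_region: CropRegion,
             icp: ICPConfig, case_id: str = "case") -> dict[str, SweepResult]:
    """Full per-case pipeline; see module docstring."""
    if reference.n_faces == 0:
        raise ValueError("reference mesh is empty")
    if not volumes:
        raise ValueError("need at least one device volume")

    def stage(device: str, level, exc: Exception) -> SweepStageError:
        return SweepStageError(
            f"case={case_id} device={device} level={level}: {exc}")

    meshes: dict[tuple[str, float], TriangleMesh] = {}
    for device, vol in volumes.items():
        for level in sweep.levels:
            try:
                meshes[(device, level)] = extract_mesh(
                    vol, level, provenance=f"{case_id}/{device}/{level:g}")
            except Exception as exc:
                raise stage(device, level, exc) from exc

    # group registration to the hub (mid-sweep extraction of the first device)
    hub_level = sweep.levels[len(sweep.levels) // 2]
    first_device = next(iter(volumes))
    hub = meshes[(first_device, hub_level)]
    hub_query = SurfaceQuery(hub)
    registered: dict[tuple[str, float], TriangleMesh] = {}
    for key, mesh in meshes.items():
        if mesh is hub:
            registered[key] = mesh
            continue
        try:
            rt, _ = icp_register(mesh, hub, icp, query=hub_query)
        except Exception as exc:
            raise stage(key[0], key[1], exc) from exc
        registered[key] = mesh.transformed(rt)

    # simultaneous crop of the whole co-registered group
    keys = list(registered)
    cropped_list = crop([registered[k] for k in keys], crop_region)
    cropped = dict(zip(keys, cropped_list))

    # per-pair registration to the reference, deviations, summaries
    ref_query = SurfaceQuery(reference)
    results: dict[str, SweepResult] = {}
    for device in volumes:
        per_threshold: dict[float, DeviationSummary] = {}
        for level in sweep.levels:
            mesh = cropped[(device, level)]
            try:
                rt, _ = icp_register(mesh, reference, icp, query=ref_query)
                aligned = mesh.transformed(rt)
                sample = face_deviations(aligned, reference, query=ref_query)
                per_threshold[level] = summarize(sample)
            except Exception as exc:
                raise stage(device, level, exc) from exc
            log.debug("case=%s device=%s level=%g di=%.3f",
                      case_id, device, level, per_threshold[level].di)
        best = _select_best(per_threshold)
        results[device] = SweepResult(case_id, device, per_threshold,
                                      best, per_threshold[best])
    return results


# ---------------------------------------------------------------------------
# Study tables
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ["case_id", "device", "threshold", "p95_mm", "median_mm",
                 "iqr_mm", "di"]


def results_to_table(case_results: list[dict[str, SweepResult]]) -> pd.DataFrame:
    """Best-threshold rows, one per case x device (the study's Table-2 shape)."""
    rows = []
    for per_device in case_results:
        for device, res in per_device.items():
            s = res.best_summary
            rows.append((res.case_id, device, res.best_threshold,
                         s.p95_mm, s.median_mm, s.iqr_mm, s.di))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def sweep_long_table(case_results: list[dict[str, SweepResult]]) -> pd.DataFrame:
    """All case x device x threshold summaries (input for the two-way ANOVA)."""
    rows = []
    for per_device in case_results:
        for device, res in per_device.items():
            for level, s in res.per_threshold.items():
                rows.append((res.case_id, device, level, s.p95_mm,
                             s.median_mm, s.iqr_mm, s.di))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _ci_half_width(values: np.ndarray) -> float:
    n = len(values)
    if n < 2:
        return float("nan")
    return float(stats.t.ppf(0.975, n - 1) * values.std(ddof=1) / np.sqrt(n))


def summarize_study(table: pd.DataFrame) -> pd.DataFrame:
    """Per-device and pooled descriptive statistics of the best-threshold rows.

    Requires a complete balanced crossing (every case appears once per
    device). Single-row groups get NaN dispersion values.
    """
    counts = table.groupby(["case_id", "device"]).size()
    if (counts != 1).any():
        raise ValueError("table is not a balanced case x device crossing")
    per_device = table.groupby("device").size()
    if per_device.nunique() != 1:
        raise ValueError("unequal number of cases per device")

    def group_stats(label: str, g: pd.DataFrame) -> dict:
        thr = g["threshold"].to_numpy(dtype=float)
        med = g["median_mm"].to_numpy(dtype=float)
        return {
            "group": label,
            "n": len(g),
            "mean_threshold": thr.mean(),
            "min_threshold": thr.min(),
            "max_threshold": thr.max(),
            "sd_threshold": thr.std(ddof=1) if len(thr) > 1 else float("nan"),
            "ci95_threshold": _ci_half_width(thr),
            "mean_median_mm": med.mean(),
            "sd_median_mm": med.std(ddof=1) if len(med) > 1 else float("nan"),
            "min_median_mm": med.min(),
            "max_median_mm": med.max(),
            "ci95_median_mm": _ci_half_width(med),
            "mean_p95_mm": g["p95_mm"].mean(),
            "min_p95_mm": g["p95_mm"].min(),
            "max_p95_mm": g["p95_mm"].max(),
            "mean_iqr_mm": g["iqr_mm"].mean(),
            "mean_di": g["di"].mean(),
        }

    rows = [group_stats("Total", table)]
    for device, g in table.groupby("device", sort=False):
        rows.append(group_stats(str(device), g))
    return pd.DataFrame(rows)
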