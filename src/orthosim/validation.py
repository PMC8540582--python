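"""Quantitative validation: rigid registration and signed error maps.

The validation loop mirrors how a planning prediction is scored against a
post-operative scan: (1) the transform actually applied to each bone
fragment is recovered by rigidly registering its pre-operative surface to
the post-operative one with point-to-point ICP; (2) the simulated tissue
surface is compared to the reference surface with a signed closest-point
distance (negative = the simulation lies inside the reference); (3) the
cumulative percentage of surface area with |error| below 1 mm-spaced
thresholds is reported, 3 mm being the clinically acceptable limit.

Percentages are area-weighted (one third of incident face area per
vertex); plain vertex counting is available behind a flag.  Regions
outside the clinical region of interest (neck, occiput) are excluded via
a vertex mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    MeshValidationError,
    SurfaceMesh,
    Transform,
    closest_point_query,
    signed_distance_query,
    write_vtk,
)

__all__ = [
    "RegistrationResult",
    "ErrorMap",
    "icp_register",
    "compute_error_map",
    "error_report",
    "DEFAULT_THRESHOLDS_MM",
    "CLINICAL_THRESHOLD_MM",
]

DEFAULT_THRESHOLDS_MM = tuple(float(t) for t in range(1, 9))
CLINICAL_THRESHOLD_MM = 3.0
COLORMAP_RANGE_MM = 4.0  # +-range convention for error color maps


@dataclass
class RegistrationResult:
    transform: Transform
    rms_residual: float
    iterations: int
    converged: bool
    rms_history: list[float] = field(default_factory=list)


def _best_fit_rigid(src: np.ndarray, dst: np.ndarray) -> Transform:
    """Least-squares rigid transform src -> dst (Procrustes/SVD with a
    reflection guard)."""
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    R = Vt.T @ U.T
    if np.linalg.det(R) < 0:
        Vt2 = Vt.copy()
        Vt2[-1] *= -1.0
        R = Vt2.T @ U.T
    return Transform(R, cd - R @ cs)


def icp_register(
    source: SurfaceMesh,
    target: SurfaceMesh,
    max_iters: int = 100,
    tol: float = 1e-8,
) -> RegistrationResult:
    """Point-to-point ICP: alternate closest-point correspondences on the
    target surface with the best-fit rigid transform, until the RMS
    residual change drops below ``tol`` (mm).  Assumes rough initial
    overlap; no outlier trimming."""
    if source.n_vertices == 0 or target.n_faces == 0:
        raise MeshValidationError("ICP needs a non-empty source and target")
    # only vertices that belong to the surface take part in the fit
    pts = (
        source.vertices[source.used_vertices()]
        if source.n_faces
        else source.vertices
    ).copy()
    current = Transform.identity()
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        moved = current.apply(pts)
        dist, closest, _ = closest_point_query(moved, target)
        rms = float(np.sqrt(np.mean(dist**2)))
        history.append(rms)
        step = _best_fit_rigid(moved, closest)
        current = step.compose(current)
        if len(history) >= 2 and abs(history[-2] - history[-1]) < tol:
            converged = True
            break
        if rms < tol:
            converged = True
            break
    return RegistrationResult(current, history[-1], it, converged, history)


@dataclass
class ErrorMap:
    """Signed per-vertex error against a reference surface plus the
    cumulative area fraction below each threshold."""

    per_vertex_signed_error: np.ndarray  # mm; negative = inside reference
    roi_mask: np.ndarray  # bool per vertex, True = inside the ROI
    thresholds: np.ndarray  # mm, sorted ascending
    cumulative_pct: np.ndarray  # % of ROI surface area with |err| <= threshold
    vertex_areas: np.ndarray


def compute_error_map(
    sim_surface: SurfaceMesh,
    reference: SurfaceMesh,
    roi: np.ndarray | None = None,
    thresholds=DEFAULT_THRESHOLDS_MM,
    allow_open: bool = False,
    area_weighted: bool = True,
) -> ErrorMap:
    """Signed closest-point error of every simulated vertex against the
    reference surface, with cumulative area percentages per threshold."""
    thresholds = np.asarray(thresholds, float)
    if np.any(thresholds <= 0) or np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be positive and sorted ascending")
    err = signed_distance_query(sim_surface.vertices, reference, allow_open=allow_open)
    if roi is None:
        roi_mask = np.ones(sim_surface.n_vertices, bool)
    else:
        roi_mask = np.asarray(roi, bool).reshape(sim_surface.n_vertices)
    weights = (
        sim_surface.vertex_areas() if area_weighted else np.ones(sim_surface.n_vertices)
    )
    w = weights * roi_mask
    total = w.sum()
    if total <= 0:
        raise ValueError("ROI mask excludes the whole surface")
    pct = np.minimum(
        100.0,
        np.array([100.0 * w[np.abs(err) <= t].sum() / total for t in thresholds]),
    )
    return ErrorMap(err, roi_mask, thresholds, pct, weights)


def pct_below(emap: ErrorMap, threshold_mm: float) -> float:
    w = emap.vertex_areas * emap.roi_mask
    pct = 100.0 * w[np.abs(emap.per_vertex_signed_error) <= threshold_mm].sum() / w.sum()
    return float(min(100.0, pct))


def error_report(
    emap: ErrorMap,
    clinical_threshold: float = CLINICAL_THRESHOLD_MM,
    csv_path: str | None = None,
    vtk_path: str | None = None,
    surface: SurfaceMesh | None = None,
) -> dict:
    """Summarize an error map: % of ROI area within the clinical
    threshold, signed-error statistics, cumulative curve.  Optionally
    writes the curve as CSV and the per-vertex error as a VTK overlay
    (color-map range metadata is +-4 mm)."""
    inroi = emap.roi_mask
    err = emap.per_vertex_signed_error[inroi]
    summary = {
        "pct_within_clinical": pct_below(emap, clinical_threshold),
        "clinical_threshold_mm": float(clinical_threshold),
        "min_signed_error_mm": float(err.min()),
        "max_signed_error_mm": float(err.max()),
        "mean_signed_error_mm": float(err.mean()),
        "thresholds_mm": emap.thresholds.tolist(),
        "cumulative_pct": emap.cumulative_pct.tolist(),
        "colormap_range_mm": COLORMAP_RANGE_MM,
    }
    if csv_path is not None:
        import pandas as pd

        pd.DataFrame(
            {"threshold_mm": emap.thresholds, "cumulative_pct": emap.cumulative_pct}
        ).to_csv(csv_path, index=False)
    if vtk_path is not None:
        if surface is None:
            raise ValueError("vtk_path requires the simulated surface")
        write_vtk(
            surface,
            {
                "signed_error_mm": emap.per_vertex_signed_error,
                "roi_mask": emap.roi_mask.astype(float),
            },
            vtk_path,
        )
    return summary
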