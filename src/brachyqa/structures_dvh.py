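"""Contour rasterization, DVH computation and plan-criteria checks.

ROIs are stacks of closed planar polygons (mm, grouped by slice z).  A voxel
belongs to a structure iff its centre lies inside the slice's polygon set
under the even-odd rule (compound polygons such as annular applicator
cross-sections are handled by XOR-ing per-polygon membership).  No
partial-volume weighting is applied, so rasterized volumes depend on the
grid size — the transparent mechanism behind grid-size-dependent DVH
parameters.

DVH metrics are computed from the exact sorted voxel doses: Dx% is the
minimum dose received by the hottest x% of the structure volume, Dxcc the
minimum dose received by the hottest x cm^3, with linear interpolation
between adjacent sorted doses at fractional voxel counts.  Exported curves
are binned at 1 cGy for plotting only; metrics never pass through bins.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath

from .dose_engine import DoseVolume, GridSpec
from .errors import (
    ConfigurationError,
    EmptyInputWarning,
    EmptyStructureError,
    InsufficientVolumeError,
    ValidationError,
)

ROLES = ("hrctv", "bladder", "rectum", "sigmoid", "applicator", "other")


@dataclass
class ROI:
    """A region of interest: per-slice lists of closed polygons.

    ``slices`` maps slice z (mm) to a list of (N, 2) vertex arrays (mm).
    Polygons are implicitly closed (last vertex connects to the first).
    """

    name: str
    role: str = "other"
    slices: dict[float, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"ROI {self.name!r}: unknown role {self.role!r}")
        for z, polys in self.slices.items():
            if not np.isfinite(z):
                raise ValidationError(f"ROI {self.name!r}: non-finite slice z")
            self.slices[z] = [np.asarray(p, float) for p in polys]
            for p in self.slices[z]:
                if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
                    raise ValidationError(
                        f"ROI {self.name!r} slice z={z}: polygon needs >= 3 (x, y) vertices"
                    )


@dataclass
class StructureSet:
    """Named ROIs of a plan's structure set."""

    rois: dict[str, ROI] = field(default_factory=dict)

    def add(self, roi: ROI) -> None:
        self.rois[roi.name] = roi

    def by_role(self, role: str) -> ROI | None:
        for roi in self.rois.values():
            if roi.role == role:
                return roi
        return None

    def slice_zs(self) -> np.ndarray:
        zs = sorted({z for roi in self.rois.values() for z in roi.slices})
        return np.asarray(zs)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(min_xyz, max_xyz) in mm over every contour vertex."""
        mins, maxs = [], []
        for roi in self.rois.values():
            for z, polys in roi.slices.items():
                for p in polys:
                    mins.append([p[:, 0].min(), p[:, 1].min(), z])
                    maxs.append([p[:, 0].max(), p[:, 1].max(), z])
        if not mins:
            raise ValidationError("structure set has no contours")
        return np.min(mins, axis=0), np.max(maxs, axis=0)


@dataclass
class DVHResult:
    """Cumulative DVH and dosimetric parameters for one structure."""

    name: str
    volume_cc: float
    voxel_volume_cc: float
    metrics: dict[str, float]
    bins_cgy: np.ndarray
    volumes_cc: np.ndarray
    applicator_excluded: bool = False
    grid_id: str = ""


def rasterize(roi: ROI, grid: GridSpec) -> np.ndarray:
    """Boolean voxel mask of ``roi`` on ``grid`` (shape (nz, ny, nx)).

    Each contour slice is matched to the nearest grid slice; slices further
    than half the grid slice spacing from any grid slice are skipped with a
    warning.  Membership is voxel-centre point-in-polygon (even-odd rule).
    """
    xs, ys, zs = grid.axis_coords()
    dz = grid.spacing_mm[2]
    X, Y = np.meshgrid(xs, ys)  # (ny, nx)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    mask = np.zeros(grid.shape, dtype=bool)
    matched_any = False
    for z_roi, polys in roi.slices.items():
        iz = int(np.argmin(np.abs(zs - z_roi)))
        if abs(zs[iz] - z_roi) > dz / 2:
            warnings.warn(
                f"ROI {roi.name!r} slice z={z_roi} mm is further than dz/2 from any "
                "grid slice; skipped", EmptyInputWarning, stacklevel=2)
            continue
        matched_any = True
        inside = np.zeros(len(pts), dtype=bool)
        for poly in polys:
            ring = np.vstack([poly, poly[:1]])  # Path's closed form consumes the last vertex
            inside ^= MplPath(ring, closed=True).contains_points(pts)
        mask[iz] ^= inside.reshape(X.shape)
    if not matched_any:
        warnings.warn(f"ROI {roi.name!r} does not overlap the grid; empty mask",
                      EmptyInputWarning, stacklevel=2)
    return mask


def exclude_applicator(target_mask: np.ndarray, applicator_mask: np.ndarray) -> np.ndarray:
    """Target voxels outside the applicator: ``target AND NOT applicator``."""
    if target_mask.shape != applicator_mask.shape:
        raise ConfigurationError(
            f"mask grids differ: {target_mask.shape} vs {applicator_mask.shape}"
        )
    return target_mask & ~applicator_mask


_METRIC_RE = re.compile(r"^D\s*([0-9.]+)\s*(%|cc)$", re.IGNORECASE)


def _dose_at_sorted_position(sorted_desc: np.ndarray, m: float) -> float:
    """Dose at fractional position ``m`` (voxels, 1-based) in the descending
    sort; linear interpolation between adjacent voxels, clamped to [1, N]."""
    n = len(sorted_desc)
    m = min(max(m, 1.0), float(n))
    lo = int(np.floor(m))
    hi = int(np.ceil(m))
    if lo == hi:
        return float(sorted_desc[lo - 1])
    w = m - lo
    return float((1 - w) * sorted_desc[lo - 1] + w * sorted_desc[hi - 1])


def dvh_metric(doses_cgy: np.ndarray, voxel_volume_cc: float, spec: str) -> float:
    """Evaluate a DVH parameter (``"D90%"``, ``"D2cc"``, ...) from voxel doses.

    Dx% = minimum dose to the hottest x% of the structure volume; Dxcc = the
    minimum dose to the hottest x cm^3.
    """
    m = _METRIC_RE.match(spec.strip())
    if not m:
        raise ConfigurationError(f"cannot parse DVH metric spec {spec!r}")
    x = float(m.group(1))
    unit = m.group(2).lower()
    doses = np.sort(np.asarray(doses_cgy, float))[::-1]
    n = len(doses)
    if n == 0:
        raise EmptyStructureError("DVH metric requested on an empty structure")
    if unit == "%":
        if not 0 < x <= 100:
            raise ConfigurationError(f"Dx% requires 0 < x <= 100, got {x}")
        pos = x / 100.0 * n
    else:
        total_cc = n * voxel_volume_cc
        if x > total_cc:
            raise InsufficientVolumeError(
                f"D{x}cc requested but structure volume is only {total_cc:.3f} cc"
            )
        pos = x / voxel_volume_cc
    return _dose_at_sorted_position(doses, pos)


DEFAULT_METRICS = ("D100%", "D90%", "D10cc", "D2cc", "D0.1cc")


def cumulative_dvh(dose: DoseVolume, mask: np.ndarray, name: str,
                   metrics: tuple[str, ...] = DEFAULT_METRICS,
                   applicator_excluded: bool = False) -> DVHResult:
    """Cumulative DVH and dosimetric parameters for the voxels in ``mask``.

    Metrics whose requested absolute volume exceeds the structure volume are
    omitted from the result rather than raising (small OARs on coarse grids
    legitimately have < 10 cc).
    """
    if mask.shape != dose.values.shape:
        raise ConfigurationError("mask and dose volume are on different grids")
    doses = dose.values[mask]
    if doses.size == 0:
        raise EmptyStructureError(f"structure {name!r} has an empty mask on this grid")
    vox_cc = dose.grid.voxel_volume_cc
    volume_cc = doses.size * vox_cc
    out_metrics: dict[str, float] = {}
    for spec in metrics:
        try:
            out_metrics[spec] = dvh_metric(doses, vox_cc, spec)
        except InsufficientVolumeError:
            continue
    bins = np.arange(0.0, float(np.ceil(doses.max())) + 2.0, 1.0)
    volumes = np.array([(doses >= b).sum() * vox_cc for b in bins])
    return DVHResult(
        name=name, volume_cc=volume_cc, voxel_volume_cc=vox_cc,
        metrics=out_metrics, bins_cgy=bins, volumes_cc=volumes,
        applicator_excluded=applicator_excluded,
    )


#: clinical plan criteria for a tandem-and-ring cervix plan (cGy per fraction)
DEFAULT_CRITERIA = (
    {"roi": "hrctv", "metric": "D90%", "op": ">=", "limit_cgy": 550.0},
    {"roi": "bladder", "metric": "D2cc", "op": "<", "limit_cgy": 460.0},
    {"roi": "rectum", "metric": "D2cc", "op": "<", "limit_cgy": 420.0},
    {"roi": "sigmoid", "metric": "D2cc", "op": "<", "limit_cgy": 420.0},
)


def check_plan_criteria(metrics_by_roi: dict[str, dict[str, float]],
                        criteria=DEFAULT_CRITERIA) -> dict:
    """Evaluate per-ROI dose criteria; limits written with ``<`` are strict.

    ``metrics_by_roi`` maps ROI name (or role) to its metric dict.  A
    criterion whose ROI or metric is missing is reported unevaluable and
    fails the overall check.
    """
    rows = []
    overall = True
    lookup = {k.lower(): v for k, v in metrics_by_roi.items()}
    for crit in criteria:
        roi = crit["roi"].lower()
        metric = crit["metric"]
        limit = float(crit["limit_cgy"])
        op = crit["op"]
        value = lookup.get(roi, {}).get(metric)
        if value is None:
            rows.append({**crit, "value_cgy": None, "passed": False, "evaluable": False,
                         "margin_cgy": None})
            overall = False
            continue
        if op == "<":
            passed = value < limit
            margin = limit - value
        elif op == "<=":
            passed = value <= limit
            margin = limit - value
        elif op == ">=":
            passed = value >= limit
            margin = value - limit
        elif op == ">":
            passed = value > limit
            margin = value - limit
        else:
            raise ConfigurationError(f"unknown criterion operator {op!r}")
        rows.append({**crit, "value_cgy": value, "passed": passed, "evaluable": True,
                     "margin_cgy": margin})
        overall = overall and passed
    return {"criteria": rows, "overall_pass": overall}
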