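"""The full second-check verification workflow and its report.

``run_verification`` chains the stages a physicist expects from an
independent dose check of a tandem-and-ring plan: source-orientation
reconstruction, grid dose computation, reference-point doses (with percent
differences against TPS values when supplied), DVH parameters for the
target with and without the applicator volume, plan-criteria evaluation,
EQD2 conversion, and — when a TPS dose volume is supplied — a gamma
comparison in the ring's axis plane.  The report body is deterministic for
fixed inputs; stage progress and timings go to the logger, never into the
body.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import __version__
from .applicator_geometry import RingFit, assign_directions
from .dose_engine import (
    DoseVolume,
    DwellPoint,
    GridSpec,
    ReferencePoint,
    compute_dose_volume,
    construct_points_AB,
    dose_at_points,
    percent_difference,
)
from .errors import ConfigurationError, ValidationError
from .gamma_eval import GammaCriteria, extract_plane, gamma_map
from .io_formats import PlanDocument, load_source
from .radiobiology import DEFAULT_ALPHA_BETA, eqd2_total
from .structures_dvh import (
    DEFAULT_CRITERIA,
    DVHResult,
    StructureSet,
    check_plan_criteria,
    cumulative_dvh,
    exclude_applicator,
    rasterize,
)

log = logging.getLogger("brachyqa")


@dataclass
class VerificationConfig:
    """Explicit physical choices of a verification run.

    Nothing here is silently defaulted away: the chosen values are echoed in
    the report.  ``grid_mm`` is the in-plane dose-grid size (0.5 / 1.0 / 2.5
    mm are the standard options, any positive value is accepted);
    ``slice_mm`` defaults to the structure set's slice spacing.
    """

    source_model: str | None = None      # None -> the plan's source id
    grid_mm: float = 1.0
    slice_mm: float | None = None
    margin_mm: float = 5.0
    alpha_beta: dict = field(default_factory=lambda: dict(DEFAULT_ALPHA_BETA))
    criteria: tuple = DEFAULT_CRITERIA
    gamma_dose_tolerance_pct: float = 3.0
    gamma_dta_mm: float = 3.0
    gamma_low_dose_threshold_pct: float = 0.0
    auto_points_AB: bool = True
    points: list = field(default_factory=list)          # ReferencePoint list
    tps_point_doses_cgy: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.grid_mm > 0:
            raise ConfigurationError("grid size must be > 0 mm")

    @classmethod
    def from_yaml(cls, path) -> "VerificationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        points = [ReferencePoint(p["name"], p["position_mm"]) for p in doc.pop("points", [])]
        cfg = cls(**{k: v for k, v in doc.items() if k != "points"})
        cfg.points = points
        return cfg

    def digest(self) -> str:
        doc = {k: v for k, v in asdict(self).items() if k != "points"}
        doc["points"] = [{"name": p.name, "position_mm": list(map(float, p.position_mm))}
                         for p in self.points]
        return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class VerificationReport:
    """Everything a second check reports, plus provenance."""

    provenance: dict
    ring_fits: dict[str, RingFit]
    direction_methods: dict[str, str]
    point_doses: list[dict]
    dvh_results: list[DVHResult]
    criteria: dict
    eqd2_tables: list[dict]
    gamma_summary: dict | None
    dose: DoseVolume

    def to_text(self) -> str:
        lines = ["# brachyqa verification report", ""]
        lines.append("## provenance")
        for k in sorted(self.provenance):
            lines.append(f"{k}: {self.provenance[k]}")
        lines.append("")
        if self.ring_fits:
            lines.append("## ring fits")
            for ch, fit in sorted(self.ring_fits.items()):
                lines.append(
                    f"{ch}: normal=({fit.plane_normal[0]:.6f},{fit.plane_normal[1]:.6f},"
                    f"{fit.plane_normal[2]:.6f}) center_mm=({fit.center_mm[0]:.4f},"
                    f"{fit.center_mm[1]:.4f},{fit.center_mm[2]:.4f}) "
                    f"radius_mm={fit.radius_mm:.4f} rmse_mm={fit.rmse_mm:.6f}"
                )
            lines.append("")
        lines.append("## direction methods")
        for ch in sorted(self.direction_methods):
            lines.append(f"{ch}: {self.direction_methods[ch]}")
        lines.append("")
        if self.point_doses:
            lines.append("## reference point doses (cGy per fraction)")
            for row in self.point_doses:
                txt = f"{row['name']}: {row['dose_cgy']:.4f}"
                if row.get("tps_cgy") is not None:
                    txt += f"  tps={row['tps_cgy']:.4f}  pct_diff={row['pct_diff']:+.2f}%"
                lines.append(txt)
            lines.append("")
        lines.append("## DVH parameters (cGy per fraction)")
        for res in self.dvh_results:
            tag = " (applicator excluded)" if res.applicator_excluded else ""
            metr = "  ".join(f"{k}={v:.2f}" for k, v in res.metrics.items())
            lines.append(f"{res.name}{tag}: volume_cc={res.volume_cc:.3f}  {metr}")
        lines.append("")
        lines.append("## plan criteria")
        for row in self.criteria["criteria"]:
            if not row["evaluable"]:
                lines.append(f"{row['roi']} {row['metric']}: UNEVALUABLE")
            else:
                verdict = "pass" if row["passed"] else "FAIL"
                lines.append(
                    f"{row['roi']} {row['metric']}={row['value_cgy']:.2f} cGy "
                    f"{row['op']} {row['limit_cgy']:.0f}: {verdict} "
                    f"(margin {row['margin_cgy']:+.2f} cGy)"
                )
        lines.append(f"overall: {'pass' if self.criteria['overall_pass'] else 'FAIL'}")
        lines.append("")
        if self.eqd2_tables:
            lines.append("## EQD2 (Gy)")
            for row in self.eqd2_tables:
                per = "  ".join(f"f{i + 1}={v:.4f}" for i, v in enumerate(row["per_fraction_gy"]))
                lines.append(
                    f"{row['structure']} {row['metric']} (a/b={row['alpha_beta']:g}): "
                    f"{per}  total={row['total_gy']:.4f}"
                )
            lines.append("")
        if self.gamma_summary is not None:
            g = self.gamma_summary
            lines.append("## gamma comparison (ring axis plane)")
            lines.append(
                f"criteria: {g['dose_tolerance_pct']:g}%/{g['dta_mm']:g} mm, "
                f"normalization={g['normalization']}, threshold={g['threshold_pct']:g}%"
            )
            lines.append(f"n_evaluated: {g['n_evaluated']}")
            lines.append(f"pass_rate_pct: {g['pass_rate_pct']:.2f}")
            lines.append(f"gamma_mean: {g['gamma_mean']:.4f}  gamma_max: {g['gamma_max']:.4f}")
            lines.append("")
        return "\n".join(lines)


def plan_dwells(plan: PlanDocument) -> tuple[list[DwellPoint], dict, dict]:
    """Assign source orientations to every channel of a plan.

    Returns ``(dwells, ring_fits_by_channel, method_by_channel)``.
    """
    dwells: list[DwellPoint] = []
    fits: dict[str, RingFit] = {}
    methods: dict[str, str] = {}
    for ch in plan.channels:
        directions, method, fit = assign_directions(ch.positions_mm, ch.applicator_type)
        methods[ch.channel_id] = method
        if fit is not None:
            fits[ch.channel_id] = fit
        for pos, direction, t in zip(ch.positions_mm, directions, ch.times_s):
            dwells.append(DwellPoint(
                position_mm=pos, direction=direction, time_s=float(t),
                air_kerma_strength_U=plan.air_kerma_strength_U, channel_id=ch.channel_id,
            ))
    return dwells, fits, methods


def default_grid(structures: StructureSet, grid_mm: float, slice_mm: float | None,
                 margin_mm: float = 5.0) -> GridSpec:
    """A grid covering the structure set with the requested resolutions."""
    lo, hi = structures.bounding_box()
    zs = structures.slice_zs()
    if slice_mm is None:
        slice_mm = float(np.median(np.diff(zs))) if len(zs) > 1 else grid_mm
    nx = int(np.ceil((hi[0] - lo[0] + 2 * margin_mm) / grid_mm)) + 1
    ny = int(np.ceil((hi[1] - lo[1] + 2 * margin_mm) / grid_mm)) + 1
    origin = (lo[0] - margin_mm, lo[1] - margin_mm, float(zs[0]) if len(zs) else lo[2])
    nz = len(zs) if len(zs) else int(np.ceil((hi[2] - lo[2]) / slice_mm)) + 1
    return GridSpec(origin_mm=origin, spacing_mm=(grid_mm, grid_mm, slice_mm),
                    dims=(nx, ny, nz))


def run_verification(plan: PlanDocument, structures: StructureSet,
                     config: VerificationConfig | None = None,
                     tps_dose: DoseVolume | None = None) -> VerificationReport:
    """Execute the full verification workflow on one plan."""
    config = config or VerificationConfig()
    t0 = time.perf_counter()
    source = load_source(config.source_model or plan.source_model)

    dwells, fits, methods = plan_dwells(plan)
    log.info("directions assigned for %d channels (%.2f s)", len(plan.channels),
             time.perf_counter() - t0)

    grid = default_grid(structures, config.grid_mm, config.slice_mm, config.margin_mm)
    if tps_dose is not None:
        # a shared frame of reference is required before any computation
        t_lo = np.array(tps_dose.grid.origin_mm)
        g_lo, g_hi = structures.bounding_box()
        t_hi = t_lo + np.array(tps_dose.grid.spacing_mm) * (np.array(tps_dose.grid.dims) - 1)
        if np.any(t_hi < g_lo) or np.any(t_lo > g_hi):
            raise ValidationError(
                "TPS dose volume and structure set do not share a frame of reference"
            )
    t1 = time.perf_counter()
    dose = compute_dose_volume(dwells, source, grid,
                               metadata={"direction_methods": methods,
                                         "grid_mm": config.grid_mm})
    log.info("dose volume %s computed (%.2f s)", grid.dims, time.perf_counter() - t1)

    # reference points
    points: list[ReferencePoint] = list(config.points)
    ring_fit = next(iter(fits.values()), None)
    if config.auto_points_AB and ring_fit is not None:
        ring_channel = next(ch for ch in plan.channels if ch.channel_id in fits)
        lateral = ring_channel.positions_mm[0] - ring_fit.center_mm
        lateral = lateral - (lateral @ ring_fit.plane_normal) * ring_fit.plane_normal
        tandem_ch = next((ch for ch in plan.channels if ch.applicator_type == "tandem"), None)
        if tandem_ch is not None and len(tandem_ch.positions_mm) > 1:
            axis = tandem_ch.positions_mm[-1] - tandem_ch.positions_mm[0]
        else:
            axis = ring_fit.plane_normal
        if np.linalg.norm(lateral) > 1e-9:
            points = construct_points_AB(ring_fit, axis, lateral) + points
    point_rows = []
    if points:
        for name, dose_cgy in dose_at_points(dwells, source, points):
            row = {"name": name, "dose_cgy": dose_cgy, "tps_cgy": None, "pct_diff": None}
            tps_val = config.tps_point_doses_cgy.get(name)
            if tps_val is not None:
                row["tps_cgy"] = float(tps_val)
                row["pct_diff"] = percent_difference(dose_cgy, float(tps_val))
            point_rows.append(row)

    # DVH: every ROI; the target also with the applicator excluded
    dvh_results: list[DVHResult] = []
    applicator = structures.by_role("applicator")
    app_mask = rasterize(applicator, grid) if applicator is not None else None
    metrics_by_roi: dict[str, dict[str, float]] = {}
    for roi in structures.rois.values():
        if roi.role == "applicator":
            continue
        mask = rasterize(roi, grid)
        res = cumulative_dvh(dose, mask, roi.name)
        dvh_results.append(res)
        metrics_by_roi[roi.role if roi.role != "other" else roi.name] = res.metrics
        if roi.role == "hrctv" and app_mask is not None:
            res_wo = cumulative_dvh(dose, exclude_applicator(mask, app_mask),
                                    roi.name, applicator_excluded=True)
            dvh_results.append(res_wo)
            metrics_by_roi["hrctv"] = res_wo.metrics  # criteria use the W/O variant
    log.info("DVH computed for %d structures (%.2f s)", len(dvh_results),
             time.perf_counter() - t1)

    criteria = check_plan_criteria(metrics_by_roi, config.criteria)

    # EQD2 per structure metric, per fraction and total
    n_frac = plan.n_fractions or 1
    eqd2_rows = []
    eqd2_specs = [("hrctv", "D90%"), ("bladder", "D0.1cc"), ("bladder", "D2cc"),
                  ("rectum", "D0.1cc"), ("rectum", "D2cc"),
                  ("sigmoid", "D0.1cc"), ("sigmoid", "D2cc")]
    for role, metric in eqd2_specs:
        value = metrics_by_roi.get(role, {}).get(metric)
        if value is None:
            continue
        ab = config.alpha_beta.get(role, 3.0)
        per_dose_gy = value / 100.0
        total, breakdown = eqd2_total([per_dose_gy] * n_frac, ab)
        eqd2_rows.append({"structure": role, "metric": metric, "alpha_beta": ab,
                          "per_fraction_gy": breakdown, "total_gy": total})

    # gamma against the TPS dose in the ring axis plane
    gamma_summary = None
    if tps_dose is not None and ring_fit is not None:
        crit = GammaCriteria(dose_tolerance_pct=config.gamma_dose_tolerance_pct,
                             dta_mm=config.gamma_dta_mm,
                             low_dose_threshold_pct=config.gamma_low_dose_threshold_pct)
        ref_plane = extract_plane(tps_dose, ring_fit)
        ev_plane = extract_plane(dose, ring_fit)
        finite = np.isfinite(ref_plane.values)
        ref_plane.values = np.where(finite, ref_plane.values, np.nan)
        result = gamma_map(ref_plane, ev_plane, crit)
        g = result.gamma[np.isfinite(result.gamma)]
        gamma_summary = {
            "dose_tolerance_pct": crit.dose_tolerance_pct, "dta_mm": crit.dta_mm,
            "normalization": "global-max", "threshold_pct": crit.low_dose_threshold_pct,
            "n_evaluated": result.n_evaluated, "pass_rate_pct": result.pass_rate,
            "gamma_mean": float(g.mean()), "gamma_max": float(g.max()),
        }

    provenance = {
        "tool": f"brachyqa {__version__}",
        "source_model": source.name,
        "grid_mm": config.grid_mm,
        "slice_mm": grid.spacing_mm[2],
        "alpha_beta": dict(sorted(config.alpha_beta.items())),
        "gamma_criteria": f"{config.gamma_dose_tolerance_pct:g}%/{config.gamma_dta_mm:g}mm",
        "direction_methods": dict(sorted(methods.items())),
        "config_sha256": config.digest(),
        "n_fractions": n_frac,
    }
    log.info("verification complete (%.2f s total)", time.perf_counter() - t0)
    return VerificationReport(
        provenance=provenance, ring_fits=fits, direction_methods=methods,
        point_doses=point_rows, dvh_results=dvh_results, criteria=criteria,
        eqd2_tables=eqd2_rows, gamma_summary=gamma_summary, dose=dose,
    )
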