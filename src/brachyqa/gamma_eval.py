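"""Gamma-index comparison of dose distributions and plane extraction.

For each reference point r the gamma index is

    gamma(r) = min_e sqrt( |x_e - x_r|^2 / dta^2
                           + (D_eval(e) - D_ref(r))^2 / (tol * D_norm)^2 )

over evaluated points e.  gamma <= 1 (boundary inclusive) counts as a pass.
The search starts within a radius of 3 * dta and grows adaptively until the
distance penalty alone excludes any better candidate, so the coarse result
equals a full-grid exhaustive search.  One optional level of 10x sub-grid
refinement (linear dose interpolation around the best coarse point) bounds
the discretization error of gamma from above.

Doses are normalized to the global maximum of the reference distribution by
default, matching comparisons of planar dose maps normalized to their
maximum dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.ndimage import map_coordinates

from .applicator_geometry import RingFit
from .dose_engine import DoseVolume
from .errors import ConfigurationError, EmptyEvaluationError, GeometryError, ValidationError

#: initial search radius in units of dta
SEARCH_RADIUS_DTA = 3.0
#: sub-grid refinement factor
REFINE_FACTOR = 10
#: relative guard so the exact boundary gamma == 1 passes in floating point
PASS_EPS = 1e-9


@dataclass
class DosePlane:
    """A 2D dose map on a regular grid (row/col axes, mm), with optional
    3D basis metadata describing where the plane sits in patient space."""

    values: np.ndarray
    origin: np.ndarray   # (2,) mm, centre of pixel [0, 0]
    spacing: np.ndarray  # (2,) mm
    basis: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        if self.values.ndim != 2:
            raise ConfigurationError("DosePlane values must be 2D")
        if np.any(self.spacing <= 0):
            raise ConfigurationError("DosePlane spacing must be > 0")


@dataclass(frozen=True)
class GammaCriteria:
    """Dose tolerance (% of the normalization dose), DTA (mm), normalization
    ('global-max' or an explicit dose), and a low-dose threshold (% of the
    normalization dose; 0 evaluates every point)."""

    dose_tolerance_pct: float = 3.0
    dta_mm: float = 3.0
    normalization: object = "global-max"
    low_dose_threshold_pct: float = 0.0

    def __post_init__(self) -> None:
        if not self.dose_tolerance_pct > 0:
            raise ValidationError("dose tolerance must be > 0 %")
        if not self.dta_mm > 0:
            raise ValidationError("DTA must be > 0 mm")
        if not 0 <= self.low_dose_threshold_pct < 100:
            raise ValidationError("low-dose threshold must be in [0, 100) %")
        if self.normalization != "global-max":
            if not (np.isscalar(self.normalization) and float(self.normalization) > 0):
                raise ValidationError("normalization must be 'global-max' or a positive dose")


@dataclass
class GammaResult:
    """Gamma map (NaN at unevaluated points), pass rate (%) and count."""

    gamma: np.ndarray
    pass_rate: float
    n_evaluated: int
    criteria: GammaCriteria


def _grid_fields(dist) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(values, origin, spacing) for DosePlane or DoseVolume inputs."""
    if isinstance(dist, (DosePlane, DoseVolume)):
        return dist.values, np.asarray(dist.origin, float), np.asarray(dist.spacing, float)
    raise ConfigurationError(f"cannot interpret {type(dist).__name__} as a dose distribution")


def gamma_map(reference, evaluated, criteria: GammaCriteria = GammaCriteria(),
              refine: bool = True) -> GammaResult:
    """Gamma index of ``evaluated`` against ``reference`` (planes or volumes)."""
    ref_vals, ref_org, ref_sp = _grid_fields(reference)
    ev_vals, ev_org, ev_sp = _grid_fields(evaluated)
    if ref_vals.ndim != ev_vals.ndim:
        raise ConfigurationError("reference and evaluated must have the same dimensionality")
    ndim = ref_vals.ndim
    dta = criteria.dta_mm
    # disjoint-grid guard: bounding boxes must come within the search radius
    ref_hi = ref_org + ref_sp * (np.array(ref_vals.shape) - 1)
    ev_hi = ev_org + ev_sp * (np.array(ev_vals.shape) - 1)
    if np.any(ev_org - ref_hi > SEARCH_RADIUS_DTA * dta) or \
       np.any(ref_org - ev_hi > SEARCH_RADIUS_DTA * dta):
        raise GeometryError("reference and evaluated grids are disjoint")

    if criteria.normalization == "global-max":
        d_norm = float(np.nanmax(ref_vals))
    else:
        d_norm = float(criteria.normalization)
    if not d_norm > 0:
        raise ValidationError("normalization dose must be > 0")
    tol = criteria.dose_tolerance_pct / 100.0 * d_norm

    eval_axes = [ev_org[a] + ev_sp[a] * np.arange(ev_vals.shape[a]) for a in range(ndim)]
    finite_ref = np.isfinite(ref_vals)
    evaluate = finite_ref & (ref_vals >= criteria.low_dose_threshold_pct / 100.0 * d_norm)
    if not np.any(evaluate):
        raise EmptyEvaluationError("no reference points above the low-dose threshold")

    gamma = np.full(ref_vals.shape, np.nan)
    max_extent = float(np.max(ev_hi - ev_org)) + float(np.max(ev_sp)) if ev_vals.size else 0.0

    for idx in zip(*np.nonzero(evaluate)):
        coord = ref_org + ref_sp * np.array(idx)
        d_ref = ref_vals[idx]
        radius = SEARCH_RADIUS_DTA * dta
        while True:
            slices, offsets2 = [], []
            empty = False
            for a in range(ndim):
                lo = int(np.ceil((coord[a] - radius - ev_org[a]) / ev_sp[a]))
                hi = int(np.floor((coord[a] + radius - ev_org[a]) / ev_sp[a]))
                lo = max(lo, 0)
                hi = min(hi, ev_vals.shape[a] - 1)
                if hi < lo:
                    empty = True
                    break
                slices.append(slice(lo, hi + 1))
                offsets2.append((eval_axes[a][lo:hi + 1] - coord[a]) ** 2)
            if empty:
                radius *= 2.0
                if radius > 2 * (max_extent + np.linalg.norm(ref_hi - ref_org) + dta):
                    raise GeometryError("gamma search found no evaluated points in range")
                continue
            dist2 = offsets2[0]
            for o2 in offsets2[1:]:
                dist2 = dist2[..., None] + o2
            window = ev_vals[tuple(slices)]
            g2 = dist2 / dta ** 2 + (window - d_ref) ** 2 / tol ** 2
            if not np.any(np.isfinite(g2)):
                radius *= 2.0
                if radius > 2 * (max_extent + np.linalg.norm(ref_hi - ref_org) + dta):
                    raise GeometryError("gamma search found no evaluated points in range")
                continue
            best_flat = int(np.nanargmin(g2))
            best = float(np.sqrt(g2.flat[best_flat]))
            # candidates outside the window have distance penalty > radius/dta;
            # if the best found is worse than that, a better one may lie outside
            if best <= radius / dta or radius >= max_extent:
                break
            radius = (best + 1e-9) * dta

        if refine and best > 0:  # an exact agreement cannot be improved upon
            local = np.unravel_index(best_flat, window.shape)
            center_idx = np.array([slices[a].start + local[a] for a in range(ndim)], float)
            step = 1.0 / REFINE_FACTOR
            axes_frac = [
                np.clip(center_idx[a] + np.arange(-REFINE_FACTOR, REFINE_FACTOR + 1) * step,
                        0, ev_vals.shape[a] - 1)
                for a in range(ndim)
            ]
            mesh = np.meshgrid(*axes_frac, indexing="ij")
            coords = np.stack([m.ravel() for m in mesh])
            doses = map_coordinates(ev_vals, coords, order=1, mode="nearest")
            pos = np.stack([ev_org[a] + ev_sp[a] * coords[a] for a in range(ndim)])
            dist2f = ((pos - coord[:, None]) ** 2).sum(axis=0)
            g2f = dist2f / dta ** 2 + (doses - d_ref) ** 2 / tol ** 2
            if np.any(np.isfinite(g2f)):
                best = min(best, float(np.sqrt(np.nanmin(g2f))))
        gamma[idx] = best

    evaluated_g = gamma[evaluate]
    n_eval = int(evaluated_g.size)
    rate = 100.0 * float(np.count_nonzero(evaluated_g <= 1.0 + PASS_EPS)) / n_eval
    return GammaResult(gamma=gamma, pass_rate=rate, n_evaluated=n_eval, criteria=criteria)


def pass_rate(result: GammaResult) -> float:
    """Percentage of evaluated points with gamma <= 1 (boundary passes)."""
    if result.n_evaluated == 0:
        raise EmptyEvaluationError("gamma result contains no evaluated points")
    return result.pass_rate


def extract_plane(volume: DoseVolume, fit: RingFit, spacing_mm: float | None = None
                  ) -> DosePlane:
    """Resample a dose volume onto the ring's axis plane.

    The plane passes through the ring centre and contains the ring normal
    (the applicator axis); its in-plane lateral direction is the projection
    of the volume x axis onto the plane (y axis if degenerate).  Values are
    trilinearly interpolated; samples outside the volume are NaN.
    """
    n = fit.plane_normal
    lat = np.array([1.0, 0.0, 0.0])
    lat = lat - (lat @ n) * n
    if np.linalg.norm(lat) < 1e-9:
        lat = np.array([0.0, 1.0, 0.0])
        lat = lat - (lat @ n) * n
    lat /= np.linalg.norm(lat)

    if spacing_mm is None:
        spacing_mm = float(min(volume.grid.spacing_mm[:2]))
    # extents: project volume corners onto (lat, n) relative to the ring centre
    xs, ys, zs = volume.grid.axis_coords()
    corners = np.array(list(product([xs[0], xs[-1]], [ys[0], ys[-1]], [zs[0], zs[-1]])))
    rel = corners - fit.center_mm
    s_rng = rel @ lat
    t_rng = rel @ n
    s = np.arange(np.floor(s_rng.min() / spacing_mm), np.ceil(s_rng.max() / spacing_mm) + 1
                  ) * spacing_mm
    t = np.arange(np.floor(t_rng.min() / spacing_mm), np.ceil(t_rng.max() / spacing_mm) + 1
                  ) * spacing_mm
    S, T = np.meshgrid(s, t, indexing="xy")  # rows index t (axis), cols index s (lateral)
    pts = (fit.center_mm[None, :]
           + S.ravel()[:, None] * lat[None, :]
           + T.ravel()[:, None] * n[None, :])
    ox, oy, oz = volume.grid.origin_mm
    dx, dy, dz = volume.grid.spacing_mm
    idx = np.stack([
        (pts[:, 2] - oz) / dz,
        (pts[:, 1] - oy) / dy,
        (pts[:, 0] - ox) / dx,
    ])
    vals = map_coordinates(volume.values, idx, order=1, mode="constant", cval=np.nan)
    vals = vals.reshape(S.shape)
    if not np.any(np.isfinite(vals)):
        raise GeometryError("ring axis plane does not intersect the dose volume")
    return DosePlane(
        values=vals,
        origin=np.array([t[0], s[0]]),
        spacing=np.array([spacing_mm, spacing_mm]),
        basis={"center_mm": fit.center_mm.tolist(), "axis": n.tolist(),
               "lateral": lat.tolist()},
    )
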