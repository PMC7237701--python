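"""Dose evaluation on 3D grids and at arbitrary absolute points.

Grid doses are pure point samples of the TG-43 kernel at voxel centres (no
supersampling), so refining the grid never changes the value at a shared
voxel centre.  Voxels closer to a dwell centre than half the active length
are capped at the transverse-axis dose at that radius, which keeps the
singular near-source region (inside the applicator lumen) finite.

Reference-point doses (points A/B, rectal point) are exact kernel
evaluations at absolute coordinates — no grid interpolation — matching how
a second-check system verifies a clinical plan against the TPS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .applicator_geometry import RingFit
from .errors import ConfigurationError, GeometryError, ValidationError
from .source_model import (
    MM_PER_CM,
    DwellPoint,
    SourceModel,
    anisotropy,
    geometry_factor_line,
    radial_dose,
)

#: dwell contributions inside this fraction of the active length are capped
CAPSULE_RADIUS_FACTOR = 0.5


@dataclass(frozen=True)
class GridSpec:
    """A regular calculation grid.

    ``origin_mm`` is the centre of the first voxel (ix=iy=iz=0);
    ``spacing_mm`` = (dx, dy, dz); ``dims`` = (nx, ny, nz).  Dose arrays are
    indexed ``values[iz, iy, ix]``.
    """

    origin_mm: tuple[float, float, float]
    spacing_mm: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))
        object.__setattr__(self, "spacing_mm", tuple(float(v) for v in self.spacing_mm))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError(f"grid spacings must be > 0, got {self.spacing_mm}")
        if any(d < 1 for d in self.dims):
            raise ConfigurationError(f"grid dimensions must be >= 1, got {self.dims}")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape (nz, ny, nx)."""
        nx, ny, nz = self.dims
        return (nz, ny, nx)

    @property
    def voxel_volume_cc(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz / 1000.0

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates along (x, y, z) in mm."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.dims[a])
            for a in range(3)
        )

    def voxel_centers(self) -> np.ndarray:
        """All voxel centres as an (nz, ny, nx, 3) array in mm."""
        xs, ys, zs = self.axis_coords()
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)


@dataclass
class DoseVolume:
    """Scalar absorbed dose per fraction (cGy) on a grid, plus provenance."""

    grid: GridSpec
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ConfigurationError(
                f"dose array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("dose values must be finite and >= 0")

    # convenience aliases used by the gamma module
    @property
    def origin(self) -> np.ndarray:
        ox, oy, oz = self.grid.origin_mm
        return np.array([oz, oy, ox])  # array-axis order (z, y, x)

    @property
    def spacing(self) -> np.ndarray:
        dx, dy, dz = self.grid.spacing_mm
        return np.array([dz, dy, dx])


@dataclass(frozen=True)
class ReferencePoint:
    """A named absolute dose point (mm, patient coordinates)."""

    name: str
    position_mm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position_mm", np.asarray(self.position_mm, float))
        if self.position_mm.shape != (3,) or not np.all(np.isfinite(self.position_mm)):
            raise ValidationError(f"reference point {self.name!r} position must be a finite 3-vector")


def _capsule_radius_mm(source: SourceModel) -> float:
    return CAPSULE_RADIUS_FACTOR * source.active_length_cm * MM_PER_CM


def _dwell_dose(source: SourceModel, dwell: DwellPoint, points_mm: np.ndarray,
                cap: bool) -> tuple[np.ndarray, int]:
    """Dose (cGy) from one dwell at an array of points, optionally capping
    points inside the capsule radius at the transverse-axis surface dose."""
    d = points_mm - dwell.position_mm
    dist_mm = np.linalg.norm(d, axis=-1)
    zero = dist_mm == 0
    if np.any(zero) and not cap:
        raise GeometryError(
            f"point of interest coincides with dwell {dwell.channel_id!r} "
            f"at {dwell.position_mm.tolist()} mm"
        )
    safe = np.where(zero, 1.0, dist_mm)
    cos_t = np.clip(np.einsum("...i,i->...", d, dwell.direction) / safe, -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_t))
    r_cm = dist_mm / MM_PER_CM
    cap_r_cm = CAPSULE_RADIUS_FACTOR * source.active_length_cm
    inside = r_cm < cap_r_cm
    n_inside = int(np.count_nonzero(inside))
    if n_inside and not cap:
        raise GeometryError(
            f"{n_inside} point(s) inside the source capsule of dwell {dwell.channel_id!r}"
        )
    r_eval = np.where(inside, cap_r_cm, r_cm)
    theta_eval = np.where(inside, 90.0, theta)
    g_ref = geometry_factor_line(source.reference_distance_cm, source.reference_angle_deg,
                                 source.active_length_cm)
    G = geometry_factor_line(np.atleast_1d(r_eval), np.atleast_1d(theta_eval),
                             source.active_length_cm).reshape(r_eval.shape)
    rate = (dwell.air_kerma_strength_U * source.dose_rate_constant * (G / g_ref)
            * radial_dose(source, r_eval) * anisotropy(source, r_eval, theta_eval))
    return rate * (dwell.time_s / 3600.0), n_inside


def compute_dose_volume(dwells: Sequence[DwellPoint], source: SourceModel,
                        grid: GridSpec, metadata: dict | None = None) -> DoseVolume:
    """Superpose all dwell contributions at every voxel centre of ``grid``."""
    if not dwells:
        raise ValidationError("plan has no dwells")
    if not any(d.time_s > 0 for d in dwells):
        raise ValidationError("plan has no dwell with time > 0")
    points = grid.voxel_centers()
    flat = points.reshape(-1, 3)
    total = np.zeros(len(flat))
    n_capped = 0
    for dw in dwells:
        contrib, n_in = _dwell_dose(source, dw, flat, cap=True)
        total += contrib
        n_capped += n_in
    meta = dict(metadata or {})
    meta.setdefault("source_model", source.name)
    meta["n_capped_voxel_contributions"] = n_capped
    meta["capsule_radius_mm"] = _capsule_radius_mm(source)
    return DoseVolume(grid=grid, values=total.reshape(grid.shape), metadata=meta)


def dose_at_points(dwells: Sequence[DwellPoint], source: SourceModel,
                   points: Sequence[ReferencePoint]) -> list[tuple[str, float]]:
    """Exact kernel dose (cGy) at named absolute points, in input order.

    Points inside any dwell's source capsule raise :class:`GeometryError`.
    """
    results: list[tuple[str, float]] = []
    for pt in points:
        dose = 0.0
        for dw in dwells:
            contrib, _ = _dwell_dose(source, dw, pt.position_mm[None, :], cap=False)
            dose += float(contrib[0])
        results.append((pt.name, dose))
    return results


def construct_points_AB(fit: RingFit, tandem_axis, lateral_axis=None) -> list[ReferencePoint]:
    """Geometric points A and B relative to a fitted ring.

    Points A sit 20 mm superior (along the tandem axis) to the ring centre and
    +/- 20 mm along the lateral in-plane axis; points B use a 50 mm lateral
    offset.  When ``lateral_axis`` is omitted it is derived as
    ``normal x tandem``; that fails for the common geometry where the tandem
    runs along the ring normal, in which case an explicit lateral axis is
    required (the verification workflow uses the direction towards the first
    ring dwell).
    """
    t = np.asarray(tandem_axis, float)
    tn = np.linalg.norm(t)
    if tn == 0:
        raise GeometryError("tandem axis must be non-zero")
    t = t / tn
    if abs(float(t @ fit.plane_normal)) < 1e-9:
        raise GeometryError("tandem axis lies in the ring plane; points A/B undefined")
    if lateral_axis is None:
        lat = np.cross(fit.plane_normal, t)
        if np.linalg.norm(lat) < 1e-9:
            raise GeometryError(
                "lateral axis undefined (tandem parallel to ring normal); "
                "supply lateral_axis explicitly"
            )
        lat /= np.linalg.norm(lat)
    else:
        lat = np.asarray(lateral_axis, float)
        lat = lat / np.linalg.norm(lat)
    c = fit.center_mm
    sup = 20.0 * t
    return [
        ReferencePoint("A_right", c + sup + 20.0 * lat),
        ReferencePoint("A_left", c + sup - 20.0 * lat),
        ReferencePoint("B_right", c + sup + 50.0 * lat),
        ReferencePoint("B_left", c + sup - 50.0 * lat),
    ]


def percent_difference(test: float, reference: float) -> float:
    """100 * (test - reference) / reference; the comparison (TPS) value is
    the denominator, so test < reference yields a negative difference."""
    if reference == 0:
        raise ValidationError("percent difference undefined for zero reference dose")
    return 100.0 * (test - reference) / reference
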