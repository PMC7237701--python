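"""TG-43U1 line-source kernel and physical source description.

The absorbed-dose rate in water around a sealed HDR source is modelled with
the AAPM TG-43U1 line-source formalism::

    Ddot(r, theta) = S_K * Lambda * [G_L(r, theta) / G_L(r0, theta0)]
                     * g_L(r) * F(r, theta)

where ``r`` (cm) is the distance from the centre of the active source to the
point of interest and ``theta`` (degrees) the polar angle between the source
long axis and the line joining source centre and point.  ``S_K`` is the air
kerma strength (U, 1 U = 1 cGy cm^2 h^-1), ``Lambda`` the dose-rate constant
(cGy h^-1 U^-1), ``G_L`` the line-source geometry factor, ``g_L`` the radial
dose function and ``F`` the 2D anisotropy function.  The reference geometry
is ``r0 = 1 cm``, ``theta0 = 90 deg``.

Geometry is carried in millimetres (the DICOM convention) and converted to
centimetres only inside the kernel; dose rates are cGy/h, accumulated doses
cGy, dwell times seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from scipy.interpolate import RegularGridInterpolator

from .errors import EmptyInputWarning, ExtrapolationWarning, GeometryError, ValidationError

MM_PER_CM = 10.0
REFERENCE_DISTANCE_CM = 1.0
REFERENCE_ANGLE_DEG = 90.0

#: sin(theta) below which the on-axis geometry-factor branch is used
ON_AXIS_SIN_THRESHOLD = 1e-6


@dataclass(frozen=True)
class PolarCoordinates:
    """Source-centred polar coordinates: distance r (cm), polar angle theta (deg)."""

    r_cm: float
    theta_deg: float

    def __post_init__(self) -> None:
        if not self.r_cm > 0:
            raise ValidationError(f"polar distance must be > 0, got r={self.r_cm}")
        if not 0.0 <= self.theta_deg <= 180.0:
            raise ValidationError(f"polar angle must be in [0, 180] deg, got {self.theta_deg}")


@dataclass(frozen=True)
class DwellPoint:
    """A single HDR dwell: position (mm), source long-axis direction, time (s).

    ``air_kerma_strength_U`` is the plan's S_K in U (1 U = 1 cGy cm^2 h^-1).
    """

    position_mm: np.ndarray
    direction: np.ndarray
    time_s: float
    air_kerma_strength_U: float
    channel_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "position_mm", np.asarray(self.position_mm, dtype=float))
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))
        if self.position_mm.shape != (3,) or self.direction.shape != (3,):
            raise ValidationError("dwell position and direction must be 3-vectors")
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValidationError(
                f"dwell direction must be a unit vector (|d|={np.linalg.norm(self.direction)!r})"
            )
        if self.time_s < 0:
            raise ValidationError(f"dwell time must be >= 0 s, got {self.time_s}")
        if not self.air_kerma_strength_U > 0:
            raise ValidationError("air kerma strength S_K must be > 0 U")


@dataclass(frozen=True)
class SourceModel:
    """Physical description of a stepping source plus its TG-43 tables.

    ``radial_r_cm``/``radial_g`` tabulate the radial dose function g_L(r) on a
    strictly increasing grid; ``aniso_F`` tabulates F(r, theta) on the outer
    product of ``aniso_r_cm`` and ``aniso_theta_deg`` (rows index r, columns
    theta).  Both tables are normalized at the TG-43 reference geometry:
    g_L(1 cm) = 1 and F(r, 90 deg) = 1 within table round-off.
    """

    name: str
    active_length_cm: float
    dose_rate_constant: float  # cGy / (h U)
    radial_r_cm: np.ndarray
    radial_g: np.ndarray
    aniso_r_cm: np.ndarray
    aniso_theta_deg: np.ndarray
    aniso_F: np.ndarray
    reference_distance_cm: float = REFERENCE_DISTANCE_CM
    reference_angle_deg: float = REFERENCE_ANGLE_DEG

    def __post_init__(self) -> None:
        for attr in ("radial_r_cm", "radial_g", "aniso_r_cm", "aniso_theta_deg", "aniso_F"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if not self.active_length_cm > 0:
            raise ValidationError("active length must be > 0 cm")
        if not self.dose_rate_constant > 0:
            raise ValidationError("dose-rate constant must be > 0")
        if np.any(np.diff(self.radial_r_cm) <= 0):
            raise ValidationError(f"radial grid of {self.name!r} must be strictly increasing")
        if np.any(np.diff(self.aniso_r_cm) <= 0) or np.any(np.diff(self.aniso_theta_deg) <= 0):
            raise ValidationError(f"anisotropy grids of {self.name!r} must be strictly increasing")
        if self.aniso_F.shape != (self.aniso_r_cm.size, self.aniso_theta_deg.size):
            raise ValidationError("anisotropy table shape does not match its r/theta grids")
        if not (self.aniso_theta_deg[0] <= self.reference_angle_deg <= self.aniso_theta_deg[-1]):
            raise ValidationError("anisotropy grid must cover the 90 deg reference angle")
        if np.any(self.radial_g <= 0) or np.any(self.aniso_F <= 0):
            raise ValidationError("all g_L and F table values must be > 0")
        g_ref = float(np.interp(self.reference_distance_cm, self.radial_r_cm, self.radial_g))
        if abs(g_ref - 1.0) > 5e-3:
            raise ValidationError(f"g_L(r0) = {g_ref} departs from 1 beyond table round-off")

    # -- interpolators ------------------------------------------------------

    @cached_property
    def _aniso_interp(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.aniso_r_cm, self.aniso_theta_deg), self.aniso_F, method="linear"
        )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict) -> "SourceModel":
        try:
            return cls(
                name=str(doc["name"]),
                active_length_cm=float(doc["active_length_cm"]),
                dose_rate_constant=float(doc["dose_rate_constant"]),
                radial_r_cm=doc["radial_dose"]["r_cm"],
                radial_g=doc["radial_dose"]["g"],
                aniso_r_cm=doc["anisotropy"]["r_cm"],
                aniso_theta_deg=doc["anisotropy"]["theta_deg"],
                aniso_F=doc["anisotropy"]["F"],
            )
        except KeyError as exc:  # pragma: no cover - message path
            raise ValidationError(f"source table missing field {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "SourceModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def packaged(cls, name: str) -> "SourceModel":
        """Load a source table shipped with the package (``toy``, ``ir192-generic``)."""
        fname = {"toy": "toy_source.yaml", "ir192-generic": "ir192_generic.yaml"}.get(name)
        if fname is None:
            raise ValidationError(f"no packaged source model named {name!r}")
        ref = resources.files("brachyqa.data").joinpath(fname)
        return cls.from_dict(yaml.safe_load(ref.read_text()))

    @classmethod
    def toy(cls, active_length_cm: float = 0.36, dose_rate_constant: float = 1.109,
            name: str = "toy") -> "SourceModel":
        """Analytic toy source with g_L == 1 and F == 1 everywhere (unit tables)."""
        r = [0.05, 50.0]
        theta = [0.0, 180.0]
        return cls(
            name=name,
            active_length_cm=active_length_cm,
            dose_rate_constant=dose_rate_constant,
            radial_r_cm=r,
            radial_g=[1.0, 1.0],
            aniso_r_cm=r,
            aniso_theta_deg=theta,
            aniso_F=np.ones((2, 2)),
        )


# ---------------------------------------------------------------------------
# kernel operations
# ---------------------------------------------------------------------------

def polar_arrays(position_mm: np.ndarray, direction: np.ndarray,
                 points_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized source-centred polar coordinates for an array of points.

    Returns ``(r_cm, theta_deg)`` with shapes matching ``points_mm[..., 0]``.
    Raises :class:`GeometryError` for any point coincident with the dwell.
    """
    position_mm = np.asarray(position_mm, dtype=float)
    points_mm = np.asarray(points_mm, dtype=float)
    d = points_mm - position_mm
    dist_mm = np.linalg.norm(d, axis=-1)
    if np.any(dist_mm == 0):
        raise GeometryError(
            f"point of interest coincides with dwell at {position_mm.tolist()} mm"
        )
    cos_t = np.clip(np.einsum("...i,i->...", d, np.asarray(direction, float)) / dist_mm, -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_t))
    return dist_mm / MM_PER_CM, theta


def to_polar(dwell: DwellPoint, point_mm) -> PolarCoordinates:
    """Polar coordinates of a single point of interest relative to a dwell."""
    try:
        r, theta = polar_arrays(dwell.position_mm, dwell.direction, np.asarray(point_mm, float))
    except GeometryError as exc:
        raise GeometryError(
            f"degenerate geometry for dwell {dwell.channel_id!r}: {exc}"
        ) from exc
    return PolarCoordinates(float(r), float(np.clip(theta, 0.0, 180.0)))


def geometry_factor_line(r_cm, theta_deg, active_length_cm: float):
    """Line-source geometry factor G_L(r, theta) in cm^-2.

    Off axis ``G_L = beta / (L r sin(theta))`` with ``beta`` the angle (rad)
    subtended by the active line at the point; for ``sin(theta)`` below
    ``ON_AXIS_SIN_THRESHOLD`` the on-axis closed form
    ``G_L = 1 / (r^2 - L^2/4)`` is used.  Accepts scalars or arrays.
    """
    if isinstance(r_cm, PolarCoordinates):
        r_cm, theta_deg = r_cm.r_cm, r_cm.theta_deg
    r = np.asarray(r_cm, dtype=float)
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    L = float(active_length_cm)
    if np.any(r <= 0):
        raise GeometryError("geometry factor requires r > 0")
    scalar = r.ndim == 0 and theta.ndim == 0
    r, theta = np.broadcast_arrays(np.atleast_1d(r), np.atleast_1d(theta))

    sin_t = np.sin(theta)
    on_axis = sin_t < ON_AXIS_SIN_THRESHOLD
    if np.any(on_axis & (r <= L / 2)):
        raise GeometryError(
            f"on-axis point with r <= L/2 = {L / 2} cm lies inside the active source"
        )

    # beta from the two vectors joining the point to the active-line ends
    x = r * sin_t            # perpendicular distance to the source axis
    z = r * np.cos(theta)    # along-axis coordinate
    u1x, u1z = -x, L / 2 - z
    u2x, u2z = -x, -L / 2 - z
    cross = u1z * u2x - u1x * u2z
    dot = u1x * u2x + u1z * u2z
    beta = np.arctan2(np.abs(cross), dot)

    with np.errstate(divide="ignore", invalid="ignore"):
        g_off = beta / (L * r * sin_t)
        g_on = 1.0 / (r ** 2 - L ** 2 / 4.0)
    out = np.where(on_axis, g_on, g_off)
    if not np.all(np.isfinite(out) & (out > 0)):
        raise GeometryError("geometry factor evaluated to a non-finite value")
    return float(out[0]) if scalar else out.reshape(np.shape(r))


def radial_dose(source: SourceModel, r_cm):
    """Radial dose function g_L(r), linear interpolation, clamped at table edges."""
    r = np.asarray(r_cm, dtype=float)
    lo, hi = source.radial_r_cm[0], source.radial_r_cm[-1]
    if np.any(r < lo) or np.any(r > hi):
        warnings.warn(
            f"g_L lookup outside [{lo}, {hi}] cm for source {source.name!r}; clamped",
            ExtrapolationWarning, stacklevel=2,
        )
    out = np.interp(np.clip(r, lo, hi), source.radial_r_cm, source.radial_g)
    return float(out) if np.ndim(r_cm) == 0 else out


def anisotropy(source: SourceModel, r_cm, theta_deg=None):
    """Anisotropy function F(r, theta), bilinear interpolation, clamped at edges."""
    if isinstance(r_cm, PolarCoordinates):
        r_cm, theta_deg = r_cm.r_cm, r_cm.theta_deg
    r = np.asarray(r_cm, dtype=float)
    t = np.asarray(theta_deg, dtype=float)
    if np.any(t < 0) or np.any(t > 180):
        raise ValidationError("anisotropy angle must be within [0, 180] deg")
    r_lo, r_hi = source.aniso_r_cm[0], source.aniso_r_cm[-1]
    t_lo, t_hi = source.aniso_theta_deg[0], source.aniso_theta_deg[-1]
    if np.any(r < r_lo) or np.any(r > r_hi) or np.any(t < t_lo) or np.any(t > t_hi):
        warnings.warn(
            f"F lookup outside table range for source {source.name!r}; clamped",
            ExtrapolationWarning, stacklevel=2,
        )
    rc = np.clip(r, r_lo, r_hi)
    tc = np.clip(t, t_lo, t_hi)
    rc, tc = np.broadcast_arrays(np.atleast_1d(rc), np.atleast_1d(tc))
    out = source._aniso_interp(np.stack([rc.ravel(), tc.ravel()], axis=-1)).reshape(rc.shape)
    if np.ndim(r_cm) == 0 and np.ndim(theta_deg) == 0:
        return float(out[0])
    return out.reshape(np.broadcast_shapes(np.shape(r_cm), np.shape(theta_deg)))


def dose_rate(source: SourceModel, dwell: DwellPoint, points_mm):
    """TG-43U1 line-source dose rate (cGy/h) at one point or an array of points."""
    points = np.asarray(points_mm, dtype=float)
    scalar = points.ndim == 1
    try:
        r, theta = polar_arrays(dwell.position_mm, dwell.direction, points)
    except GeometryError as exc:
        raise GeometryError(f"dwell {dwell.channel_id!r}: {exc}") from exc
    g_ref = geometry_factor_line(
        source.reference_distance_cm, source.reference_angle_deg, source.active_length_cm
    )
    try:
        G = geometry_factor_line(r, theta, source.active_length_cm)
    except GeometryError as exc:
        raise GeometryError(f"dwell {dwell.channel_id!r}: {exc}") from exc
    rate = (
        dwell.air_kerma_strength_U
        * source.dose_rate_constant
        * (G / g_ref)
        * radial_dose(source, r)
        * anisotropy(source, r, theta)
    )
    return float(rate) if scalar else rate


def accumulate_dose(source: SourceModel, dwells: Sequence[DwellPoint], points_mm):
    """Total dose (cGy) at the given point(s): sum of dose_rate * time/3600 over dwells."""
    points = np.asarray(points_mm, dtype=float)
    scalar = points.ndim == 1
    if len(dwells) == 0:
        warnings.warn("accumulate_dose called with no dwells; returning 0 cGy",
                      EmptyInputWarning, stacklevel=2)
        return 0.0 if scalar else np.zeros(points.shape[:-1])
    total = np.zeros(points.shape[:-1])
    for dw in dwells:
        total = total + np.asarray(dose_rate(source, dw, points)) * (dw.time_s / 3600.0)
    return float(total) if scalar else total
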