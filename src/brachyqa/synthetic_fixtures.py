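"""Deterministic synthetic plans, phantoms and comparison doses.

The generator emulates a tandem-and-ring intracavitary cervix application in
a water-equivalent phantom: one ring channel with dwells equally spaced on a
circle, one tandem channel with collinear dwells along the applicator axis,
an ellipsoidal HR-CTV enclosing the ring, offset ellipsoidal organs at risk
(bladder / rectum / sigmoid), and an applicator ROI built from the tandem
cylinder plus the ring torus.  Everything is a deterministic function of the
fixture seed, so stochastic tests are reproducible bit for bit.

Default study conditions: 15 mm ring radius with 8 dwells over the full
circle, 40 mm tandem with 8 dwells, 18 s dwell times, S_K = 40700 U (a
nominal 10 Ci source), 2.5 mm contour slice spacing, and a 5 x 5.5 Gy
fraction scheme — a realistic tandem-and-ring loading at typical clinical
magnitudes whose DVH parameters sit near the usual plan criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .dose_engine import DoseVolume
from .errors import ConfigurationError, ValidationError
from .io_formats import PlanChannel, PlanDocument
from .structures_dvh import ROI, StructureSet


@dataclass
class FixtureSpec:
    """Parameters of the synthetic tandem-and-ring study."""

    seed: int = 1
    # ring channel
    ring_radius_mm: float = 15.0
    ring_n_dwells: int = 8
    ring_center_mm: tuple = (0.0, 0.0, 0.0)
    ring_normal: tuple = (0.0, 0.0, 1.0)
    ring_dwell_time_s: float = 18.0
    # tandem channel
    tandem_length_mm: float = 40.0
    tandem_n_dwells: int = 8
    tandem_axis: tuple = (0.0, 0.0, 1.0)
    tandem_offset_mm: float = 5.0
    tandem_dwell_time_s: float = 18.0
    # perturbations / phantom
    noise_sigma_mm: float = 0.0
    slice_spacing_mm: float = 2.5
    contour_step_deg: float = 1.0
    # physics
    source_model: str = "toy"
    air_kerma_strength_U: float = 40700.0
    n_fractions: int = 5
    dose_per_fraction_gy: float = 5.5

    def __post_init__(self) -> None:
        if not self.ring_radius_mm > 0:
            raise ValidationError("ring radius must be > 0 mm")
        if self.ring_n_dwells < 3:
            raise ValidationError("a ring channel needs >= 3 dwells")
        if self.noise_sigma_mm < 0:
            raise ValidationError("noise sigma must be >= 0 mm")


def _ring_basis(normal) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(n)))] = 1.0
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return n, u, v


def make_ring_plan(spec: FixtureSpec) -> tuple[PlanDocument, dict[str, np.ndarray]]:
    """Synthetic tandem-and-ring plan plus ground-truth source directions.

    Ring dwells are equally spaced counter-clockwise on the specified circle
    (optionally jittered with seeded Gaussian noise); ground-truth tangents
    are those of the noiseless circle.  Tandem dwells step along the axis
    starting ``tandem_offset_mm`` beyond the ring centre.
    """
    rng = np.random.default_rng(spec.seed)
    n, u, v = _ring_basis(spec.ring_normal)
    c = np.asarray(spec.ring_center_mm, float)

    phi = 2.0 * np.pi * np.arange(spec.ring_n_dwells) / spec.ring_n_dwells
    ring_pos = (c[None, :]
                + spec.ring_radius_mm * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v))
    ring_truth = -np.sin(phi)[:, None] * u + np.cos(phi)[:, None] * v
    if spec.noise_sigma_mm > 0:
        ring_pos = ring_pos + rng.normal(0.0, spec.noise_sigma_mm, ring_pos.shape)

    axis = np.asarray(spec.tandem_axis, float)
    axis = axis / np.linalg.norm(axis)
    if spec.tandem_n_dwells > 1:
        steps = np.linspace(0.0, spec.tandem_length_mm, spec.tandem_n_dwells)
    else:
        steps = np.array([0.0])
    tandem_pos = c[None, :] + (spec.tandem_offset_mm + steps)[:, None] * axis[None, :]
    tandem_truth = np.tile(axis, (spec.tandem_n_dwells, 1))

    plan = PlanDocument(
        channels=[
            PlanChannel(channel_id="ring", applicator_type="ring",
                        positions_mm=ring_pos,
                        times_s=np.full(spec.ring_n_dwells, spec.ring_dwell_time_s)),
            PlanChannel(channel_id="tandem", applicator_type="tandem",
                        positions_mm=tandem_pos,
                        times_s=np.full(spec.tandem_n_dwells, spec.tandem_dwell_time_s)),
        ],
        air_kerma_strength_U=spec.air_kerma_strength_U,
        source_model=spec.source_model,
        n_fractions=spec.n_fractions,
        dose_per_fraction_gy=spec.dose_per_fraction_gy,
        metadata={"fixture_seed": spec.seed, "noise_sigma_mm": spec.noise_sigma_mm},
    )
    return plan, {"ring": ring_truth, "tandem": tandem_truth}


def _ellipse_polygon(center_xy, ax_a, ax_b, step_deg) -> np.ndarray:
    ang = np.radians(np.arange(0.0, 360.0, step_deg))
    return np.column_stack([
        center_xy[0] + ax_a * np.cos(ang),
        center_xy[1] + ax_b * np.sin(ang),
    ])


def _ellipsoid_roi(name, role, center, semi, zs, step_deg) -> ROI:
    slices: dict[float, list[np.ndarray]] = {}
    for z in zs:
        dz = (z - center[2]) / semi[2]
        if abs(dz) >= 1.0:
            continue
        scale = np.sqrt(1.0 - dz ** 2)
        slices[float(z)] = [
            _ellipse_polygon(center[:2], semi[0] * scale, semi[1] * scale, step_deg)
        ]
    return ROI(name=name, role=role, slices=slices)


#: phantom geometry (mm): ROI -> (centre, semi-axes), relative to the ring centre
PHANTOM_ELLIPSOIDS = {
    "HR-CTV": ((0.0, 0.0, 10.0), (22.0, 22.0, 28.0), "hrctv"),
    "Bladder": ((0.0, 36.0, 15.0), (18.0, 15.0, 20.0), "bladder"),
    "Rectum": ((0.0, -33.0, 5.0), (12.0, 12.0, 25.0), "rectum"),
    "Sigmoid": ((0.0, -25.0, 50.0), (15.0, 15.0, 18.0), "sigmoid"),
}

APPLICATOR_TUBE_RADIUS_MM = 3.0


def make_phantom(spec: FixtureSpec) -> StructureSet:
    """Ellipsoidal HR-CTV and OARs plus a cylinder+torus applicator ROI.

    Contours are sampled at ``contour_step_deg`` vertex spacing on slices
    every ``slice_spacing_mm``; the geometry assumes the default z-normal
    ring (contour slices are transverse planes).
    """
    c = np.asarray(spec.ring_center_mm, float)
    dz = spec.slice_spacing_mm
    z_lo = c[2] - 35.0
    z_hi = c[2] + 70.0
    zs = np.arange(z_lo, z_hi + dz / 2, dz)

    ss = StructureSet()
    for name, (rel_center, semi, role) in PHANTOM_ELLIPSOIDS.items():
        center = c + np.asarray(rel_center)
        ss.add(_ellipsoid_roi(name, role, center, np.asarray(semi, float), zs,
                              spec.contour_step_deg))

    # applicator: tandem cylinder along +z from the ring plane, ring torus at z = c_z
    rho = APPLICATOR_TUBE_RADIUS_MM
    app_slices: dict[float, list[np.ndarray]] = {}
    tandem_top = c[2] + spec.tandem_offset_mm + spec.tandem_length_mm + rho
    for z in zs:
        polys: list[np.ndarray] = []
        if c[2] - rho <= z <= tandem_top:
            polys.append(_ellipse_polygon(c[:2], rho, rho, spec.contour_step_deg))
        dzr = z - c[2]
        if abs(dzr) < rho:
            half = np.sqrt(rho ** 2 - dzr ** 2)
            outer = spec.ring_radius_mm + half
            inner = spec.ring_radius_mm - half
            polys.append(_ellipse_polygon(c[:2], outer, outer, spec.contour_step_deg))
            if inner > rho:  # annulus hole (even-odd rule removes it)
                polys.append(_ellipse_polygon(c[:2], inner, inner, spec.contour_step_deg))
        if polys:
            app_slices[float(z)] = polys
    ss.add(ROI(name="Applicator", role="applicator", slices=app_slices))
    return ss


def make_comparison_dose(dose: DoseVolume, mode: str, *, factor: float = 1.0,
                         shift_mm=(0.0, 0.0, 0.0), sigma_pct: float = 1.0,
                         seed: int = 0) -> DoseVolume:
    """A perturbed copy of ``dose`` for gamma testing.

    Modes: ``identical``; ``scaled`` (multiply by ``factor``); ``shifted``
    (translate the distribution by ``shift_mm``, edge-clamped linear
    resampling); ``noisy`` (multiplicative Gaussian noise of ``sigma_pct`` %,
    seeded).  The perturbation is recorded in the metadata.
    """
    meta = dict(dose.metadata)
    meta["perturbation"] = {"mode": mode}
    if mode == "identical":
        values = dose.values.copy()
    elif mode == "scaled":
        values = dose.values * factor
        meta["perturbation"]["factor"] = factor
    elif mode == "shifted":
        shift = np.asarray(shift_mm, float)
        dx, dy, dz = dose.grid.spacing_mm
        # a feature at x appears at x + shift: sample the original at x - shift
        off = np.array([shift[2] / dz, shift[1] / dy, shift[0] / dx])
        idx = np.indices(dose.values.shape).astype(float)
        coords = idx - off[:, None, None, None]
        values = map_coordinates(dose.values, coords.reshape(3, -1), order=1,
                                 mode="nearest").reshape(dose.values.shape)
        meta["perturbation"]["shift_mm"] = list(map(float, shift))
    elif mode == "noisy":
        rng = np.random.default_rng(seed)
        values = dose.values * np.clip(1.0 + rng.normal(0.0, sigma_pct / 100.0,
                                                        dose.values.shape), 0.0, None)
        meta["perturbation"].update({"sigma_pct": sigma_pct, "seed": seed})
    else:
        raise ConfigurationError(f"unknown comparison-dose mode {mode!r}")
    return DoseVolume(grid=dose.grid, values=values, metadata=meta)
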