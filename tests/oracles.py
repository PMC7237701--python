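"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by a route deliberately different from the
implementation: numerical line integration for the geometry factor, scalar
interpolation loops for the tabulated kernel, cumulative-volume
interpolation for DVH metrics, and full exhaustive search for gamma.
"""

from __future__ import annotations

from bisect import bisect_right

import numpy as np


def line_integral_geometry_factor(r_cm, theta_deg, length_cm, n_segments=100_000):
    """(1/L) * integral dl / d^2 over the active line, by midpoint summation.

    Discretizes the active length into ``n_segments`` point sources and sums
    inverse-square contributions; equals the line-source geometry factor.
    """
    L = length_cm
    zl = (np.arange(n_segments) + 0.5) / n_segments * L - L / 2  # segment midpoints
    theta = np.radians(np.asarray(theta_deg, float))
    r = np.asarray(r_cm, float)
    x = r * np.sin(theta)
    z0 = r * np.cos(theta)
    d2 = x[..., None] ** 2 + (z0[..., None] - zl) ** 2
    return np.mean(1.0 / d2, axis=-1)


def _interp1(x, xs, ys):
    """Scalar linear interpolation with edge clamping (bisect based)."""
    if x <= xs[0]:
        return ys[0]
    if x >= xs[-1]:
        return ys[-1]
    i = bisect_right(list(xs), x)
    x0, x1 = xs[i - 1], xs[i]
    w = (x - x0) / (x1 - x0)
    return (1 - w) * ys[i - 1] + w * ys[i]


def kernel_dose_rate_oracle(source, s_k, position_mm, direction, point_mm,
                            n_segments=100_000):
    """Brute-force TG-43 dose rate: line-integral geometry factor plus scalar
    bilinear table lookups, written independently of the implementation."""
    d = np.asarray(point_mm, float) - np.asarray(position_mm, float)
    dist_cm = float(np.linalg.norm(d)) / 10.0
    cos_t = float(np.dot(d, direction)) / (dist_cm * 10.0)
    theta = float(np.degrees(np.arccos(np.clip(cos_t, -1, 1))))
    L = source.active_length_cm
    G = float(line_integral_geometry_factor(np.array(dist_cm), np.array(theta), L, n_segments))
    G_ref = float(line_integral_geometry_factor(np.array(1.0), np.array(90.0), L, n_segments))
    g = _interp1(dist_cm, source.radial_r_cm, source.radial_g)
    # bilinear F: interpolate along theta at the two bracketing r rows
    rs = list(source.aniso_r_cm)
    r_clamped = min(max(dist_cm, rs[0]), rs[-1])
    if r_clamped <= rs[0]:
        i0 = i1 = 0
        w = 0.0
    elif r_clamped >= rs[-1]:
        i0 = i1 = len(rs) - 1
        w = 0.0
    else:
        i1 = bisect_right(rs, r_clamped)
        i0 = i1 - 1
        w = (r_clamped - rs[i0]) / (rs[i1] - rs[i0])
    f0 = _interp1(theta, source.aniso_theta_deg, source.aniso_F[i0])
    f1 = _interp1(theta, source.aniso_theta_deg, source.aniso_F[i1])
    F = (1 - w) * f0 + w * f1
    return s_k * source.dose_rate_constant * (G / G_ref) * g * F


def dvh_metric_oracle(doses_cgy, voxel_cc, spec):
    """Sort-based DVH metric via interpolation on cumulative voxel counts."""
    doses = np.sort(np.asarray(doses_cgy, float))[::-1]
    n = len(doses)
    if spec.endswith("%"):
        m = float(spec[1:-1]) / 100.0 * n
    else:
        m = float(spec[1:-2]) / voxel_cc
    m = min(max(m, 1.0), float(n))
    return float(np.interp(m, np.arange(1, n + 1), doses))


def gamma_oracle(ref_vals, ref_origin, ref_spacing, ev_vals, ev_origin, ev_spacing,
                 tol_pct, dta_mm, d_norm=None):
    """Exhaustive gamma: every reference point against every evaluated point."""
    ref_vals = np.asarray(ref_vals, float)
    ev_vals = np.asarray(ev_vals, float)
    if d_norm is None:
        d_norm = np.nanmax(ref_vals)
    tol = tol_pct / 100.0 * d_norm
    nd = ref_vals.ndim
    ref_axes = [ref_origin[a] + ref_spacing[a] * np.arange(ref_vals.shape[a]) for a in range(nd)]
    ev_axes = [ev_origin[a] + ev_spacing[a] * np.arange(ev_vals.shape[a]) for a in range(nd)]
    ref_mesh = np.meshgrid(*ref_axes, indexing="ij")
    ev_mesh = np.meshgrid(*ev_axes, indexing="ij")
    ref_pts = np.stack([m.ravel() for m in ref_mesh], axis=1)
    ev_pts = np.stack([m.ravel() for m in ev_mesh], axis=1)
    dist2 = ((ref_pts[:, None, :] - ev_pts[None, :, :]) ** 2).sum(axis=2)
    dd2 = (ev_vals.ravel()[None, :] - ref_vals.ravel()[:, None]) ** 2
    g2 = dist2 / dta_mm ** 2 + dd2 / tol ** 2
    return np.sqrt(np.nanmin(g2, axis=1)).reshape(ref_vals.shape)
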