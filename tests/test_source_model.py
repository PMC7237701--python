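"""TG-43 kernel: polar geometry, geometry factor, table lookups, dose rate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brachyqa.errors import EmptyInputWarning, ExtrapolationWarning, GeometryError, ValidationError
from brachyqa.source_model import (
    DwellPoint,
    SourceModel,
    accumulate_dose,
    anisotropy,
    dose_rate,
    geometry_factor_line,
    radial_dose,
    to_polar,
)
from oracles import line_integral_geometry_factor


class TestToPolar:
    @pytest.mark.parametrize("point, r_exp, theta_exp", [
        ([10, 0, 0], 1.0, 90.0),          # orthogonal axis
        ([0, 0, 10], 1.0, 0.0),           # on axis
        ([10, 0, 10], np.sqrt(2), 45.0),  # hand trigonometry
    ])
    def test_examples(self, reference_dwell, point, r_exp, theta_exp):
        coords = to_polar(reference_dwell, point)
        assert coords.r_cm == pytest.approx(r_exp, rel=1e-12)
        assert coords.theta_deg == pytest.approx(theta_exp, abs=1e-9)

    def test_zero_distance_names_dwell(self, reference_dwell):
        with pytest.raises(GeometryError, match="dwell"):
            to_polar(reference_dwell, [0, 0, 0])


class TestGeometryFactor:
    def test_transverse_closed_form(self):
        expected = 2 * np.arctan(0.18) / 0.36
        assert geometry_factor_line(1.0, 90.0, 0.36) == pytest.approx(expected, rel=1e-12)

    def test_on_axis_closed_form(self):
        assert geometry_factor_line(1.0, 0.0, 0.36) == pytest.approx(1 / (1 - 0.0324), rel=1e-12)

    def test_point_source_limit_single(self):
        assert geometry_factor_line(2.0, 37.0, 1e-6) == pytest.approx(0.25, rel=1e-6)

    def test_point_source_limit_uniform(self):
        """G_L -> 1/r^2 within 0.5% for r >= 10 L over theta in [5, 175] deg."""
        L = 0.36
        r = np.linspace(10 * L, 12.0, 40)
        theta = np.linspace(5.0, 175.0, 35)
        R, T = np.meshgrid(r, theta)
        G = geometry_factor_line(R.ravel(), T.ravel(), L).reshape(R.shape)
        assert np.all(np.abs(G * R ** 2 - 1.0) < 0.005)

    def test_matches_line_integral_oracle(self):
        """Agreement with the brute-force line integral to 1e-4 relative."""
        L = 0.36
        rng = np.random.default_rng(42)
        r = rng.uniform(L, 6.0, 60)
        theta = rng.uniform(0.0, 180.0, 60)
        G = geometry_factor_line(r, theta, L)
        G_oracle = line_integral_geometry_factor(r, theta, L)
        assert np.all(np.abs(G / G_oracle - 1.0) <= 1e-4)

    def test_on_axis_inside_source_error(self):
        with pytest.raises(GeometryError, match="inside"):
            geometry_factor_line(0.1, 0.0, 0.36)

    def test_near_axis_branch_continuity(self):
        """The on-axis branch engages smoothly below the angular threshold."""
        g_branch = geometry_factor_line(1.0, 1e-8, 0.36)
        g_near = geometry_factor_line(1.0, 0.01, 0.36)
        assert g_branch == pytest.approx(g_near, rel=1e-4)


class TestTables:
    def test_radial_reference_and_knots(self, ir_source):
        assert radial_dose(ir_source, 1.0) == pytest.approx(1.0, abs=5e-3)
        for r, g in zip(ir_source.radial_r_cm, ir_source.radial_g):
            assert radial_dose(ir_source, float(r)) == pytest.approx(float(g), rel=1e-12)

    def test_radial_midpoint_linear(self):
        src = SourceModel(
            name="twoknot", active_length_cm=0.36, dose_rate_constant=1.0,
            radial_r_cm=[0.5, 2.0], radial_g=[1.004, 0.996],
            aniso_r_cm=[0.5, 2.0], aniso_theta_deg=[0.0, 180.0], aniso_F=np.ones((2, 2)),
        )
        assert radial_dose(src, 1.25) == pytest.approx((1.004 + 0.996) / 2, rel=1e-12)

    def test_radial_clamp_warns(self, ir_source):
        with pytest.warns(ExtrapolationWarning):
            val = radial_dose(ir_source, 99.0)
        assert val == pytest.approx(float(ir_source.radial_g[-1]))

    def test_anisotropy_transverse_normalization(self, ir_source):
        for r in (0.3, 1.0, 4.2):
            assert anisotropy(ir_source, r, 90.0) == pytest.approx(1.0, abs=5e-4)

    def test_anisotropy_knot_identity(self, ir_source):
        i, j = 2, 5
        assert anisotropy(ir_source, float(ir_source.aniso_r_cm[i]),
                          float(ir_source.aniso_theta_deg[j])) == pytest.approx(
            float(ir_source.aniso_F[i, j]), rel=1e-12)

    def test_anisotropy_cell_center_bilinear(self):
        a, b, c, d = 0.7, 0.8, 0.9, 1.0
        src = SourceModel(
            name="cell", active_length_cm=0.36, dose_rate_constant=1.0,
            radial_r_cm=[0.5, 2.0], radial_g=[1.0, 1.0],
            aniso_r_cm=[1.0, 3.0], aniso_theta_deg=[80.0, 90.0],
            aniso_F=[[a, b], [c, d]],
        )
        assert anisotropy(src, 2.0, 85.0) == pytest.approx((a + b + c + d) / 4, rel=1e-12)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValidationError):
            SourceModel(name="bad", active_length_cm=0.36, dose_rate_constant=1.0,
                        radial_r_cm=[2.0, 0.5], radial_g=[1.0, 1.0],
                        aniso_r_cm=[0.5, 2.0], aniso_theta_deg=[0.0, 180.0],
                        aniso_F=np.ones((2, 2)))
        with pytest.raises(ValidationError):
            SourceModel(name="bad", active_length_cm=0.36, dose_rate_constant=1.0,
                        radial_r_cm=[0.5, 2.0], radial_g=[1.0, -1.0],
                        aniso_r_cm=[0.5, 2.0], aniso_theta_deg=[0.0, 180.0],
                        aniso_F=np.ones((2, 2)))


class TestDoseRate:
    def test_reference_identity(self, toy_source, reference_dwell):
        """Toy source at (r0, theta0): the G ratio, g and F are all 1."""
        rate = dose_rate(toy_source, reference_dwell, [10, 0, 0])
        expected = reference_dwell.air_kerma_strength_U * toy_source.dose_rate_constant
        assert rate == pytest.approx(expected, rel=1e-12)

    def test_inverse_square_limit(self, reference_dwell):
        src = SourceModel.toy(active_length_cm=1e-4, dose_rate_constant=1.1)
        rate = dose_rate(src, reference_dwell, [20, 0, 0])
        assert rate == pytest.approx(1.1 / 4, rel=1e-3)

    def test_matches_brute_force_oracle(self, ir_source):
        from oracles import kernel_dose_rate_oracle
        rng = np.random.default_rng(3)
        dwell = DwellPoint(position_mm=[5.0, -3.0, 12.0],
                           direction=np.array([1.0, 1.0, 1.0]) / np.sqrt(3),
                           time_s=10.0, air_kerma_strength_U=40700.0)
        for _ in range(10):
            point = dwell.position_mm + rng.uniform(-40, 40, 3)
            if np.linalg.norm(point - dwell.position_mm) < 5.0:
                continue
            got = dose_rate(ir_source, dwell, point)
            want = kernel_dose_rate_oracle(ir_source, 40700.0, dwell.position_mm,
                                           dwell.direction, point)
            assert got == pytest.approx(want, rel=1e-3)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_rigid_motion_invariance(self, toy_source, seed):
        """Jointly rotating/translating dwell and point leaves the dose rate unchanged."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        t = rng.uniform(-50, 50, 3)
        pos = rng.uniform(-20, 20, 3)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        point = pos + rng.uniform(5, 30) * (lambda v: v / np.linalg.norm(v))(rng.normal(size=3))
        d1 = DwellPoint(position_mm=pos, direction=axis, time_s=1.0, air_kerma_strength_U=2.0)
        d2 = DwellPoint(position_mm=Q @ pos + t, direction=Q @ axis / np.linalg.norm(Q @ axis),
                        time_s=1.0, air_kerma_strength_U=2.0)
        r1 = dose_rate(toy_source, d1, point)
        r2 = dose_rate(toy_source, d2, Q @ point + t)
        assert r2 == pytest.approx(r1, rel=1e-9)


class TestAccumulate:
    def test_unit_hour_identity(self, toy_source, reference_dwell):
        assert accumulate_dose(toy_source, [reference_dwell], [10, 0, 0]) == pytest.approx(
            1.1, rel=1e-12)

    def test_linearity_and_homogeneity(self, toy_source, reference_dwell):
        point = [14.0, 3.0, -6.0]
        one = accumulate_dose(toy_source, [reference_dwell], point)
        two = accumulate_dose(toy_source, [reference_dwell, reference_dwell], point)
        assert two == pytest.approx(2 * one, rel=1e-12)
        doubled = DwellPoint(position_mm=reference_dwell.position_mm,
                             direction=reference_dwell.direction,
                             time_s=2 * reference_dwell.time_s,
                             air_kerma_strength_U=reference_dwell.air_kerma_strength_U)
        assert accumulate_dose(toy_source, [doubled], point) == pytest.approx(2 * one, rel=1e-12)

    def test_partition_additivity(self, toy_source):
        rng = np.random.default_rng(7)
        dwells = [
            DwellPoint(position_mm=rng.uniform(-10, 10, 3), direction=[0, 0, 1],
                       time_s=rng.uniform(1, 30), air_kerma_strength_U=40700.0)
            for _ in range(6)
        ]
        point = [40.0, 40.0, 0.0]
        total = accumulate_dose(toy_source, dwells, point)
        parts = (accumulate_dose(toy_source, dwells[:2], point)
                 + accumulate_dose(toy_source, dwells[2:], point))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_empty_dwell_list_warns_zero(self, toy_source):
        with pytest.warns(EmptyInputWarning):
            assert accumulate_dose(toy_source, [], [10, 0, 0]) == 0.0
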