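"""Rasterization, applicator exclusion, DVH metrics and plan criteria."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon as ShapelyPolygon

from brachyqa.dose_engine import DoseVolume, GridSpec
from brachyqa.errors import (
    ConfigurationError,
    EmptyInputWarning,
    EmptyStructureError,
    InsufficientVolumeError,
)
from brachyqa.structures_dvh import (
    ROI,
    check_plan_criteria,
    cumulative_dvh,
    dvh_metric,
    exclude_applicator,
    rasterize,
)
from oracles import dvh_metric_oracle

SQUARE = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])


def square_roi(z=0.0):
    return ROI(name="square", role="other", slices={z: [SQUARE]})


def uniform_dose(grid, value):
    return DoseVolume(grid=grid, values=np.full(grid.shape, float(value)))


class TestRasterize:
    @pytest.mark.parametrize("spacing, expected", [(1.0, 100), (2.5, 16)])
    def test_square_voxel_counts(self, spacing, expected):
        """A 10x10 mm square catches 100 voxel centres at 1 mm and 16 at
        2.5 mm — the mechanism behind grid-size-dependent structure volumes."""
        n = int(10 / spacing)
        grid = GridSpec(origin_mm=(spacing / 2, spacing / 2, 0.0),
                        spacing_mm=(spacing, spacing, 2.5), dims=(n, n, 1))
        mask = rasterize(square_roi(), grid)
        assert mask.sum() == expected

    @pytest.mark.parametrize("spacing", [1.0, 2.5])
    def test_matches_point_in_polygon_oracle(self, spacing):
        """Every voxel decision agrees with an independent geometric oracle."""
        poly = ShapelyPolygon(SQUARE)
        grid = GridSpec(origin_mm=(-2 + spacing / 2, -2 + spacing / 2, 0.0),
                        spacing_mm=(spacing, spacing, 2.5),
                        dims=(int(14 / spacing), int(14 / spacing), 1))
        mask = rasterize(square_roi(), grid)
        xs, ys, _ = grid.axis_coords()
        for iy, y in enumerate(ys):
            for ix, x in enumerate(xs):
                assert mask[0, iy, ix] == poly.contains(Point(x, y))

    def test_polygon_between_slices_warns_empty(self):
        grid = GridSpec(origin_mm=(0.5, 0.5, 0.0), spacing_mm=(1, 1, 2.5), dims=(10, 10, 2))
        with pytest.warns(EmptyInputWarning):
            mask = rasterize(square_roi(z=3.8), grid)  # > dz/2 from both slices
        assert not mask.any()

    def test_annulus_even_odd(self):
        """Outer + inner circle polygons leave an annular mask (even-odd rule)."""
        ang = np.radians(np.arange(0, 360, 2.0))
        outer = np.column_stack([8 * np.cos(ang), 8 * np.sin(ang)])
        inner = np.column_stack([4 * np.cos(ang), 4 * np.sin(ang)])
        roi = ROI(name="ring", role="applicator", slices={0.0: [outer, inner]})
        grid = GridSpec(origin_mm=(-9.5, -9.5, 0.0), spacing_mm=(1, 1, 1), dims=(20, 20, 1))
        mask = rasterize(roi, grid)
        assert mask[0, 10, 10 + 6]    # 6 mm from centre: inside the annulus
        assert not mask[0, 10, 10]    # centre: in the hole


class TestExcludeApplicator:
    def test_set_arithmetic(self):
        target = np.zeros((1, 10, 10), bool)
        target[0, :10, :10] = True
        app = np.zeros_like(target)
        app[0, :2, :10] = True
        out = exclude_applicator(target, app)
        assert out.sum() == 80
        assert not (out & app).any()

    def test_disjoint_and_superset(self):
        target = np.zeros((1, 4, 4), bool)
        target[0, :2] = True
        assert exclude_applicator(target, np.zeros_like(target)).sum() == target.sum()
        assert exclude_applicator(target, np.ones_like(target)).sum() == 0

    def test_grid_mismatch(self):
        with pytest.raises(ConfigurationError):
            exclude_applicator(np.zeros((1, 4, 4), bool), np.zeros((1, 5, 4), bool))


class TestDvhMetric:
    def test_d100_is_minimum(self):
        assert dvh_metric([3.0, 5.0, 7.0], 1.0, "D100%") == 3.0

    def test_d90_ten_equal_voxels(self):
        assert dvh_metric(np.arange(1.0, 11.0), 1.0, "D90%") == 2.0

    def test_d2cc_27_unit_voxels(self):
        assert dvh_metric(np.arange(1.0, 28.0), 1.0, "D2cc") == 26.0

    def test_d01cc_uniform(self):
        assert dvh_metric(np.full(50, 123.0), 0.1, "D0.1cc") == 123.0

    def test_insufficient_volume(self):
        with pytest.raises(InsufficientVolumeError):
            dvh_metric(np.arange(1.0, 11.0), 0.1, "D2cc")

    def test_matches_sort_oracle_randomized(self):
        """All five standard metrics equal the independent cumulative-volume
        oracle on 50 randomized dose sets."""
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = int(rng.integers(30, 4000))
            vox_cc = float(rng.uniform(0.001, 0.2))
            doses = rng.gamma(2.0, 150.0, n)
            for spec in ("D100%", "D90%", "D10cc", "D2cc", "D0.1cc"):
                if spec.endswith("cc") and float(spec[1:-2]) > n * vox_cc:
                    continue
                got = dvh_metric(doses, vox_cc, spec)
                want = dvh_metric_oracle(doses, vox_cc, spec)
                assert got == pytest.approx(want, rel=1e-9, abs=1e-9)


class TestCumulativeDvh:
    def grid(self, n=3):
        return GridSpec(origin_mm=(0, 0, 0), spacing_mm=(10, 10, 10), dims=(n, n, n))

    def test_uniform_dose_identities(self):
        grid = self.grid()
        dose = uniform_dose(grid, 250.0)
        res = cumulative_dvh(dose, np.ones(grid.shape, bool), "s")
        assert res.metrics["D100%"] == pytest.approx(250.0)
        assert res.metrics["D90%"] == pytest.approx(250.0)
        assert res.volume_cc == pytest.approx(27.0)

    def test_hottest_two_cc(self):
        grid = self.grid()  # 27 voxels of 1 cc
        dose = DoseVolume(grid=grid, values=np.arange(1.0, 28.0).reshape(grid.shape))
        res = cumulative_dvh(dose, np.ones(grid.shape, bool), "s")
        assert res.metrics["D2cc"] == pytest.approx(26.0)

    def test_scale_equivariance(self):
        grid = self.grid()
        values = np.random.default_rng(4).uniform(10, 500, grid.shape)
        mask = np.ones(grid.shape, bool)
        r1 = cumulative_dvh(DoseVolume(grid=grid, values=values), mask, "s")
        r2 = cumulative_dvh(DoseVolume(grid=grid, values=2 * values), mask, "s")
        for k in r1.metrics:
            assert r2.metrics[k] == pytest.approx(2 * r1.metrics[k], rel=1e-12)

    def test_curve_monotone_and_volume_at_zero(self):
        grid = self.grid()
        values = np.random.default_rng(5).uniform(0, 800, grid.shape)
        res = cumulative_dvh(DoseVolume(grid=grid, values=values),
                             np.ones(grid.shape, bool), "s")
        assert np.all(np.diff(res.volumes_cc) <= 0)
        assert res.volumes_cc[0] == pytest.approx(res.volume_cc)
        assert res.metrics["D100%"] <= res.metrics["D90%"]

    def test_applicator_exclusion_properties(self):
        grid = self.grid()
        values = np.random.default_rng(6).uniform(0, 800, grid.shape)
        dose = DoseVolume(grid=grid, values=values)
        target = np.ones(grid.shape, bool)
        app = np.zeros(grid.shape, bool)
        app[0] = True
        excl = exclude_applicator(target, app)
        r_w = cumulative_dvh(dose, target, "s")
        r_wo = cumulative_dvh(dose, excl, "s", applicator_excluded=True)
        assert r_wo.volume_cc <= r_w.volume_cc
        assert r_wo.metrics["D100%"] >= r_w.metrics["D100%"]

    def test_empty_mask_error_names_roi(self):
        grid = self.grid()
        with pytest.raises(EmptyStructureError, match="sigmoid"):
            cumulative_dvh(uniform_dose(grid, 1.0), np.zeros(grid.shape, bool), "sigmoid")


class TestPlanCriteria:
    def test_bladder_margin(self):
        report = check_plan_criteria({"bladder": {"D2cc": 324.0}},
                                     ({"roi": "bladder", "metric": "D2cc", "op": "<",
                                       "limit_cgy": 460.0},))
        row = report["criteria"][0]
        assert row["passed"] and row["margin_cgy"] == pytest.approx(136.0)
        assert report["overall_pass"]

    def test_strict_boundary_fails(self):
        report = check_plan_criteria({"rectum": {"D2cc": 420.0}},
                                     ({"roi": "rectum", "metric": "D2cc", "op": "<",
                                       "limit_cgy": 420.0},))
        assert not report["criteria"][0]["passed"]

    def test_missing_roi_unevaluable(self):
        report = check_plan_criteria({"bladder": {"D2cc": 100.0}})
        sigmoid = [r for r in report["criteria"] if r["roi"] == "sigmoid"][0]
        assert not sigmoid["evaluable"]
        assert not report["overall_pass"]
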