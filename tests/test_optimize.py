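"""Admissible-region construction, window bounds and dose conversion.

Oracles: set identities on random masks, a 0.1-step fine-grid brute force
for window bounds, and closed-form intersection of an ellipse iso-curve
with a plane iso-line for the boundary refinement.
"""

import numpy as np
import pytest

from fertigation.optimize import (GridSpec, admissible_region,
                                  boundary_intersections, irrigation_from_twi)
from fertigation.surface import SurfaceModel, predict
from fertigation.synthetic import surface_from_vertex

CK = (420.0, 4444.6)
GRID = GridSpec((300.0, 500.0), 1.0, (3500.0, 5000.0), 5.0)


def concave_yield():
    # peak inside the grid, CK on the shoulder
    return SurfaceModel("yield", surface_from_vertex(
        70.0, 400.0, 4300.0, -2e-3, 0.0, -1e-4))


def sugar_plane():
    # decreasing in both doses, as quality responds to input reduction
    return SurfaceModel("sugar_content", (30.0, -0.01, 0.0, -2e-3, 0.0, 0.0))


class TestAdmissibleRegion:
    def test_single_criterion_region_contains_ck_cell(self):
        ck = (420.0, 4445.0)  # on-grid control dose
        m = SurfaceModel("yield", surface_from_vertex(
            70.0, ck[0], ck[1], -2e-3, 0.0, -1e-4))
        reg = admissible_region({"yield": m}, ck, GRID)
        assert not reg.empty
        fi = np.argmin(np.abs(reg.F_axis - ck[0]))
        ti = np.argmin(np.abs(reg.TWI_axis - ck[1]))
        assert reg.intersection[fi, ti]
        # region = cells predicting >= the CK value
        FF, TT = np.meshgrid(reg.F_axis, reg.TWI_axis, indexing="ij")
        np.testing.assert_array_equal(
            reg.intersection, predict(m, FF, TT) >= reg.references["yield"])

    def test_intersection_is_logical_and_of_masks(self, rng):
        models = {
            "a": concave_yield(),
            "b": sugar_plane(),
            "c": SurfaceModel("c", surface_from_vertex(
                20.0, 380.0, 4200.0, -1e-3, 2e-5, -5e-5)),
        }
        reg = admissible_region(models, CK, GRID)
        expected = models.keys()
        acc = np.ones_like(reg.intersection)
        for name in expected:
            acc = acc & reg.masks[name]
        np.testing.assert_array_equal(reg.intersection, acc)
        for name in expected:
            assert (reg.intersection <= reg.masks[name]).all()

    def test_disjoint_criteria_give_empty_region_with_diagnostics(self):
        # the CK water dose (4444.6) falls between grid nodes, so the two
        # opposed half-planes in TWI admit disjoint sets of cells
        inc = SurfaceModel("inc", (0.0, 0.0, 0.0, 1.0, 0.0, 0.0))
        dec = SurfaceModel("dec", (0.0, 0.0, 0.0, -1.0, 0.0, 0.0))
        reg = admissible_region({"inc": inc, "dec": dec}, CK, GRID)
        assert reg.empty
        assert reg.diagnostics["eliminated_last_by"] == "dec"
        with pytest.raises(ValueError):
            boundary_intersections(reg)

    def test_ck_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            admissible_region({"y": concave_yield()}, (10.0, 4000.0), GRID)

    def test_constant_surfaces_admit_whole_grid(self):
        flat = SurfaceModel("flat", (5.0, 0, 0, 0, 0, 0))
        reg = admissible_region({"flat": flat}, CK, GRID)
        assert reg.intersection.all()
        w = reg.window()
        assert w == {"F_min": 300.0, "F_max": 500.0,
                     "TWI_min": 3500.0, "TWI_max": 5000.0}
        bounds = boundary_intersections(reg)
        assert all(b.box_limited for b in bounds.values())

    def test_window_matches_fine_grid_brute_force(self):
        models = {"yield": concave_yield(), "sugar_content": sugar_plane()}
        coarse = GridSpec((300.0, 500.0), 2.0, (3500.0, 5000.0), 10.0)
        reg = admissible_region(models, CK, coarse)
        w = reg.window()
        fine = GridSpec((300.0, 500.0), 0.1, (3500.0, 5000.0), 0.5)
        ref = admissible_region(models, CK, fine).window()
        assert abs(w["F_min"] - ref["F_min"]) <= 2.0
        assert abs(w["F_max"] - ref["F_max"]) <= 2.0
        assert abs(w["TWI_min"] - ref["TWI_min"]) <= 10.0
        assert abs(w["TWI_max"] - ref["TWI_max"]) <= 10.0

    def test_refinement_never_widens_window_by_more_than_old_step(self):
        models = {"yield": concave_yield(), "sugar_content": sugar_plane()}
        prev = admissible_region(models, CK,
                                 GridSpec((300, 500), 4.0, (3500, 5000), 20.0))
        finer = admissible_region(models, CK,
                                  GridSpec((300, 500), 1.0, (3500, 5000), 5.0))
        wp, wf = prev.window(), finer.window()
        assert wf["F_min"] >= wp["F_min"] - 4.0
        assert wf["F_max"] <= wp["F_max"] + 4.0
        assert wf["TWI_min"] >= wp["TWI_min"] - 20.0
        assert wf["TWI_max"] <= wp["TWI_max"] + 20.0


class TestBoundaryIntersections:
    def test_refined_crossing_matches_analytic_line_intersection(self):
        # two planar criteria whose iso-lines both pass through CK (their
        # references are the CK predictions) admit a wedge with apex
        # exactly at CK; the F_min extreme is the analytic crossing
        p1 = SurfaceModel("p1", (0.0, 1.0, 0.0, 0.05, 0.0, 0.0))
        p2 = SurfaceModel("p2", (0.0, 1.0, 0.0, -0.05, 0.0, 0.0))
        reg = admissible_region({"p1": p1, "p2": p2}, CK,
                                GridSpec((300, 500), 0.5, (3500, 5000), 2.0))
        bounds = boundary_intersections(reg, tol=0.01)
        b = bounds["F_min"]
        assert set(b.criteria) == {"p1", "p2"}
        assert not b.box_limited
        assert b.intersection_point is not None
        F_r, T_r = b.intersection_point
        assert F_r == pytest.approx(CK[0], abs=1e-2)
        assert T_r == pytest.approx(CK[1], abs=1e-2)
        assert b.value == pytest.approx(F_r)

    def test_twi_min_crossing_of_upward_wedge(self):
        # apex pointing down in TWI: TWI_min is the crossing of the two
        # iso-lines, again exactly at CK
        p1 = SurfaceModel("p1", (0.0, 1.0, 0.0, 0.05, 0.0, 0.0))
        p2 = SurfaceModel("p2", (0.0, -1.0, 0.0, 0.05, 0.0, 0.0))
        reg = admissible_region({"p1": p1, "p2": p2}, CK,
                                GridSpec((300, 500), 0.5, (3500, 5000), 2.0))
        bounds = boundary_intersections(reg, tol=0.01)
        b = bounds["TWI_min"]
        assert set(b.criteria) == {"p1", "p2"}
        assert b.intersection_point is not None
        assert b.intersection_point[0] == pytest.approx(CK[0], abs=1e-2)
        assert b.intersection_point[1] == pytest.approx(CK[1], abs=1e-2)
        assert b.value == pytest.approx(CK[1], abs=1e-2)

    def test_crossing_satisfies_both_iso_equations(self):
        # concave yield ellipse cut by a tilted plane: wherever a refined
        # two-criterion crossing is reported, it must lie on both
        # reference iso-curves to within the bisection tolerance
        yld = concave_yield()
        tilt = SurfaceModel("tilt", (0.0, -1.0, 0.0, 0.09, 0.0, 0.0))
        reg = admissible_region({"yield": yld, "tilt": tilt}, CK,
                                GridSpec((300, 500), 0.5, (3500, 5000), 2.0))
        bounds = boundary_intersections(reg, tol=0.01)
        seen = 0
        for b in bounds.values():
            if b.intersection_point is None:
                continue
            seen += 1
            F_r, T_r = b.intersection_point
            for name in b.criteria:
                resid = abs(float(predict(reg.models[name], F_r, T_r))
                            - reg.references[name])
                assert resid < 0.05
        assert seen >= 1

    def test_axis_aligned_constraints_flagged_box_limited(self):
        inc_f = SurfaceModel("inc_f", (0.0, 1.0, 0, 0, 0, 0))
        reg = admissible_region({"inc_f": inc_f}, CK, GRID)
        bounds = boundary_intersections(reg)
        # admissible half-plane F >= F_ck: every TWI bound and F_max are
        # grid-box edges
        assert bounds["TWI_min"].box_limited
        assert bounds["TWI_max"].box_limited
        assert bounds["F_max"].box_limited
        assert not bounds["F_min"].box_limited
        assert bounds["F_min"].criteria == ("inc_f",)
        assert bounds["F_min"].grid_value == pytest.approx(420.0, abs=1.0)


class TestIrrigationConversion:
    @pytest.mark.parametrize("twi, expected", [
        (4136.46, 1041.86), (4380.82, 1286.22)])
    def test_reported_window_endpoints_convert(self, twi, expected):
        assert irrigation_from_twi(twi, 309.46) == pytest.approx(expected,
                                                                 abs=1e-9)

    def test_twi_equal_precip_gives_zero(self):
        assert irrigation_from_twi(3094.6, 309.46) == pytest.approx(0.0)

    def test_negative_result_logged(self, caplog):
        with caplog.at_level("WARNING"):
            out = irrigation_from_twi(1000.0, 309.46)
        assert out < 0
        assert "negative" in caplog.text
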