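import numpy as np
import pytest

from hydrogait import reference
from hydrogait.cot_surface import (
    ReferenceCOTCurve,
    SurfaceModel,
    fit_surface,
    iso_cost_speed,
    per_depth_curve,
    self_selected_summary,
    surface_extrema,
)

PUBLISHED = SurfaceModel(
    coefficients=reference.SURFACE_COEFFICIENTS,
    speed_domain=reference.SPEED_BOUNDS,
    depth_domain=reference.DEPTH_BOUNDS,
)


def _grid_points(coefs=reference.SURFACE_COEFFICIENTS):
    model = SurfaceModel(coefficients=coefs)
    speeds, depths, cots = [], [], []
    for d in reference.STUDY_DEPTHS.values():
        for s in reference.NOMINAL_SPEEDS:
            speeds.append(s)
            depths.append(d)
            cots.append(float(model.evaluate(s, d)))
    return np.array(speeds), np.array(depths), np.array(cots)


class TestFitSurface:
    def test_noise_free_fit_recovers_coefficients_exactly(self):
        s, d, y = _grid_points()
        model = fit_surface(s, d, y)
        assert np.allclose(model.coefficients, reference.SURFACE_COEFFICIENTS,
                           atol=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_fit_of_condition_mean_costs_is_tight(self):
        """OLS on the 16 condition-mean costs explains nearly all variance."""
        speeds, depths, cots = [], [], []
        for name, depth in reference.STUDY_DEPTHS.items():
            for s, c in zip(reference.NOMINAL_SPEEDS, reference.CONDITION_MEAN_COT[name]):
                speeds.append(s)
                depths.append(depth)
                cots.append(c)
        model = fit_surface(speeds, depths, cots)
        assert model.r_squared >= 0.98
        # fitted interaction and depth terms carry the published signs
        assert model.coefficients[2] > 0  # speed*depth
        assert model.coefficients[4] < 0  # depth

    def test_underdetermined_fit_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            fit_surface([0.2] * 5, [0.5] * 5, [1.0] * 5)

    def test_collinear_design_rejected(self):
        s = np.linspace(0.2, 0.8, 8)
        with pytest.raises(ValueError, match="rank"):
            fit_surface(s, np.full(8, 0.85), np.ones(8))  # single depth

    def test_confidence_intervals_bracket_estimates(self):
        rng = np.random.default_rng(0)
        s, d, y = _grid_points()
        model = fit_surface(s, d, y + rng.normal(0, 0.1, size=len(y)))
        for term, coef in zip(
            ("speed2", "depth2", "speed_depth", "speed", "depth", "intercept"),
            model.coefficients,
        ):
            lo, hi = model.conf_int[term]
            assert lo < coef < hi


class TestEvaluateSurface:
    def test_published_maximum_condition(self):
        assert float(PUBLISHED.evaluate(0.8, 1.3)) == pytest.approx(13.0, abs=0.05)

    def test_origin_returns_intercept(self):
        assert float(PUBLISHED.evaluate(0.0, 0.0)) == pytest.approx(10.52)

    def test_hip_self_selected_point(self):
        assert round(float(PUBLISHED.evaluate(0.54, 0.85)), 1) == 4.1


class TestSurfaceExtrema:
    def test_maximum_at_deepest_fastest_corner(self):
        _, maximum = surface_extrema(PUBLISHED, (0.2, 0.8), (0.5, 1.3))
        assert round(maximum["value"], 1) == 13.0
        assert (maximum["speed"], maximum["depth"]) == (0.8, 1.3)

    def test_saddle_surface_puts_extrema_on_boundary(self):
        """The published quadratic has a negative Hessian determinant
        (4 a_ss a_dd - a_sd^2 < 0), so both extrema sit on the box edge."""
        a_ss, a_dd, a_sd = PUBLISHED.coefficients[:3]
        assert 4 * a_ss * a_dd - a_sd**2 < 0
        minimum, maximum = surface_extrema(PUBLISHED, (0.2, 0.8), (0.5, 1.3))
        assert minimum["where"] == "boundary"
        assert maximum["where"] == "boundary"

    def test_bowl_has_interior_minimum_and_corner_maximum(self):
        bowl = SurfaceModel(coefficients=(1, 1, 0, 0, 0, 0),
                            speed_domain=(-1, 1), depth_domain=(-1, 1))
        minimum, maximum = surface_extrema(bowl, (-1, 1), (-1, 1))
        assert minimum["value"] == pytest.approx(0.0, abs=1e-12)
        assert minimum["where"] == "interior"
        assert maximum["value"] == pytest.approx(2.0)

    def test_extrema_bound_a_dense_grid(self):
        minimum, maximum = surface_extrema(PUBLISHED, (0.2, 0.8), (0.5, 1.3))
        s = np.linspace(0.2, 0.8, 100)
        d = np.linspace(0.5, 1.3, 100)
        grid = PUBLISHED.evaluate(s[:, None], d[None, :])
        assert minimum["value"] <= grid.min() + 1e-9
        assert maximum["value"] >= grid.max() - 1e-9

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            surface_extrema(PUBLISHED, (0.5, 0.5), (0.5, 1.3))


class TestPerDepthCurve:
    def test_knee_depth_costs_form_j_shape(self):
        """The shallowest-depth condition means bend upward with an
        interior vertex — the J-shaped cost-speed relation."""
        curve = per_depth_curve(
            reference.NOMINAL_SPEEDS, reference.CONDITION_MEAN_COT["knee"], depth=0.5
        )
        assert curve.coefficients[0] > 0
        assert curve.shape == "interior_minimum"
        assert 0.2 < curve.vertex_speed < 0.8

    def test_linear_points_classified_monotone(self):
        curve = per_depth_curve([0.2, 0.4, 0.6, 0.8], [1.0, 2.0, 3.0, 4.0])
        assert curve.shape == "monotone"
        assert abs(curve.coefficients[0]) < 1e-9

    def test_symmetric_points_put_vertex_at_centre(self):
        curve = per_depth_curve([0.3, 0.5, 0.7], [1.0, 0.0, 1.0])
        assert curve.vertex_speed == pytest.approx(0.5)
        assert curve.shape == "interior_minimum"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            per_depth_curve([0.2, 0.4], [1.0, 2.0])


class TestIsoCostSpeed:
    def test_constant_meets_parabola_at_unit_speed(self):
        const = ReferenceCOTCurve("const", (3.0,), (0.0, 2.0))
        parab = ReferenceCOTCurve("parab", (1.0, 0.0, 2.0), (0.0, 2.0))
        points, degenerate = iso_cost_speed(const, parab, (0.0, 2.0))
        assert not degenerate
        assert len(points) == 1
        assert points[0][0] == pytest.approx(1.0)
        assert points[0][1] == pytest.approx(3.0)

    def test_identical_curves_flagged_degenerate(self):
        a = ReferenceCOTCurve("a", (1.0, 2.0, 3.0), (0.0, 2.0))
        b = ReferenceCOTCurve("b", (1.0, 2.0, 3.0), (0.0, 2.0))
        points, degenerate = iso_cost_speed(a, b, (0.0, 2.0))
        assert degenerate and points == []

    def test_offset_curves_never_intersect(self):
        a = ReferenceCOTCurve("a", (1.0, 0.0, 2.0), (0.0, 2.0))
        b = ReferenceCOTCurve("b", (1.0, 0.0, 3.0), (0.0, 2.0))
        points, degenerate = iso_cost_speed(a, b, (0.0, 2.0))
        assert points == [] and not degenerate

    def test_quadratic_pair_has_at_most_two_roots(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = ReferenceCOTCurve("a", tuple(rng.normal(size=3)), (-5, 5))
            b = ReferenceCOTCurve("b", tuple(rng.normal(size=3)), (-5, 5))
            points, degenerate = iso_cost_speed(a, b, (-5, 5))
            assert degenerate or len(points) <= 2


class TestSelfSelectedSummary:
    def test_hip_prediction_and_power(self):
        rows = self_selected_summary(PUBLISHED, {0.85: 0.54})
        (hip,) = rows
        assert round(hip.cot, 1) == 4.1
        assert round(hip.power_w_per_kg, 1) == 2.2

    def test_power_identity_and_met_definition(self):
        rows = self_selected_summary(
            PUBLISHED, {d: s for d, s in zip((0.5, 0.85, 1.12, 1.3),
                                             (0.62, 0.54, 0.49, 0.43))}
        )
        for r in rows:
            assert r.power_w_per_kg == pytest.approx(r.cot * r.speed, rel=1e-12)
            assert r.met == pytest.approx(r.vo2_ml_kg_min / 3.5, rel=1e-12)
            assert r.cal_kg_min == pytest.approx(r.power_w_per_kg * 60 / 4.186)

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ValueError):
            self_selected_summary(PUBLISHED, {0.85: 0.0})
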