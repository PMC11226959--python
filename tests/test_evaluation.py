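"""Slope regressions, significance labels, surfaces, and sweep plumbing."""

import numpy as np
import pytest

from bestmcg import (
    AccuracyTable,
    PipelineConfig,
    SweepPoint,
    cubic_geometries,
    cuboid_h_fixed_geometries,
    d4_grid_geometries,
    interpolate_surface,
    ols_slope_test,
    run_sweep,
    significance_label,
    slope_regression_protocol,
)
from conftest import quick_classifier


class TestOlsSlopeTest:
    def test_hand_derived_three_point_case(self):
        # x=(0,1,2), y=(0,1,1): beta1 = 1/2, SE = sqrt(1/12), t = sqrt(3),
        # two-tailed p from the 1-df t (Cauchy) distribution = 1/3 exactly.
        r = ols_slope_test([0, 1, 2], [0, 1, 1])
        assert r.slope == pytest.approx(0.5, rel=1e-12)
        assert r.stderr == pytest.approx(np.sqrt(1 / 12), rel=1e-9)
        assert r.t == pytest.approx(np.sqrt(3), rel=1e-9)
        assert r.p == pytest.approx(1 / 3, rel=1e-9)

    def test_constant_response_has_zero_slope_and_p_one(self):
        r = ols_slope_test([0, 1, 2, 3], [5.0, 5.0, 5.0, 5.0])
        assert r.slope == 0.0 and r.t == 0.0 and r.p == 1.0
        assert r.label == "n.s."

    def test_perfect_fit_is_flagged_degenerate(self):
        r = ols_slope_test([0.0, 1.0, 2.0, 3.0], [0.0, 2.0, 4.0, 6.0])
        assert r.slope == pytest.approx(2.0)
        assert r.degenerate and r.stderr == 0.0 and r.p == 0.0
        assert np.isinf(r.t)

    def test_matches_statsmodels_on_random_inputs(self, rng):
        import statsmodels.api as sm

        for _ in range(10):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = 0.3 * x + rng.normal(size=n)
            ours = ols_slope_test(x, y)
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            assert ours.slope == pytest.approx(fit.params[1], rel=1e-10)
            assert ours.stderr == pytest.approx(fit.bse[1], rel=1e-10)
            assert ours.t == pytest.approx(fit.tvalues[1], rel=1e-10)
            assert ours.p == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_two_tailed_p_symmetric_under_negation(self, rng):
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        forward = ols_slope_test(x, y)
        backward = ols_slope_test(x, -y)
        assert backward.slope == pytest.approx(-forward.slope, rel=1e-12)
        assert backward.t == pytest.approx(-forward.t, rel=1e-12)
        assert backward.p == pytest.approx(forward.p, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ols_slope_test([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            ols_slope_test([0.0, 1.0], [0.0, 1.0])


class TestSignificanceLabels:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.0005, "***"),
            (0.009, "**"),
            (0.019, "*"),
            (0.095, "n.s."),
            (0.001, "**"),   # boundaries are strict
            (0.01, "*"),
            (0.05, "n.s."),
        ],
    )
    def test_star_thresholds(self, p, label):
        assert significance_label(p) == label

    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            significance_label(p)


def _synthetic_table(family, geometries, fn, replicate=0):
    points = tuple(
        SweepPoint(a=a, h=h, d=d, accuracy=fn(a, h, d), seed=0, replicate=replicate)
        for a, h, d in geometries
    )
    return AccuracyTable(points=points, family=family)


class TestSlopeRegressionProtocol:
    def test_cubic_family_yields_twelve_rows(self):
        table = _synthetic_table(
            "cubic", cubic_geometries(), lambda a, h, d: 0.9 - 0.02 * a - 0.03 * d
        )
        results = slope_regression_protocol(table)
        assert len(results) == 12
        assert sum(r.regressor == "a" for r in results) == 5
        assert sum(r.regressor == "d" for r in results) == 7

    def test_d4_grid_yields_fourteen_rows(self):
        table = _synthetic_table(
            "d4_grid", d4_grid_geometries(), lambda a, h, d: 0.8 - 0.01 * h
        )
        results = slope_regression_protocol(table)
        assert len(results) == 14
        assert sum(r.regressor == "a" for r in results) == 7
        assert sum(r.regressor == "h" for r in results) == 7

    def test_single_control_level_with_three_points(self):
        geometries = [(a, 0.5, 2.0) for a in (0.5, 1.0, 1.5)]
        table = _synthetic_table(
            "cuboid_h_fixed", geometries, lambda a, h, d: 0.9 - 0.01 * a
        )
        results = slope_regression_protocol(table)
        assert len(results) == 1
        assert results[0].regressor == "a" and results[0].control == "d = 2"

    def test_recovers_planted_slopes(self):
        table = _synthetic_table(
            "cubic", cubic_geometries(), lambda a, h, d: 0.9 - 0.02 * a - 0.03 * d
        )
        for r in slope_regression_protocol(table):
            planted = -0.02 if r.regressor == "a" else -0.03
            assert r.slope == pytest.approx(planted, rel=1e-9)
            assert r.degenerate  # a perfect plane leaves zero residual


class TestSurfaces:
    def test_default_ad_surface_node_counts(self):
        table = _synthetic_table(
            "cubic", cubic_geometries(), lambda a, h, d: 0.9 - 0.02 * a - 0.03 * d
        )
        surface = interpolate_surface(table, mode="cubic")
        assert surface.values.shape == (301, 401)
        assert surface.x[0] == 2.0 and surface.x[-1] == 5.0 and len(surface.x) == 301
        assert surface.y[0] == 0.0 and surface.y[-1] == 4.0 and len(surface.y) == 401

    def test_constant_table_gives_constant_surface(self):
        for mode in ("linear", "cubic"):
            table = _synthetic_table("cubic", cubic_geometries(), lambda a, h, d: 0.75)
            surface = interpolate_surface(table, mode=mode)
            np.testing.assert_allclose(surface.values, 0.75, atol=1e-9)

    @pytest.mark.parametrize("mode", ["linear", "cubic"])
    def test_surface_reproduces_grid_nodes(self, mode):
        table = _synthetic_table(
            "cubic", cubic_geometries(), lambda a, h, d: 0.9 - 0.02 * a - 0.03 * d
        )
        surface = interpolate_surface(table, mode=mode)
        # d = 2 and a = 4 lie exactly on output nodes
        i = np.where(np.isclose(surface.x, 2.0))[0][0]
        j = np.where(np.isclose(surface.y, 4.0))[0][0]
        assert surface.values[i, j] == pytest.approx(0.9 - 0.02 * 4 - 0.03 * 2, abs=1e-9)

    def test_d4_grid_surface_axes(self):
        table = _synthetic_table(
            "d4_grid", d4_grid_geometries(), lambda a, h, d: 0.8 - 0.01 * h
        )
        surface = interpolate_surface(table, mode="linear")
        assert surface.values.shape == (401, 401)
        assert surface.x_name == "h" and surface.y_name == "a"

    def test_non_grid_scatter_rejected(self):
        geometries = [(0.5, 0.5, 2.0), (1.0, 1.0, 3.0), (1.5, 1.5, 2.0)]
        table = _synthetic_table("cubic", geometries, lambda a, h, d: 0.7)
        with pytest.raises(ValueError):
            interpolate_surface(table, mode="linear")

    def test_unknown_mode_rejected(self):
        table = _synthetic_table("cubic", cubic_geometries(), lambda a, h, d: 0.7)
        with pytest.raises(ValueError):
            interpolate_surface(table, mode="nearest")


class TestGeometryFamilies:
    def test_family_sizes_match_the_parameter_products(self):
        assert len(cubic_geometries()) == 35
        assert len(cuboid_h_fixed_geometries()) == 35
        assert len(d4_grid_geometries()) == 49
        assert all(a == h for a, h, _ in cubic_geometries())
        assert all(h == 0.5 for _, h, _ in cuboid_h_fixed_geometries())
        assert all(d == 4.0 for _, _, d in d4_grid_geometries())


class TestRunSweep:
    def test_scaled_sweep_is_deterministic(self):
        pipeline = PipelineConfig(
            n_per_class=30, sigma=0.04, classifier=quick_classifier(epochs=2)
        )
        geometries = [(0.5, 0.5, 2.0), (0.5, 0.5, 5.0)]
        t1 = run_sweep("cubic", geometries, pipeline, replicates=2, master_seed=5)
        t2 = run_sweep("cubic", geometries, pipeline, replicates=2, master_seed=5)
        assert t1.to_frame().equals(t2.to_frame())
        assert len(t1.points) == 4

    def test_empty_geometry_list_rejected(self):
        with pytest.raises(ValueError):
            run_sweep("cubic", [], PipelineConfig(sigma=0.1))
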