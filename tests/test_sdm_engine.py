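import numpy as np
import pandas as pd
import pytest
import shapely
from scipy.stats import percentileofscore

from sdmflow.geo_core import AccessibleArea, EnvStack, Grid, Raster, haversine_km
from sdmflow.sdm_engine import (
    BackgroundConfig,
    ThinConfig,
    TuneGrid,
    evaluate,
    fit_bioclim,
    fit_final,
    fit_maxent_like,
    run_pipeline,
    sample_background,
    select_method,
    spatial_partition,
    thin,
    tune,
)
from tests.conftest import presence_sample

KM = 1.0 / 111.195  # degrees of latitude per km


class TestThin:
    def test_close_pair_drops_one(self):
        keep = thin([-74.0, -74.0], [4.0, 4.0 + 0.5 * KM], 1.0, seed=0)
        assert len(keep) == 1

    def test_spaced_collinear_points_all_kept(self):
        lats = 4.0 + np.arange(5) * 2.0 * KM
        keep = thin(np.full(5, -74.0), lats, 1.0, seed=0)
        assert len(keep) == 5

    def test_single_point_returned(self):
        assert list(thin([-74.0], [4.0], 5.0, seed=0)) == [0]

    def test_no_violations_and_at_least_sequential_count(self):
        rng = np.random.default_rng(9)
        lon = -74.0 + rng.uniform(0, 0.3, 30)
        lat = 4.0 + rng.uniform(0, 0.3, 30)
        keep = thin(lon, lat, 5.0, seed=1)
        d = haversine_km(lon[keep][:, None], lat[keep][:, None],
                         lon[keep][None, :], lat[keep][None, :])
        off_diag = d[~np.eye(len(keep), dtype=bool)]
        assert (off_diag >= 5.0).all()
        # naive sequential scan oracle: keep a point if it is far enough
        # from everything already kept
        kept = []
        for i in range(30):
            if all(haversine_km(lon[i], lat[i], lon[j], lat[j]) >= 5.0
                   for j in kept):
                kept.append(i)
        assert len(keep) >= len(kept)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        lon = -74 + rng.uniform(0, 0.05, 20)
        lat = 4 + rng.uniform(0, 0.05, 20)
        a = thin(lon, lat, 2.0, seed=7)
        b = thin(lon, lat, 2.0, seed=7)
        np.testing.assert_array_equal(a, b)


class TestLadder:
    @pytest.mark.parametrize("n,method", [
        (1, "buffer"), (2, "buffer"), (3, "hull"), (4, "hull"),
        (5, "bioclim"), (9, "bioclim"), (10, "maxent_like"),
        (100, "maxent_like"),
    ])
    def test_count_to_method(self, n, method):
        assert select_method(n) == method

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            select_method(0)


class TestSampleBackground:
    def test_uniform_over_quadrants(self, env_stack, whole_area):
        lon, lat = sample_background(
            BackgroundConfig(mode="random", n_background=2000, seed=5),
            whole_area, env_stack)
        cx, cy = env_stack.grid.centroid
        counts = [
            ((lon < cx) & (lat < cy)).sum(), ((lon < cx) & (lat >= cy)).sum(),
            ((lon >= cx) & (lat < cy)).sum(), ((lon >= cx) & (lat >= cy)).sum(),
        ]
        from scipy.stats import chisquare

        assert chisquare(counts).pvalue > 0.001

    def test_bias_surface_confines_samples(self, env_stack, whole_area):
        bias = np.zeros(env_stack.grid.shape)
        bias[:, : env_stack.grid.width // 2] = 1.0
        lon, lat = sample_background(
            BackgroundConfig(mode="bias_surface", n_background=500, seed=1),
            whole_area, env_stack, bias_raster=Raster(env_stack.grid, bias))
        assert (lon < env_stack.grid.centroid[0]).all()

    def test_target_group_returns_points_inside_m(self, env_stack):
        g = env_stack.grid
        west_half = shapely.box(g.x0, g.y0 - g.dy * g.height,
                                g.x0 + g.dx * g.width / 2, g.y0)
        M = AccessibleArea(west_half, provenance="expert-drawn")
        rng = np.random.default_rng(0)
        pts = np.column_stack([
            rng.uniform(g.x0, g.x0 + g.dx * g.width, 100),
            rng.uniform(g.y0 - g.dy * g.height, g.y0, 100)])
        lon, lat = sample_background(
            BackgroundConfig(mode="target_group", n_background=10),
            M, env_stack, target_group_points=pts)
        inside = pts[:, 0] < g.x0 + g.dx * g.width / 2
        assert len(lon) == inside.sum()

    def test_reproducible_per_seed_and_capped(self, env_stack, whole_area):
        cfg = BackgroundConfig(mode="random", n_background=10_000, seed=3)
        with pytest.warns(UserWarning, match="valid cells"):
            lon1, lat1 = sample_background(cfg, whole_area, env_stack)
        with pytest.warns(UserWarning):
            lon2, _ = sample_background(cfg, whole_area, env_stack)
        np.testing.assert_array_equal(lon1, lon2)
        assert len(lon1) == env_stack.valid_mask.sum()  # one point per cell

    def test_zero_bias_in_m_errors(self, env_stack, whole_area):
        zero = Raster(env_stack.grid, np.zeros(env_stack.grid.shape))
        with pytest.raises(ValueError):
            sample_background(BackgroundConfig(mode="bias_surface"),
                              whole_area, env_stack, bias_raster=zero)


class TestBioclim:
    def test_multivariate_median_scores_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(21, 2))
        model = fit_bioclim(X)
        med = np.median(X, axis=0)  # 21 points: the median is a data point
        assert model.score(med[None, :])[0] == pytest.approx(1.0, abs=0.05)

    def test_beyond_envelope_scores_zero(self):
        X = np.random.default_rng(1).normal(size=(10, 2))
        model = fit_bioclim(X)
        probe = np.array([[X[:, 0].max() + 1.0, 0.0]])
        assert model.score(probe)[0] == 0.0

    def test_matches_percentile_oracle_on_toy_grid(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 10, size=(20, 2))
        model = fit_bioclim(X)
        cells = rng.uniform(-1, 11, size=(400, 2))  # a 20x20 grid's worth
        got = model.score(cells)
        for c, g in zip(cells, got):
            scores = []
            for j in range(2):
                if c[j] < X[:, j].min() or c[j] > X[:, j].max():
                    scores.append(0.0)
                else:
                    p = percentileofscore(X[:, j], c[j], kind="mean") / 100.0
                    scores.append(2 * min(p, 1 - p))
            assert g == pytest.approx(min(scores), abs=1e-12)

    def test_constant_variable_degenerates_with_warning(self):
        X = np.column_stack([np.full(8, 3.0),
                             np.random.default_rng(3).normal(size=8)])
        with pytest.warns(UserWarning, match="constant"):
            model = fit_bioclim(X)
        probe = np.array([[3.0, float(np.median(X[:, 1]))]])
        assert model.score(probe)[0] == pytest.approx(1.0, abs=0.07)

    def test_too_few_presences_rejected(self):
        with pytest.raises(ValueError):
            fit_bioclim(np.zeros((4, 2)))


class TestMaxentLike:
    def _one_var_data(self, seed=0, n_p=60, n_b=500):
        rng = np.random.default_rng(seed)
        Xb = rng.uniform(0, 1, size=(n_b, 1))
        # presences concentrated at high values of the single variable
        Xp = rng.beta(6, 1.5, size=(n_p, 1))
        return Xp, Xb

    def test_monotone_in_informative_variable(self):
        Xp, Xb = self._one_var_data()
        model = fit_maxent_like(Xp, Xb, ["v"], features=("linear", "quadratic"),
                                reg_multiplier=1.0)
        probe = np.linspace(0.05, 0.95, 50)[:, None]
        s = model.score(probe)
        from scipy.stats import spearmanr

        assert spearmanr(probe.ravel(), s).statistic > 0.95

    def test_huge_regularization_flattens_surface(self):
        Xp, Xb = self._one_var_data()
        model = fit_maxent_like(Xp, Xb, ["v"], features=("linear",),
                                reg_multiplier=1e6)
        s = model.score(np.linspace(0, 1, 20)[:, None])
        assert s.max() - s.min() < 1e-3

    def test_output_bounded_and_deterministic(self):
        Xp, Xb = self._one_var_data(seed=4)
        m1 = fit_maxent_like(Xp, Xb, ["v"], seed=3)
        m2 = fit_maxent_like(Xp, Xb, ["v"], seed=3)
        s1, s2 = m1.score(Xb), m2.score(Xb)
        np.testing.assert_array_equal(s1, s2)
        assert (s1 >= 0).all() and (s1 <= 1).all()

    def test_virtual_species_holdout_auc(self, env_stack, species, whole_area):
        xy = presence_sample(species, 100, seed=21)
        lon_b, lat_b = sample_background(
            BackgroundConfig(mode="random", n_background=3000, seed=21),
            whole_area, env_stack)
        Xp = env_stack.sample(xy[:, 0], xy[:, 1])
        Xb = env_stack.sample(lon_b, lat_b)
        labels = spatial_partition(xy[:, 0], xy[:, 1], 4)
        train, test = labels != 0, labels == 0
        model = fit_maxent_like(Xp[train], Xb, env_stack.names,
                                features=("linear", "quadratic", "product"),
                                reg_multiplier=1.0)
        ev = evaluate(model.score(Xp[test]), model.score(Xb))
        assert ev["auc"] > 0.8

    def test_variable_importance_attribution(self):
        rng = np.random.default_rng(6)
        Xb = rng.uniform(0, 1, size=(400, 2))
        Xp = np.column_stack([rng.beta(6, 1.5, 80), rng.uniform(0, 1, 80)])
        model = fit_maxent_like(Xp, Xb, ["signal", "noise"],
                                features=("linear", "quadratic"))
        imp = model.variable_importance()
        assert imp["signal"] > imp["noise"]


class TestSpatialPartition:
    def test_one_point_per_quadrant(self):
        lon = [-75.0, -75.0, -73.0, -73.0]
        lat = [3.0, 5.0, 3.0, 5.0]
        labels = spatial_partition(lon, lat, 4)
        assert sorted(labels) == [0, 1, 2, 3]

    def test_two_per_quadrant(self):
        lon = [-75, -74.9, -75, -74.9, -73, -72.9, -73, -72.9]
        lat = [3, 3.1, 5, 5.1, 3, 3.1, 5, 5.1]
        labels = spatial_partition(lon, lat, 4)
        assert sorted(np.bincount(labels, minlength=4)) == [2, 2, 2, 2]

    def test_101_points_balanced_and_total(self):
        rng = np.random.default_rng(10)
        lon = rng.uniform(-76, -72, 101)
        lat = rng.uniform(2, 6, 101)
        labels = spatial_partition(lon, lat, 4)
        sizes = np.bincount(labels, minlength=4)
        assert sizes.sum() == 101
        assert sizes.max() - sizes.min() <= 2

    def test_unsupported_k(self):
        with pytest.raises(ValueError):
            spatial_partition([0, 1, 2], [0, 1, 2], 3)


def brute_force_auc(p, b):
    wins = sum((pi > bi) + 0.5 * (pi == bi) for pi in p for bi in b)
    return wins / (len(p) * len(b))


class TestEvaluate:
    def test_perfect_separation(self):
        assert evaluate([1, 1, 1], [0, 0, 0])["auc"] == 1.0

    def test_constant_scores_give_half(self):
        assert evaluate([0.5] * 10, [0.5] * 30)["auc"] == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(11)
        p = rng.random(20)
        b = np.round(rng.random(100), 1)  # induce ties
        got = evaluate(p, b)["auc"]
        assert got == pytest.approx(brute_force_auc(p, b), abs=1e-12)

    def test_omission_is_fraction_below_threshold(self):
        ev = evaluate([0.1, 0.4, 0.9], [0.0], {"t": 0.5})
        assert ev["omission"]["t"] == pytest.approx(2 / 3)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [0.1])


@pytest.fixture(scope="module")
def tune_inputs(env_stack, species, whole_area):
    xy = presence_sample(species, 60, seed=13)
    lon_b, lat_b = sample_background(
        BackgroundConfig(mode="random", n_background=1500, seed=13),
        whole_area, env_stack)
    return xy, np.column_stack([lon_b, lat_b])


class TestTune:
    def test_single_combination_returned(self, tune_inputs, env_stack):
        xy, bg = tune_inputs
        grid = TuneGrid(regularization_multipliers=(1.0,),
                        feature_classes=(("linear", "quadratic"),))
        best, table = tune(xy, bg, env_stack, grid, seed=0)
        assert best == {"features": ("linear", "quadratic"),
                        "reg_multiplier": 1.0}
        assert len(table) == 1

    def test_selection_rule_matches_table_recomputation(self, tune_inputs,
                                                        env_stack):
        xy, bg = tune_inputs
        grid = TuneGrid(regularization_multipliers=(0.5, 1.0, 4.0),
                        feature_classes=(("linear",), ("linear", "quadratic")))
        best, table = tune(xy, bg, env_stack, grid, seed=0)
        # independent re-application of the rule on the returned table
        t = table.sort_values(
            ["mean_test_omission", "mean_test_auc", "reg_multiplier"],
            ascending=[True, False, True], kind="stable").iloc[0]
        assert best["reg_multiplier"] == t["reg_multiplier"]
        assert ",".join(best["features"]) == t["features"]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            TuneGrid(regularization_multipliers=())


class TestFitFinal:
    def test_buffer_binary_is_rasterized_disks(self, env_stack, whole_area):
        g = env_stack.grid
        xy = np.array([[g.x0 + 0.3, g.y0 - 0.3]])
        res = fit_final(xy, env_stack, whole_area, "buffer", buffer_km=10.0)
        assert res.suitability is None
        from sdmflow.geo_core import buffer_points, rasterize_geometry

        expected = rasterize_geometry(
            buffer_points(xy[:, 0], xy[:, 1], 10.0), g) & env_stack.valid_mask
        np.testing.assert_array_equal(res.binaries[0].data.astype(bool),
                                      expected)

    def test_hull_binary(self, env_stack, whole_area):
        g = env_stack.grid
        xy = np.array([[g.x0 + 0.1, g.y0 - 0.1], [g.x0 + 0.5, g.y0 - 0.1],
                       [g.x0 + 0.3, g.y0 - 0.5], [g.x0 + 0.3, g.y0 - 0.2]])
        res = fit_final(xy, env_stack, whole_area, "hull")
        from sdmflow.geo_core import convex_hull, rasterize_geometry

        expected = rasterize_geometry(convex_hull(xy[:, 0], xy[:, 1]),
                                      g) & env_stack.valid_mask
        np.testing.assert_array_equal(res.binaries[0].data.astype(bool),
                                      expected)

    def test_collinear_hull_falls_back_to_buffer(self, env_stack, whole_area):
        g = env_stack.grid
        xy = np.array([[g.x0 + 0.1, g.y0 - 0.1], [g.x0 + 0.2, g.y0 - 0.2],
                       [g.x0 + 0.3, g.y0 - 0.3]])
        with pytest.warns(UserWarning, match="degenerate hull"):
            res = fit_final(xy, env_stack, whole_area, "hull")
        assert res.method == "buffer"
        assert res.binaries[0].data.any()

    def test_bioclim_minimum_training_presence_covers_presences(
            self, env_stack, species, whole_area):
        xy = presence_sample(species, 8, seed=17)
        res = fit_final(xy, env_stack, whole_area, "bioclim")
        binary = res.binaries[0]
        vals = binary.sample(xy[:, 0], xy[:, 1])
        assert (vals == 1).all()

    def test_binaries_nested_and_suitability_bounded(self, env_stack, species,
                                                     whole_area):
        xy = presence_sample(species, 30, seed=19)
        res = fit_final(xy, env_stack, whole_area, "bioclim")
        s = res.suitability.data
        assert np.nanmin(s) >= 0 and np.nanmax(s) <= 1
        assert res.suitability.grid == env_stack.grid
        for lo, hi in ((30, 20), (20, 10), (10, 0)):
            assert (res.binaries[lo].data <= res.binaries[hi].data).all()


class TestRunPipeline:
    def test_two_points_take_buffer_route(self, env_stack):
        g = env_stack.grid
        xy = np.array([[g.x0 + 0.2, g.y0 - 0.2], [g.x0 + 0.25, g.y0 - 0.25]])
        res = run_pipeline(xy, env_stack, seed=0)
        assert res.method == "buffer"
        assert res.metadata["M_provenance"] == "buffer-derived"

    def test_seven_points_take_bioclim_route(self, env_stack, species):
        xy = presence_sample(species, 7, seed=23)
        res = run_pipeline(xy, env_stack, seed=0)
        assert res.method == "bioclim"
        assert res.suitability is not None

    def test_thinning_is_applied(self, env_stack, species):
        xy = np.repeat(presence_sample(species, 3, seed=29), 4, axis=0)
        res = run_pipeline(xy, env_stack,
                           thin_config=ThinConfig(min_distance_km=1.0), seed=0)
        assert res.metadata["n_occurrences"] <= 3
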