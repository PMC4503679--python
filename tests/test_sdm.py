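import numpy as np
import pytest
from scipy.stats import chisquare

from rangerisk import sdm, synth
from rangerisk.grids import CLIMATE_VARIABLES, ClimateStack
from rangerisk.sdm import (
    binarize,
    fit,
    pca_screen,
    resample_to_analysis_grid,
    roc_auc,
    sample_background,
    validate_split,
)


class TestResample:
    def _stack(self, data, cell=0.0225):
        return ClimateStack({"x": data}, (-79.0, 2.0), cell)

    def test_constant_layer_stays_constant(self):
        out = resample_to_analysis_grid(self._stack(np.full((8, 8), 7.0)))
        assert (out.layers["x"] == 7.0).all()

    def test_block_mean(self):
        data = np.array([[10.0, 10.0], [20.0, 20.0]])
        out = resample_to_analysis_grid(self._stack(data))
        assert out.layers["x"][0, 0] == 15.0
        assert out.cell_size_deg == pytest.approx(0.045)

    def test_mass_balance_on_complete_blocks(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(16, 16))
        out = resample_to_analysis_grid(self._stack(data))
        assert out.layers["x"].mean() == pytest.approx(data.mean(), abs=1e-9)

    def test_binary_layer_majority(self):
        data = np.array([[1.0, 1.0], [1.0, 0.0]])
        out = resample_to_analysis_grid(self._stack(data))
        assert out.layers["x"][0, 0] == 1.0

    def test_coarser_input_rejected(self):
        with pytest.raises(ValueError):
            resample_to_analysis_grid(self._stack(np.ones((8, 8)), cell=0.1))


class TestPcaScreen:
    def test_perfectly_correlated_layers_load_on_first_component(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 20))
        stack = ClimateStack({"a": a, "b": 3 * a + 1}, (-79.0, 2.0), 0.045)
        _, evr = pca_screen(stack)
        assert evr[0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_noise_layers_share_variance(self):
        rng = np.random.default_rng(2)
        layers = {k: rng.normal(size=(100, 100)) for k in "abcd"}
        stack = ClimateStack(layers, (-79.0, 2.0), 0.045)
        _, evr = pca_screen(stack)
        assert evr.max() - evr.min() < 0.05

    def test_constant_layer_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        stack = ClimateStack(
            {"a": rng.normal(size=(10, 10)), "b": np.ones((10, 10)),
             "c": rng.normal(size=(10, 10))},
            (-79.0, 2.0), 0.045,
        )
        with pytest.warns(UserWarning):
            loadings, _ = pca_screen(stack)
        assert "b" not in loadings.index

    def test_default_predictor_set_is_the_four_bioclim_variables(self, world):
        loadings, _ = pca_screen(world["climate"])
        assert tuple(loadings.index) == CLIMATE_VARIABLES


class TestSampleBackground:
    def test_region_wide_points_inside_window(self, world):
        t = world["terrain"]
        bg = sample_background(t, n=1000, seed=1)
        assert bg.points.shape == (1000, 2)
        assert (bg.points[:, 0] >= t.west).all() and (bg.points[:, 0] < t.east).all()
        assert (bg.points[:, 1] > t.south).all() and (bg.points[:, 1] <= t.north).all()

    def test_within_mcp_points_inside_polygon(self, world):
        from rangerisk.geometry import convex_hull

        tri = convex_hull(np.array([[-78.5, 1.5], [-77.5, 1.5], [-78.0, 0.5]]), "t")
        bg = sample_background(world["terrain"], n=200, seed=2, scheme="within_mcp", mcp=tri)
        import shapely

        assert shapely.intersects_xy(
            tri.polygon.buffer(1e-12), bg.points[:, 0], bg.points[:, 1]
        ).all()

    def test_quadrant_uniformity_over_seeds(self, world):
        # region-wide sampling is uniform: chi-square on 4 quadrants should
        # almost never reject at alpha = 0.01
        t = world["terrain"]
        mid_lon = (t.west + t.east) / 2
        mid_lat = (t.south + t.north) / 2
        rejections = 0
        for seed in range(50):
            bg = sample_background(t, n=400, seed=seed)
            q = (
                2 * (bg.points[:, 0] >= mid_lon) + (bg.points[:, 1] >= mid_lat)
            )
            counts = np.bincount(q, minlength=4)
            if chisquare(counts).pvalue < 0.01:
                rejections += 1
        assert rejections <= 3

    def test_degenerate_region_rejected(self, world):
        from rangerisk.geometry import DegenerateHull, convex_hull

        with pytest.raises((ValueError, DegenerateHull)):
            mcp = convex_hull(np.array([[0, 0], [1, 0], [2, 0]]), "line")
            sample_background(world["terrain"], scheme="within_mcp", mcp=mcp)


class TestFit:
    def test_recovery_of_planted_niche_all_methods(self, world, montane_niche, montane_occurrences):
        clim, terrain = world["climate"], world["terrain"]
        bg = sample_background(terrain, n=500, seed=3)
        # covariates at the niche optimum vs a hot lowland anti-optimum
        anti = np.array([
            clim.layers[v].ravel()[np.argmax(terrain.data.ravel() < 0)]
            for v in CLIMATE_VARIABLES
        ])
        for method in sdm.METHODS:
            model = fit(method, montane_occurrences.points, bg, clim, seed=1)
            s = model.predict(np.vstack([montane_niche.optimum, anti]))
            assert 0 <= s.min() and s.max() <= 1
            assert s[0] > s[1], method

    def test_no_signal_auc_near_half(self, world):
        # presences drawn from the background distribution carry no signal
        rng = np.random.default_rng(0)
        t = world["terrain"]
        aucs = []
        for rep in range(50):
            pts = sample_background(t, n=30, seed=100 + rep).points
            bg = sample_background(t, n=200, seed=200 + rep)
            test_p = sample_background(t, n=30, seed=300 + rep).points
            test_b = sample_background(t, n=200, seed=400 + rep).points
            model = fit("smooth_additive", pts, bg, world["climate"], seed=rep)
            sp = model.predict(world["climate"].covariates_at(test_p[:, 0], test_p[:, 1]))
            sb = model.predict(world["climate"].covariates_at(test_b[:, 0], test_b[:, 1]))
            aucs.append(roc_auc(sp, sb))
        assert abs(np.mean(aucs) - 0.5) <= 0.05

    def test_refit_deterministic(self, world, montane_occurrences):
        bg = sample_background(world["terrain"], n=300, seed=4)
        grid_pts = world["climate"].covariates_at(
            bg.points[:50, 0], bg.points[:50, 1]
        )
        for method in sdm.METHODS:
            a = fit(method, montane_occurrences.points, bg, world["climate"], seed=7)
            b = fit(method, montane_occurrences.points, bg, world["climate"], seed=7)
            np.testing.assert_allclose(a.predict(grid_pts), b.predict(grid_pts), atol=1e-10)

    def test_degenerate_covariate_named_in_error(self, world, montane_occurrences):
        clim = world["climate"]
        flat = ClimateStack(
            {**clim.layers, "diurnal_range_C": np.full(clim.shape, 11.0)},
            clim.origin, clim.cell_size_deg,
        )
        bg = sample_background(world["terrain"], n=100, seed=5)
        with pytest.raises(ValueError, match="diurnal_range_C"):
            fit("smooth_additive", montane_occurrences.points, bg, flat)

    def test_too_few_presences_rejected(self, world):
        bg = sample_background(world["terrain"], n=100, seed=6)
        with pytest.raises(ValueError):
            fit("smooth_additive", bg.points[:4], bg, world["climate"])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_identical_sets_give_half(self):
        assert roc_auc([0.3, 0.7], [0.3, 0.7]) == 0.5

    def test_matches_brute_force_pairwise_count(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            pos = rng.integers(0, 10, size=rng.integers(2, 200)) / 10
            neg = rng.integers(0, 10, size=rng.integers(2, 200)) / 10
            brute = np.mean(
                (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
            )
            assert roc_auc(pos, neg) == pytest.approx(brute, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [0.1])


class TestValidateSplit:
    def test_separable_species_scores_auc_one(self, world, montane_occurrences):
        # score the held-out presences against a background of hot lowland
        # points only: trivially separable for a montane specialist
        t = world["terrain"]
        low = np.argwhere(t.data < 500)
        rng = np.random.default_rng(8)
        rows = low[rng.integers(0, len(low), 400)]
        lon = t.west + (rows[:, 1] + 0.5) * t.cell_size_deg
        lat = t.north - (rows[:, 0] + 0.5) * t.cell_size_deg
        bg = sdm.BackgroundSample(np.column_stack([lon, lat]), "region_wide", 400)
        res = validate_split("m", montane_occurrences.points, bg, world["climate"])
        assert res is not None and res.auc == 1.0

    def test_shuffled_presences_auc_near_half(self, world):
        aucs = []
        for seed in range(50):
            pts = sample_background(world["terrain"], n=24, seed=500 + seed).points
            bg = sample_background(world["terrain"], n=300, seed=600 + seed)
            res = validate_split("s", pts, bg, world["climate"], seed=seed)
            if res is not None:
                aucs.append(res.auc)
        assert len(aucs) > 30
        assert abs(np.mean(aucs) - 0.5) <= 0.05

    def test_within_mcp_background_is_harder(self, world, montane_occurrences):
        from rangerisk.geometry import convex_hull

        pts = montane_occurrences.points
        mcp = convex_hull(pts, "m")
        region = sample_background(world["terrain"], n=500, seed=10)
        inside = sample_background(
            world["terrain"], n=500, seed=10, scheme="within_mcp", mcp=mcp
        )
        a = validate_split("m", pts, region, world["climate"], seed=1)
        b = validate_split("m", pts, inside, world["climate"], seed=1)
        assert a.auc > b.auc

    def test_small_half_skipped(self, world):
        pts = np.column_stack([np.full(5, -78.0), np.linspace(1.0, 1.5, 5)])
        bg = sample_background(world["terrain"], n=100, seed=11)
        assert validate_split("tiny", pts, bg, world["climate"]) is None


class TestBinarize:
    def test_full_sensitivity_includes_every_presence_cell(self):
        rng = np.random.default_rng(13)
        suit = rng.random((20, 20))
        scores = rng.random(15)
        mask, cutoff = binarize(suit, scores, sensitivity=1.0)
        assert cutoff == scores.min()
        assert mask.sum() >= (suit >= scores.min()).sum()

    def test_lower_sensitivity_never_grows_range(self):
        rng = np.random.default_rng(14)
        suit = rng.random((20, 20))
        scores = rng.random(40)
        sizes = [
            binarize(suit, scores, s)[0].sum() for s in (1.0, 0.9, 0.7, 0.5, 0.3)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_planted_niche_range_overlaps_truth(self, world, montane_niche, montane_occurrences):
        clim = world["climate"]
        bg = sample_background(world["terrain"], n=1000, seed=15)
        model = fit("smooth_additive", montane_occurrences.points, bg, clim, seed=15)
        suit = model.predict_grid(clim)
        pts = montane_occurrences.points
        scores = model.predict(clim.covariates_at(pts[:, 0], pts[:, 1]))
        est, _ = binarize(suit, scores, 0.9)
        true_suit = synth.true_suitability(montane_niche, clim)
        thr = np.sort(true_suit.ravel())[::-1][int(est.sum()) - 1]
        truth = true_suit >= thr
        jaccard = (est & truth).sum() / (est | truth).sum()
        assert jaccard >= 0.7

    def test_constant_surface_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.full((5, 5), 0.4), np.array([0.4, 0.4]))


def test_scenario_projection_reuses_fitted_model(world, montane_occurrences):
    """Projection under a scenario queries the same fitted object; no refit."""
    bg = sample_background(world["terrain"], n=300, seed=16)
    model = fit("smooth_additive", montane_occurrences.points, bg, world["climate"], seed=16)
    state_before = model._state["clf"]
    fut = synth.apply_scenario(world["climate"], synth.A2_LIKE)
    model.predict_grid(fut)
    assert model._state["clf"] is state_before
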