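import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from phenoniche import maxent, synth
from phenoniche.raster import EnvStack, GridSpec


def _presences_from_density(env, layer, beta, n, seed):
    """Sample presence cell centers with probability proportional to exp(beta*layer)."""
    rng = np.random.default_rng(seed)
    vals = env.layers[layer]
    w = np.exp(beta * vals.ravel())
    w /= w.sum()
    cells = rng.choice(vals.size, size=n, p=w)
    r, c = np.unravel_index(cells, vals.shape)
    lon, lat = env.grid.cell_center(r, c)
    return np.column_stack([lon, lat])


class TestSelectPredictors:
    def test_correlated_pair_one_dropped(self):
        target = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
        cfg = synth.SyntheticConfig(grid_shape=(60, 60), n_layers=3,
                                    target_corr=target, seed=1)
        env = synth.generate_env_stack(cfg)
        kept = maxent.select_predictors(env, n_points=3000, seed=2)
        assert "env_2" in kept
        assert len([k for k in kept if k in ("env_0", "env_1")]) == 1
        # oracle: brute-force r over the same sampled points exceeds the cutoff
        X = np.column_stack([env.layers["env_0"].ravel(), env.layers["env_1"].ravel()])
        assert abs(np.corrcoef(X, rowvar=False)[0, 1]) > 0.7

    def test_independent_layers_all_kept(self):
        cfg = synth.SyntheticConfig(grid_shape=(60, 60), n_layers=3, seed=3)
        env = synth.generate_env_stack(cfg)
        kept = maxent.select_predictors(env, n_points=3000, seed=4)
        assert sorted(kept) == ["env_0", "env_1", "env_2"]

    def test_duplicated_layer_dropped_deterministically(self):
        grid = GridSpec(40, 40, 0, 0, 0.1)
        base = np.random.default_rng(5).normal(size=(40, 40))
        other = np.random.default_rng(6).normal(size=(40, 40))
        env = EnvStack(grid, {"a": base, "b": base.copy(), "c": other})
        kept1 = maxent.select_predictors(env, n_points=1000, seed=7)
        kept2 = maxent.select_predictors(env, n_points=1000, seed=7)
        assert kept1 == kept2
        assert "c" in kept1 and len(kept1) == 2

    def test_oversampling_capped_with_warning(self):
        grid = GridSpec(10, 10, 0, 0, 0.1)
        rng = np.random.default_rng(8)
        env = EnvStack(grid, {"a": rng.normal(size=(10, 10)),
                              "b": rng.normal(size=(10, 10))})
        with pytest.warns(UserWarning, match="available"):
            maxent.select_predictors(env, n_points=10_000, seed=9)


class TestSampleBackground:
    def test_unique_cells(self, unit_env):
        pts = maxent.sample_background(unit_env, 5000, seed=0)
        assert len(np.unique(pts, axis=0)) == 5000

    def test_request_capped(self, unit_env):
        with pytest.warns(UserWarning, match="valid cells"):
            pts = maxent.sample_background(unit_env, 20_000, seed=1)
        assert len(pts) == 10_000

    def test_seed_reproducible(self, unit_env):
        a = maxent.sample_background(unit_env, 100, seed=2)
        b = maxent.sample_background(unit_env, 100, seed=2)
        np.testing.assert_array_equal(a, b)


class TestFit:
    def test_raw_normalizes_over_background(self, unit_env):
        pres = _presences_from_density(unit_env, "x", 2.0, 200, 1)
        bg = maxent.sample_background(unit_env, 2000, seed=2)
        model = maxent.fit_maxent(pres, bg, unit_env)
        Xbg = maxent._extract(unit_env, bg)
        raw = maxent.raw_values(model, Xbg)
        assert raw.sum() == pytest.approx(1.0, abs=1e-8)

    def test_no_signal_flat_output(self, unit_env):
        pres = maxent.sample_background(unit_env, 500, seed=3)
        bg = maxent.sample_background(unit_env, 3000, seed=4)
        model = maxent.fit_maxent(pres, bg, unit_env,
                                  features=maxent.FeatureSpec(classes=("linear", "quadratic")))
        out = maxent.predict(model, unit_env).values
        v = out[np.isfinite(out)]
        assert v.max() - v.min() < 0.1

    def test_parameter_recovery_single_seed(self, unit_env):
        pres = _presences_from_density(unit_env, "x", 2.0, 2000, 5)
        bg = maxent.sample_background(unit_env, 5000, seed=6)
        model = maxent.fit_maxent(pres, bg, unit_env,
                                  features=maxent.FeatureSpec(classes=("linear",)))
        span = model.mapper.maxs[0] - model.mapper.mins[0]
        assert model.weights[0] / span == pytest.approx(2.0, rel=0.10)

    def test_objective_monotone_decreasing(self, unit_env):
        pres = _presences_from_density(unit_env, "x", 1.5, 150, 7)
        bg = maxent.sample_background(unit_env, 2000, seed=8)
        model = maxent.fit_maxent(pres, bg, unit_env)
        assert (np.diff(model.objective_path) <= 1e-10).all()

    def test_convergence_flag(self, unit_env):
        pres = _presences_from_density(unit_env, "x", 1.0, 100, 9)
        bg = maxent.sample_background(unit_env, 1000, seed=10)
        model = maxent.fit_maxent(pres, bg, unit_env, max_iter=500, tol=1e-5)
        assert model.converged
        short = maxent.fit_maxent(pres, bg, unit_env, max_iter=2, tol=1e-12)
        assert not short.converged and short.iterations_run == 2

    def test_nonfinite_layer_named(self):
        grid = GridSpec(10, 10, 0, 0, 0.1)
        vals = np.ones((10, 10))
        env = EnvStack(grid, {"good": vals, "broken": vals})
        Xp = np.array([[1.0, np.inf], [1.0, 1.0]])
        Xb = np.ones((50, 2))
        with pytest.raises(ValueError, match="broken"):
            maxent.fit_maxent_design(Xp, Xb, ["good", "broken"])

    def test_too_few_presences(self):
        with pytest.raises(ValueError, match="presence"):
            maxent.fit_maxent_design(np.ones((1, 1)), np.ones((10, 1)), ["x"])

    def test_auto_features_by_sample_size(self):
        assert maxent.auto_feature_classes(5) == ("linear",)
        assert maxent.auto_feature_classes(12) == ("linear", "quadratic")
        assert "hinge" in maxent.auto_feature_classes(50)
        assert maxent.auto_feature_classes(200) == ("linear", "quadratic", "product", "hinge")


class TestPredict:
    def test_logistic_bounds(self, unit_env):
        pres = _presences_from_density(unit_env, "x", 2.0, 300, 11)
        bg = maxent.sample_background(unit_env, 2000, seed=12)
        model = maxent.fit_maxent(pres, bg, unit_env)
        out = maxent.predict(model, unit_env).values
        v = out[np.isfinite(out)]
        assert (v >= 0).all() and (v <= 1).all()

    def test_uniform_model_is_half(self, unit_env):
        bg = maxent.sample_background(unit_env, 2000, seed=13)
        Xb = maxent._extract(unit_env, bg)
        model = maxent.fit_maxent_design(Xb[:100], Xb, ["x"],
                                         features=maxent.FeatureSpec(classes=("linear",)),
                                         max_iter=1, tol=1e30)
        # zero-weight model: every background cell equally suitable
        model.weights[:] = 0.0
        model.log_z = np.log(len(Xb))
        model.entropy = np.log(len(Xb))
        vals = maxent.predict_values(model, Xb)
        np.testing.assert_allclose(vals, 0.5, atol=1e-12)

    def test_monotone_in_single_layer(self, unit_env):
        pres = _presences_from_density(unit_env, "x", 2.0, 1000, 14)
        bg = maxent.sample_background(unit_env, 3000, seed=15)
        model = maxent.fit_maxent(pres, bg, unit_env,
                                  features=maxent.FeatureSpec(classes=("linear",)))
        grid = np.linspace(0.0, 1.0, 50)[:, None]
        vals = maxent.predict_values(model, grid)
        assert (np.diff(vals) >= -1e-12).all()

    def test_missing_layer_rejected(self, unit_env):
        pres = _presences_from_density(unit_env, "x", 1.0, 50, 16)
        bg = maxent.sample_background(unit_env, 500, seed=17)
        model = maxent.fit_maxent(pres, bg, unit_env)
        other = EnvStack(unit_env.grid, {"y": np.ones(unit_env.grid.shape)})
        with pytest.raises(ValueError, match="missing"):
            maxent.predict(model, other)


class TestAuc:
    def test_matches_sklearn(self):
        rng = np.random.default_rng(18)
        pos = rng.normal(1.0, 1.0, 200)
        neg = rng.normal(0.0, 1.0, 300)
        y = np.concatenate([np.ones(200), np.zeros(300)])
        s = np.concatenate([pos, neg])
        assert maxent.auc_score(pos, neg) == pytest.approx(roc_auc_score(y, s))

    def test_ties_give_half(self):
        assert maxent.auc_score(np.ones(10), np.ones(10)) == 0.5


class TestRunReplicates:
    def test_informative_truth_high_auc(self, niche_truth):
        mel = [r for r in niche_truth.records if r.phenotype == "melanistic"]
        _, ev = maxent.run_replicates(
            mel, niche_truth.env, n_replicates=3, seed=0, n_background=2000,
            features=maxent.FeatureSpec(classes=("linear", "quadratic")),
        )
        assert ev.auc_test > 0.8

    def test_uninformative_auc_near_half(self, flat_truth):
        recs = [r for r in flat_truth.records if r.phenotype == "non_melanistic"][:120]
        _, ev = maxent.run_replicates(
            recs, flat_truth.env, n_replicates=4, seed=1, n_background=2000,
            features=maxent.FeatureSpec(classes=("linear", "quadratic")),
        )
        assert abs(ev.auc_test - 0.5) <= 0.05

    def test_importance_ranking_and_sum(self, niche_truth):
        mel = [r for r in niche_truth.records if r.phenotype == "melanistic"]
        _, ev = maxent.run_replicates(
            mel, niche_truth.env, n_replicates=3, seed=2, n_background=2000,
            features=maxent.FeatureSpec(classes=("linear", "quadratic")),
        )
        assert ev.importance_sum() == pytest.approx(100.0, abs=0.1)
        imp = ev.variable_importance
        # env_0 carries the true signal; env_1/env_2 have zero true coefficients
        assert imp["env_0"] > imp["env_1"]
        assert imp["env_0"] > imp["env_2"]

    def test_mean_map_masked(self, niche_truth):
        mel = [r for r in niche_truth.records if r.phenotype == "melanistic"]
        mean_map, _ = maxent.run_replicates(
            mel, niche_truth.env, n_replicates=2, seed=3, n_background=1000,
            features=maxent.FeatureSpec(classes=("linear",)),
        )
        assert np.isfinite(mean_map.values[niche_truth.env.mask]).all()

    def test_bad_train_fraction(self, niche_truth):
        with pytest.raises(ValueError):
            maxent.run_replicates(niche_truth.records, niche_truth.env,
                                  train_fraction=1.5)

    def test_separable_data_auc_one(self):
        # one layer, presences strictly above a threshold, no regularization
        grid = GridSpec(50, 50, 0, 0, 0.1)
        vals = np.linspace(0, 1, 2500).reshape(50, 50)
        env = EnvStack(grid, {"x": vals})
        rows, cols = np.nonzero(vals > 0.8)
        lon, lat = grid.cell_center(rows, cols)
        pres = np.column_stack([lon, lat])
        bg = maxent.sample_background(env, 2000, seed=4)
        model = maxent.fit_maxent(pres, bg, env,
                                  features=maxent.FeatureSpec(classes=("linear",)),
                                  reg_multiplier=1e-8, max_iter=2000, tol=1e-9)
        Xp = maxent._extract(env, pres)
        Xb = maxent._extract(env, bg)
        sp = maxent.predict_values(model, Xp)
        sb = maxent.predict_values(model, Xb)
        bg_below = sb[Xb[:, 0] <= 0.8]
        assert maxent.auc_score(sp, bg_below) > 0.99
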