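import numpy as np
import pytest
from shapely.geometry import box

from phenoniche import env_effects, maxent, synth
from phenoniche.overlap import ModelProtocol, _mean_map
from phenoniche.raster import EnvStack, GridSpec, Raster


@pytest.fixture(scope="module")
def moisture_truth():
    """Melanistic niche loads on env_0 ('moisture'); non-melanistic does not."""
    cfg = synth.SyntheticConfig(
        grid_shape=(40, 40), n_layers=2, n_records=400,
        melanism_freq_by_biome=(0.2, 0.2, 0.2, 0.2),
        niche_coeffs={"melanistic": {"env_0": (3.0, 0.0)}},
        seed=40,
    )
    return synth.generate_truth(cfg)


@pytest.fixture(scope="module")
def pheno_maps(moisture_truth):
    truth = moisture_truth
    maps = {}
    for phen in ("melanistic", "non_melanistic"):
        recs = [r for r in truth.records if r.phenotype == phen]
        m, _ = maxent.run_replicates(
            recs, truth.env, n_replicates=3, seed=41, n_background=1000,
            features=maxent.FeatureSpec(classes=("linear", "quadratic")),
        )
        maps[phen] = m
    return maps


class TestDriverContrast:
    def test_directional_recovery(self, moisture_truth, pheno_maps):
        res = env_effects.driver_contrast(moisture_truth.records, moisture_truth.env,
                                          pheno_maps)
        row = next(c for c in res.contrasts if c.variable == "env_0")
        # melanistic model (alphabetically first -> side a) tracks moisture
        assert row.slope_a > row.slope_b
        assert row.r_a > row.r_b

    def test_identical_maps_nothing_significant(self, moisture_truth, pheno_maps):
        same = {"melanistic": pheno_maps["melanistic"],
                "non_melanistic": pheno_maps["melanistic"]}
        res = env_effects.driver_contrast(moisture_truth.records, moisture_truth.env,
                                          same)
        for c in res.contrasts:
            assert c.t_statistic == pytest.approx(0.0, abs=1e-9)
            assert not c.significant

    def test_bonferroni_arithmetic(self, moisture_truth, pheno_maps):
        scales = [env_effects.ScaleDefinition("full"),
                  env_effects.ScaleDefinition("west", box(0.0, 0.0, 1.0, 2.0))]
        # 12-variable stack is emulated by replicating layers
        env = moisture_truth.env
        stacked = EnvStack(env.grid, {f"v{i}": env.layers["env_0"] + i for i in range(12)})
        res = env_effects.driver_contrast(moisture_truth.records, stacked,
                                          pheno_maps, scales=scales, alpha=0.05)
        assert res.n_comparisons == 24
        assert res.adjusted_alpha == pytest.approx(0.05 / 24)

    def test_bonferroni_flags_monotone_in_alpha(self, moisture_truth, pheno_maps):
        res_small = env_effects.driver_contrast(moisture_truth.records,
                                                moisture_truth.env, pheno_maps,
                                                alpha=0.01)
        res_big = env_effects.driver_contrast(moisture_truth.records,
                                              moisture_truth.env, pheno_maps,
                                              alpha=0.10)
        for c_small, c_big in zip(res_small.contrasts, res_big.contrasts):
            if c_small.significant:
                assert c_big.significant

    def test_tiny_scale_skipped(self, moisture_truth, pheno_maps):
        scales = [env_effects.ScaleDefinition("nowhere", box(90.0, 90.0, 91.0, 91.0))]
        with pytest.warns(UserWarning, match="<3 records"):
            res = env_effects.driver_contrast(moisture_truth.records,
                                              moisture_truth.env, pheno_maps,
                                              scales=scales)
        assert res.contrasts == []

    def test_needs_two_maps(self, moisture_truth, pheno_maps):
        with pytest.raises(ValueError):
            env_effects.driver_contrast(moisture_truth.records, moisture_truth.env,
                                        {"only": pheno_maps["melanistic"]})


def _barrier_env(step, seed=0, shape=(40, 40), barrier_row=20, autocorr=1.0):
    cfg = synth.SyntheticConfig(grid_shape=shape, n_layers=1,
                                target_corr=np.eye(1), seed=seed,
                                autocorr_range=autocorr,
                                barrier_row=barrier_row, barrier_step=step)
    env = synth.generate_env_stack(cfg)
    biomes = Raster(cfg.grid, np.zeros(shape))
    barrier_lat = cfg.grid.cell_center(np.array([barrier_row]), np.array([0]))[1][0] + \
        cfg.cell_size / 2.0
    return env, biomes, float(barrier_lat)


class TestBarrierContrast:
    def test_step_detected_with_correct_sign(self):
        env, biomes, lat = _barrier_env(step=1.0, seed=1)
        res = env_effects.barrier_contrast(env, lat, biomes, 0, n_points=600, seed=2)
        assert res.p_value < 0.001
        assert res.mean_south > res.mean_north

    def test_odd_n_rejected(self):
        env, biomes, lat = _barrier_env(step=0.0, seed=3)
        with pytest.raises(ValueError, match="even"):
            env_effects.barrier_contrast(env, lat, biomes, 0, n_points=601)

    def test_insufficient_cells_named(self):
        env, biomes, lat = _barrier_env(step=0.0, seed=4, shape=(10, 10),
                                        barrier_row=5)
        with pytest.raises(ValueError, match="insufficient"):
            env_effects.barrier_contrast(env, lat, biomes, 0, n_points=600)

    def test_label_swap_flips_t_sign(self):
        env, biomes, lat = _barrier_env(step=0.6, seed=5)
        res = env_effects.barrier_contrast(env, lat, biomes, 0, n_points=400, seed=6)
        # flipping the raster north-south with the same seed swaps the sides
        flipped = EnvStack(env.grid, {n: v[::-1].copy() for n, v in env.layers.items()})
        res_f = env_effects.barrier_contrast(flipped, lat, biomes, 0, n_points=400,
                                             seed=6)
        assert np.sign(res.t_statistic) == -np.sign(res_f.t_statistic)

    def test_null_landscape_calibrated(self):
        # fresh white-noise landscape per run: the two sides have equal means
        # in expectation, so rejections should track alpha = 0.05
        from scipy.stats import binom

        rejections = 0
        n_runs = 100
        for s in range(n_runs):
            env, biomes, lat = _barrier_env(step=0.0, seed=1000 + s,
                                            shape=(60, 60), barrier_row=30,
                                            autocorr=0.0)
            res = env_effects.barrier_contrast(env, lat, biomes, 0,
                                               n_points=200, seed=s)
            rejections += res.p_value < 0.05
        lo, hi = binom.interval(0.999, n_runs, 0.05)
        assert lo <= rejections <= hi

    def test_unknown_variable(self):
        env, biomes, lat = _barrier_env(step=0.0, seed=8)
        with pytest.raises(ValueError, match="variable"):
            env_effects.barrier_contrast(env, lat, biomes, 0, variable="nope",
                                         n_points=10)


class TestLeaveRegionOut:
    @pytest.fixture(scope="class")
    def setup(self):
        cfg = synth.SyntheticConfig(
            grid_shape=(40, 40), n_layers=2, n_records=400,
            melanism_freq_by_biome=(0.5, 0.5, 0.5, 0.5),
            niche_coeffs={"melanistic": {"env_0": (3.0, 0.0)},
                          "non_melanistic": {"env_0": (3.0, 0.0)}},
            seed=50,
        )
        truth = synth.generate_truth(cfg)
        mel = [r for r in truth.records if r.phenotype == "melanistic"]
        protocol = ModelProtocol(n_background=800)

        def fit(records):
            rng = np.random.default_rng(99)
            X = maxent._extract(truth.env, maxent._points_array(records))
            X = X[np.isfinite(X).all(axis=1)]
            Xbg = maxent._extract(
                truth.env, maxent.sample_background(truth.env, 800, seed=99)
            )
            return _mean_map(X, Xbg, truth.env.layer_names, truth.env, protocol, rng)

        return truth, mel, fit

    def test_hotspot_robust(self, setup):
        truth, mel, fit = setup
        xmin, ymin, xmax, ymax = truth.env.grid.bounds
        # exclude a quarter of the landscape; the niche signal is shared
        region = box(xmin, ymin, xmin + (xmax - xmin) / 2, ymin + (ymax - ymin) / 2)
        out = env_effects.leave_region_out(mel, truth.env, region, fit)
        assert out["n_excluded"] > 0
        assert out["ratio_after_before"] >= 0.8

    def test_disjoint_region_identity(self, setup):
        truth, mel, fit = setup
        region = box(500.0, 500.0, 501.0, 501.0)
        with pytest.raises(ValueError, match="intersect"):
            with pytest.warns(UserWarning, match="no records"):
                env_effects.leave_region_out(mel, truth.env, region, fit)

    def test_disjoint_region_same_model(self, setup):
        truth, mel, fit = setup
        xmin, ymin, xmax, ymax = truth.env.grid.bounds
        # region inside the grid but holding no records: carve out a corner
        # cell block and drop any records inside it first
        region = box(xmin, ymin, xmin + 0.06, ymin + 0.06)
        clean = [r for r in mel if not (r.lon <= xmin + 0.06 and r.lat <= ymin + 0.06)]
        with pytest.warns(UserWarning, match="no records"):
            out = env_effects.leave_region_out(clean, truth.env, region, fit)
        np.testing.assert_array_equal(out["map_full"].values,
                                      out["map_excluded"].values)

    def test_region_covering_everything_rejected(self, setup):
        truth, mel, fit = setup
        region = box(*truth.env.grid.bounds)
        with pytest.raises(ValueError, match="no training records"):
            env_effects.leave_region_out(mel, truth.env, region, fit)
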