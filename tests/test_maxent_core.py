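import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from enmgap.geodata_io import ClimateStack, RasterGrid
from enmgap.maxent_core import (
    FeatureMapper,
    FeatureSpec,
    ModelConfig,
    SampleSizeError,
    TuningError,
    aicc,
    auc,
    build_features,
    fit_penalized,
    jackknife_importance,
    logistic_map,
    permutation_importance,
    replicate_fit,
    sample_background,
    tune,
)


def penalized_objective(fit, Xp, Xb):
    """The maximized objective, recomputed independently of the fit path."""
    eta_p = Xp @ fit.beta
    eta_b = Xb @ fit.beta
    return float(eta_p.mean() - logsumexp(eta_b) - fit.lambdas @ np.abs(fit.beta))


def oracle_maximum(Xp, Xb, lambdas):
    """Exhaustive numerical maximization via the split-variable (beta =
    b+ - b-) smooth reformulation solved with L-BFGS-B; independent of the
    FISTA path."""
    k = Xp.shape[1]
    pbar = Xp.mean(axis=0)

    def neg(z):
        beta = z[:k] - z[k:]
        return -(pbar @ beta) + logsumexp(Xb @ beta) + lambdas @ (z[:k] + z[k:])

    best = None
    for x0 in (np.zeros(2 * k), np.full(2 * k, 0.1)):
        res = minimize(neg, x0, method="L-BFGS-B",
                       bounds=[(0, None)] * 2 * k,
                       options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10})
        if best is None or res.fun < best:
            best = res.fun
    return -best


@pytest.fixture()
def toy_1d(rng):
    bg = pd.DataFrame({"x": rng.uniform(0.0, 1.0, 400)})
    pres = pd.DataFrame({"x": rng.uniform(0.7, 1.0, 40)})
    return pres, bg


class TestBuildFeatures:
    def test_linear_zero_at_background_mean(self, rng):
        bg = pd.DataFrame({"x": rng.normal(5.0, 2.0, 200)})
        point = pd.DataFrame({"x": [bg["x"].mean()]})
        X, mapper = build_features(point, bg, FeatureSpec(classes=("L",)), rescale=False)
        assert X[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_hinge_first_knot_is_minmax_rescale(self, rng):
        bg = pd.DataFrame({"x": rng.uniform(2.0, 10.0, 100)})
        mapper = FeatureMapper(bg, FeatureSpec(classes=("H",), hinge_knots=5))
        X = mapper.transform(bg)
        names = mapper.feature_names()
        i = names.index(f"x:hinge_fwd@{bg['x'].min():g}")
        expected = (bg["x"] - bg["x"].min()) / (bg["x"].max() - bg["x"].min())
        np.testing.assert_allclose(X[:, i], expected, atol=1e-12)

    def test_quadratic_sign_symmetric(self, rng):
        x = rng.normal(size=300)
        bg_pos = pd.DataFrame({"x": x})
        bg_neg = pd.DataFrame({"x": -x})
        Xp, _ = build_features(bg_pos, bg_pos, FeatureSpec(classes=("Q",)))
        Xn, _ = build_features(bg_neg, bg_neg, FeatureSpec(classes=("Q",)))
        np.testing.assert_allclose(np.sort(Xp[:, 0]), np.sort(Xn[:, 0]), atol=1e-12)

    def test_constant_variable_features_dropped(self, rng):
        bg = pd.DataFrame({"x": rng.normal(size=100), "c": np.full(100, 3.0)})
        mapper = FeatureMapper(bg, FeatureSpec(classes=("L", "Q", "H")))
        assert all("c" not in n for n in mapper.feature_names())
        assert mapper.dropped  # recorded

    def test_feature_range_unit_interval(self, rng):
        bg = pd.DataFrame({"x": rng.normal(size=500), "y": rng.uniform(size=500)})
        mapper = FeatureMapper(bg, FeatureSpec(classes=("L", "Q", "H")))
        X = mapper.transform(bg)
        assert X.min() >= -1e-12 and X.max() <= 1 + 1e-12


class TestFitPenalized:
    def test_no_signal_exact_half(self, rng):
        bg = pd.DataFrame({"x": rng.normal(size=300), "y": rng.uniform(size=300)})
        fit = fit_penalized(bg, bg, rm=1.0, spec=FeatureSpec(classes=("L", "Q")))
        assert np.all(fit.beta == 0.0)
        np.testing.assert_array_equal(fit.logistic(bg), np.full(len(bg), 0.5))

    def test_1d_signal_positive_beta_matches_grid_search(self, toy_1d):
        pres, bg = toy_1d
        fit = fit_penalized(pres, bg, rm=1.0, spec=FeatureSpec(classes=("L",)))
        assert fit.beta[0] > 0
        Xp = fit.mapper.transform(pres)
        Xb = fit.mapper.transform(bg)
        obj = penalized_objective(fit, Xp, Xb)
        grid = np.linspace(fit.beta[0] - 2.0, fit.beta[0] + 2.0, 40001)
        pbar = float(Xp.mean(axis=0)[0])
        vals = pbar * grid - logsumexp(np.outer(Xb[:, 0], grid), axis=0) - fit.lambdas[0] * np.abs(grid)
        assert obj >= vals.max() - 1e-6

    def test_huge_rm_zeroes_out(self, toy_1d):
        pres, bg = toy_1d
        fit = fit_penalized(pres, bg, rm=1e3, spec=FeatureSpec(classes=("L", "Q")))
        assert np.all(fit.beta == 0.0)

    def test_penalty_monotonicity(self, rng):
        bg = pd.DataFrame({
            "x": rng.normal(size=300), "y": rng.normal(size=300), "z": rng.normal(size=300)
        })
        pres = bg.iloc[(bg["x"] + 0.5 * bg["y"]).nlargest(40).index]
        counts = []
        for rm in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0):
            fit = fit_penalized(pres, bg, rm=rm, spec=FeatureSpec(classes=("L", "Q")))
            counts.append(fit.n_nonzero)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("classes,cols", [
        (("L",), ["a", "b"]),        # 2 features
        (("L", "Q"), ["a"]),         # 2 features
        (("L",), ["a", "b", "c"]),   # 3 features
    ])
    def test_oracle_equivalence_small_instances(self, seed, classes, cols):
        rng = np.random.default_rng(seed)
        bg = pd.DataFrame({
            "a": rng.normal(size=150), "b": rng.uniform(size=150),
            "c": rng.normal(size=150),
        })[cols]
        weights = np.exp(bg["a"])
        pres = bg.sample(n=30, weights=weights, random_state=seed, replace=True)
        fit = fit_penalized(pres, bg, rm=1.0, spec=FeatureSpec(classes=classes))
        Xp = fit.mapper.transform(pres)
        Xb = fit.mapper.transform(bg)
        assert Xp.shape[1] <= 3
        fitted = penalized_objective(fit, Xp, Xb)
        oracle = oracle_maximum(Xp, Xb, fit.lambdas)
        assert fitted == pytest.approx(oracle, abs=1e-5)

    def test_too_few_presences(self, rng):
        bg = pd.DataFrame({"x": rng.normal(size=50)})
        with pytest.raises(SampleSizeError):
            fit_penalized(bg.head(1), bg)

    def test_entropy_bounds(self, toy_1d):
        pres, bg = toy_1d
        fit = fit_penalized(pres, bg, rm=1.0, spec=FeatureSpec(classes=("L",)))
        assert 0.0 <= fit.entropy <= np.log(len(bg)) + 1e-9


class TestLogisticMap:
    @pytest.fixture()
    def mini_world(self, rng):
        grid = RasterGrid(n_rows=8, n_cols=10, x_origin=0, y_origin=0.8, resolution=0.1)
        x = rng.normal(size=(8, 10))
        x[0, 0] = np.nan
        return ClimateStack(grid=grid, layers={"x": x})

    def test_identity_transfer_matches_training(self, mini_world, rng):
        valid = mini_world.valid_mask()
        bg = mini_world.env_table(valid)
        pres = bg.sample(10, random_state=1)
        fit = fit_penalized(pres, bg, rm=1.0, spec=FeatureSpec(classes=("L",)))
        smap = logistic_map(fit, mini_world)
        np.testing.assert_allclose(smap[valid], fit.logistic(bg), atol=1e-12)
        assert np.isnan(smap[0, 0])

    def test_clamping_caps_extrapolation(self, mini_world, rng):
        valid = mini_world.valid_mask()
        bg = mini_world.env_table(valid)
        pres = bg.nlargest(10, "x")
        fit = fit_penalized(pres, bg, rm=1.0, spec=FeatureSpec(classes=("L",)))
        hi = pd.DataFrame({"x": [bg["x"].max() + 100.0]})
        at_max = pd.DataFrame({"x": [bg["x"].max()]})
        assert fit.logistic(hi)[0] == pytest.approx(fit.logistic(at_max)[0], abs=1e-12)
        # unclamped prediction differs
        assert fit.logistic(hi, clamp=False)[0] != pytest.approx(fit.logistic(at_max)[0], abs=1e-6)

    def test_uniform_model_is_half(self, mini_world):
        valid = mini_world.valid_mask()
        bg = mini_world.env_table(valid)
        fit = fit_penalized(bg, bg, rm=1.0, spec=FeatureSpec(classes=("L",)))
        smap = logistic_map(fit, mini_world)
        np.testing.assert_array_equal(smap[valid], np.full(int(valid.sum()), 0.5))

    def test_missing_variable_error(self, mini_world, rng):
        bg = pd.DataFrame({"y": rng.normal(size=50)})
        fit = fit_penalized(bg.head(10), bg, spec=FeatureSpec(classes=("L",)))
        with pytest.raises(KeyError):
            logistic_map(fit, mini_world)


class TestAicc:
    def test_hand_arithmetic(self):
        assert aicc(2, -5.0, 10) == pytest.approx(4 + 10 + 12 / 7)
        assert aicc(2, -5.0, 10) == pytest.approx(15.7142857, abs=1e-6)

    def test_guard_infinite(self):
        assert aicc(9, -5.0, 10) == np.inf
        assert aicc(10, -5.0, 10) == np.inf

    def test_monotone_in_k(self):
        assert aicc(2, -5.0, 30) < aicc(3, -5.0, 30)


class TestTune:
    def test_single_candidate_selected(self, toy_1d):
        pres, bg = toy_1d
        table = tune(pres, bg, fc_grid=["L"], rm_grid=[1.0])
        assert len(table) == 1
        assert table["selected"].sum() == 1

    def test_row_format(self, toy_1d):
        pres, bg = toy_1d
        table = tune(pres, bg, fc_grid=["L", "LQ"], rm_grid=[1.0, 2.5])
        assert set(table["fc"]) == {"L", "LQ"}
        assert set(table["rm"]) == {1.0, 2.5}
        sel = table[table["selected"]]
        assert len(sel) == 1
        assert np.isfinite(sel["aicc"]).all()

    def test_selects_min_aicc(self, toy_1d):
        pres, bg = toy_1d
        table = tune(pres, bg, fc_grid=["L", "LQ"], rm_grid=[1.0, 2.0])
        finite = table[np.isfinite(table["aicc"])]
        assert table.loc[table["selected"], "aicc"].iloc[0] == finite["aicc"].min()

    def test_lq_signal_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed + 100)
            bg = pd.DataFrame({"x": rng.normal(size=400)})
            eta = 1.5 * bg["x"] - 1.2 * bg["x"] ** 2
            pres = bg.sample(n=60, weights=np.exp(eta), random_state=seed, replace=True)
            table = tune(pres, bg, fc_grid=["L", "LQ"], rm_grid=[1.0])
            if table.loc[table["selected"], "fc"].iloc[0] == "LQ":
                hits += 1
        assert hits >= 9

    def test_empty_grid_error(self, toy_1d):
        pres, bg = toy_1d
        with pytest.raises(ValueError):
            tune(pres, bg, fc_grid=[], rm_grid=[1.0])


class TestReplicates:
    @pytest.fixture()
    def mini_setup(self, rng):
        grid = RasterGrid(n_rows=10, n_cols=10, x_origin=0, y_origin=1.0, resolution=0.1)
        x = rng.normal(size=(10, 10))
        stack = ClimateStack(grid=grid, layers={"x": x})
        bg = stack.env_table(stack.valid_mask())
        pres = bg.nlargest(20, "x").reset_index(drop=True)
        return stack, bg, pres

    def config(self, n_reps=4, seed=0):
        return ModelConfig(fc=FeatureSpec(classes=("L",)), rm=1.0,
                           n_replicates=n_reps, seed=seed)

    def test_mean_within_replicate_envelope(self, mini_setup):
        stack, bg, pres = mini_setup
        reps, mean_map = replicate_fit(pres, bg, stack, self.config())
        stackmaps = np.stack([r.suitability for r in reps])
        valid = np.isfinite(mean_map)
        assert (mean_map[valid] >= np.min(stackmaps, axis=0)[valid] - 1e-12).all()
        assert (mean_map[valid] <= np.max(stackmaps, axis=0)[valid] + 1e-12).all()

    def test_seed_determinism(self, mini_setup):
        stack, bg, pres = mini_setup
        _, m1 = replicate_fit(pres, bg, stack, self.config(seed=9))
        _, m2 = replicate_fit(pres, bg, stack, self.config(seed=9))
        np.testing.assert_array_equal(m1, m2)

    def test_degenerate_single_profile(self, mini_setup):
        stack, bg, _ = mini_setup
        pres = pd.DataFrame({"x": np.full(6, float(bg["x"].iloc[0]))})
        reps, _ = replicate_fit(pres, bg, stack, self.config())
        maps = [r.suitability for r in reps]
        for m in maps[1:]:
            np.testing.assert_allclose(m, maps[0], atol=1e-9, equal_nan=True)

    def test_sample_size_guard(self, mini_setup):
        stack, bg, pres = mini_setup
        with pytest.raises(SampleSizeError):
            replicate_fit(pres.head(4), bg, stack, self.config())


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_identical_distributions(self):
        assert auc([0.5, 0.7], [0.5, 0.7]) == 0.5

    def test_enumerated_pairs(self):
        # pairs: (.9,.7) win, (.9,.85) win, (.8,.7) win, (.8,.85) loss -> 3/4
        assert auc([0.9, 0.8], [0.7, 0.85]) == 0.75

    def test_ties_count_half(self):
        assert auc([0.5], [0.5]) == 0.5


class TestImportance:
    def test_single_variable_only_with_matches(self, rng):
        bg = pd.DataFrame({"x": rng.normal(size=300)})
        pres = bg.nlargest(40, "x").reset_index(drop=True)
        table = jackknife_importance(pres, bg, FeatureSpec(classes=("L",)), rm=1.0, seed=0)
        assert len(table) == 1
        assert np.isnan(table["auc_without"]).all()
        assert 0.0 <= table["auc_only_with"].iloc[0] <= 1.0

    def test_noise_variable_ranked_low(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            bg = pd.DataFrame({"sig": rng.normal(size=300), "noise": rng.normal(size=300)})
            pres = bg.nlargest(40, "sig").reset_index(drop=True)
            table = jackknife_importance(
                pres, bg, FeatureSpec(classes=("L",)), rm=1.0, seed=seed
            ).set_index("variable")
            if table.loc["noise", "auc_without"] >= table.loc["noise", "auc_only_with"]:
                wins += 1
        assert wins >= 8

    def test_aucs_in_unit_interval(self, rng):
        bg = pd.DataFrame({"a": rng.normal(size=200), "b": rng.uniform(size=200)})
        pres = bg.nlargest(30, "a").reset_index(drop=True)
        table = jackknife_importance(pres, bg, FeatureSpec(classes=("L",)), rm=1.0)
        vals = table[["auc_without", "auc_only_with"]].to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_permutation_sums_to_100(self, rng):
        bg = pd.DataFrame({"a": rng.normal(size=300), "b": rng.normal(size=300)})
        pres = bg.nlargest(40, "a").reset_index(drop=True)
        fit = fit_penalized(pres, bg, spec=FeatureSpec(classes=("L",)))
        imp = permutation_importance(fit, pres, bg, seed=0)
        assert imp.sum() == pytest.approx(100.0, abs=0.1)
        assert (imp >= 0).all()

    def test_single_signal_near_100(self, rng):
        bg = pd.DataFrame({"a": rng.normal(size=300), "b": rng.normal(size=300)})
        pres = bg.nlargest(40, "a").reset_index(drop=True)
        fit = fit_penalized(pres, bg, spec=FeatureSpec(classes=("L",)))
        imp = permutation_importance(fit, pres, bg, seed=0)
        assert imp["a"] > 90.0

    def test_irrelevant_variable_small(self):
        meds = []
        for seed in range(10):
            rng = np.random.default_rng(seed + 50)
            bg = pd.DataFrame({"a": rng.normal(size=300), "junk": rng.normal(size=300)})
            pres = bg.nlargest(40, "a").reset_index(drop=True)
            fit = fit_penalized(pres, bg, spec=FeatureSpec(classes=("L",)))
            meds.append(permutation_importance(fit, pres, bg, seed=seed)["junk"])
        assert np.median(meds) <= 5.0


class TestSampleBackground:
    def test_uses_all_when_few(self, rng):
        grid = RasterGrid(n_rows=5, n_cols=5, x_origin=0, y_origin=0.5, resolution=0.1)
        stack = ClimateStack(grid=grid, layers={"x": rng.normal(size=(5, 5))})
        bg = sample_background(stack, np.ones((5, 5), dtype=bool), n=100, seed=0)
        assert len(bg) == 25

    def test_seeded_subset(self, rng):
        grid = RasterGrid(n_rows=20, n_cols=20, x_origin=0, y_origin=2.0, resolution=0.1)
        stack = ClimateStack(grid=grid, layers={"x": rng.normal(size=(20, 20))})
        a = sample_background(stack, np.ones((20, 20), dtype=bool), n=50, seed=1)
        b = sample_background(stack, np.ones((20, 20), dtype=bool), n=50, seed=1)
        assert a.equals(b) and len(a) == 50
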