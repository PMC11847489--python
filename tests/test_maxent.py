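import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import spearmanr

from nichecast.maxent import (FeatureSpec, MaxEntModel, ReplicateSet, auc,
                              build_feature_map, feature_penalties, fit,
                              jackknife_gains, percent_contribution,
                              permutation_importance, replicate_fit,
                              response_curve, sample_background, training_auc)


def toy_env(seed=0, n=400, k=2):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({f"v{i}": rng.normal(size=n) for i in range(k)})


class TestFeatureMap:
    def test_linear_scaling_endpoints(self):
        bg = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        fm = build_feature_map(bg, "l")
        F = fm.design_matrix(pd.DataFrame({"x": [2.0, 6.0, 4.0]}))
        assert F[:, 0] == pytest.approx([0.0, 1.0, 0.5])

    def test_quadratic_of_midpoint(self):
        bg = pd.DataFrame({"x": [0.0, 1.0]})
        fm = build_feature_map(bg, "q")
        F = fm.design_matrix(pd.DataFrame({"x": [0.5]}))
        quad = [j for j, f in enumerate(fm.features) if f.kind == "quadratic"]
        assert F[0, quad[0]] == pytest.approx(0.25)

    def test_forward_hinge_zero_at_knot(self):
        bg = pd.DataFrame({"x": np.linspace(0, 1, 101)})
        fm = build_feature_map(bg, "h", n_knots=10)
        fwd = [(j, f) for j, f in enumerate(fm.features) if f.kind == "hinge_fwd"]
        j, f = fwd[3]
        F = fm.design_matrix(pd.DataFrame({"x": [f.knot]}))
        assert F[0, j] == 0.0

    def test_all_features_in_unit_interval_on_calibration_data(self):
        bg = toy_env(5, 300, 3)
        fm = build_feature_map(bg, "lqph", n_knots=20)
        F = fm.design_matrix(bg)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_constant_variable_flagged_and_linear_zero(self):
        bg = pd.DataFrame({"c": np.ones(50), "x": np.linspace(0, 1, 50)})
        fm = build_feature_map(bg, "lqh")
        assert fm.constant_vars == ["c"]
        F = fm.design_matrix(bg)
        const_j = [j for j, f in enumerate(fm.features)
                   if f.kind == "linear" and f.variables == ("c",)]
        assert np.all(F[:, const_j[0]] == 0.0)
        assert all("c" not in f.variables for f in fm.features if f.kind != "linear")


class TestFit:
    def test_huge_rm_gives_uniform_model(self):
        bg = toy_env(1)
        pres = bg.head(30)
        m = fit(pres, bg, FeatureSpec("lqh", rm=1e6))
        assert np.all(m.lambdas == 0.0)
        q = m.raw(bg)
        assert q == pytest.approx(np.full(len(bg), 1 / len(bg)))
        assert m.cloglog(bg) == pytest.approx(np.full(len(bg), 1 - np.exp(-1)))

    def test_informative_linear_coefficient_positive(self):
        rng = np.random.default_rng(2)
        bg = pd.DataFrame({"x": rng.normal(size=600), "z": rng.normal(size=600)})
        # presences favour high x (truth increases with x)
        w = np.exp(1.5 * bg["x"])
        idx = rng.choice(600, size=80, p=w / w.sum())
        m = fit(bg.iloc[idx].reset_index(drop=True), bg, FeatureSpec("l", 1.0))
        assert m.lambdas[0] > 0

    def test_raw_distribution_normalized(self):
        bg = toy_env(4)
        m = fit(bg.head(40), bg, FeatureSpec("lq", 0.5))
        assert m.raw(bg).sum() == pytest.approx(1.0, abs=1e-8)
        assert 0 <= m.entropy <= np.log(len(bg)) + 1e-9

    def test_cloglog_monotone_in_raw(self):
        bg = toy_env(6)
        m = fit(bg.head(50), bg, FeatureSpec("lqh", 1.0))
        q = m.raw(bg)
        c = m.cloglog(bg)
        order = np.argsort(q)
        assert np.all(np.diff(c[order]) >= -1e-15)
        assert c.min() >= 0 and c.max() <= 1

    def test_non_finite_input_named_in_error(self):
        bg = toy_env(1)
        pres = bg.head(10).copy()
        pres.loc[3, "v0"] = np.nan
        with pytest.raises(ValueError, match="v0"):
            fit(pres, bg, FeatureSpec("l"))

    def test_matches_proximal_gradient_oracle_on_linear_toy(self):
        """Independent first-order solver agrees with the packaged optimizer."""
        rng = np.random.default_rng(8)
        bg = pd.DataFrame({"a": rng.normal(size=150), "b": rng.normal(size=150)})
        w = np.exp(0.8 * bg["a"] - 0.5 * bg["b"])
        pres = bg.iloc[rng.choice(150, 40, p=w / w.sum())].reset_index(drop=True)
        m = fit(pres, bg, FeatureSpec("l", 1.0), tol=1e-9, max_iter=2000)
        fm = m.feature_map
        Fp, Fb = fm.design_matrix(pres), fm.design_matrix(bg)
        beta = feature_penalties(fm, Fp, Fb, 1.0)
        lam = np.zeros(Fp.shape[1])
        lr = 0.5
        for _ in range(40000):
            p = np.exp(Fb @ lam - logsumexp(Fb @ lam))
            grad = -Fp.mean(axis=0) + p @ Fb
            step = lam - lr * grad
            lam = np.sign(step) * np.maximum(np.abs(step) - lr * beta, 0.0)
        assert m.lambdas == pytest.approx(lam, abs=1e-4)

    def test_regularization_path_shrinks_with_rm(self):
        bg = toy_env(9, 300)
        rng = np.random.default_rng(10)
        w = np.exp(bg["v0"])
        pres = bg.iloc[rng.choice(300, 60, p=w / w.sum())].reset_index(drop=True)
        norms = [np.abs(fit(pres, bg, FeatureSpec("lq", rm)).lambdas).sum()
                 for rm in (0.5, 1, 2, 4)]
        assert all(b <= a + 1e-6 for a, b in zip(norms, norms[1:]))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_identical_multisets(self):
        assert auc([0.3, 0.5, 0.7], [0.3, 0.5, 0.7]) == 0.5

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            sp = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=5)
            sb = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=5)
            brute = np.mean([(a > b) + 0.5 * (a == b) for a in sp for b in sb])
            assert auc(sp, sb) == pytest.approx(brute, abs=1e-15)


class TestImportance:
    def test_single_variable_contribution_is_100(self):
        bg = toy_env(14, 200, 1)
        m = fit(bg.head(30), bg, FeatureSpec("l"))
        assert percent_contribution(m, bg.head(30))["v0"] == 100.0

    def test_measures_nonnegative_and_sum_100(self, small_scenario):
        m = small_scenario["model"]
        pres = small_scenario["presence_env"]
        pc = percent_contribution(m, pres, max_iter=200)
        pi = permutation_importance(m, pres, seed=0)
        for s in (pc, pi):
            assert (s >= 0).all()
            assert s.sum() == pytest.approx(100.0, abs=1e-6)

    def test_driving_variable_dominates_noise(self, small_scenario):
        pc = percent_contribution(small_scenario["model"],
                                  small_scenario["presence_env"], max_iter=200)
        assert pc["var1"] > 50.0
        assert max(pc["var3"], pc["var4"], pc["var5"]) < 5.0


class TestJackknife:
    def test_informative_variable_has_highest_single_gain(self, small_scenario):
        jk = jackknife_gains(small_scenario["presence_env"],
                             small_scenario["background_env"],
                             FeatureSpec("lqh", 1.0), max_iter=200)
        assert jk.loc["var1", "gain_only"] > jk.loc["var3", "gain_only"]

    def test_gain_without_never_exceeds_full_model(self, small_scenario):
        m = small_scenario["model"]
        jk = jackknife_gains(small_scenario["presence_env"],
                             small_scenario["background_env"],
                             FeatureSpec("lqh", 1.0), max_iter=200)
        assert (jk["gain_without"] <= m.reg_gain + 1e-6).all()

    def test_twin_variables_leave_gain_unchanged(self):
        rng = np.random.default_rng(20)
        bg = pd.DataFrame({"t1": rng.normal(size=300)})
        bg["t2"] = bg["t1"]
        w = np.exp(bg["t1"])
        pres = bg.iloc[rng.choice(300, 60, p=w / w.sum())].reset_index(drop=True)
        full = fit(pres, bg, FeatureSpec("l", 1.0))
        jk = jackknife_gains(pres, bg, FeatureSpec("l", 1.0))
        for v in ("t1", "t2"):
            drop = full.reg_gain - jk.loc[v, "gain_without"]
            assert drop <= 0.01 * abs(full.reg_gain) + 1e-9


class TestResponseCurve:
    def test_uniform_model_flat_curve(self):
        bg = toy_env(16)
        m = fit(bg.head(30), bg, FeatureSpec("l", 1e6))
        curve = response_curve(m, "v0")
        assert curve["mean"].std() == pytest.approx(0.0, abs=1e-12)
        assert (curve["sd"] == 0).all()

    def test_unimodal_truth_argmax_recovered(self, small_scenario):
        truth = small_scenario["truth"]
        m = small_scenario["model"]
        curve = response_curve(m, "var2", n_points=200)
        argmax = curve.loc[curve["mean"].idxmax(), "value"]
        rng_width = curve["value"].max() - curve["value"].min()
        assert abs(argmax - truth.optimum_v2) <= 0.10 * rng_width

    def test_absent_variable_rejected(self, small_scenario):
        with pytest.raises(KeyError):
            response_curve(small_scenario["model"], "nope")


class TestReplicates:
    def test_single_replicate_zero_sd(self):
        bg = toy_env(17)
        reps = replicate_fit(bg.head(30), bg, FeatureSpec("l"), n=1, seed=0)
        mean, sd = reps.cloglog_stats(bg)
        assert np.all(sd == 0.0)
        assert mean == pytest.approx(reps.models[0].cloglog(bg))

    def test_fixed_seed_bit_identical(self):
        bg = toy_env(18)
        a = replicate_fit(bg.head(40), bg, FeatureSpec("lq"), n=3, seed=7)
        b = replicate_fit(bg.head(40), bg, FeatureSpec("lq"), n=3, seed=7)
        for ma, mb in zip(a.models, b.models):
            assert np.array_equal(ma.lambdas, mb.lambdas)

    def test_mean_raster_tracks_truth_as_well_as_single_fit(self, small_scenario):
        stack = small_scenario["stack"]
        rows, cols = stack.data_cells()
        env = stack.env_table(rows, cols)
        truth_vals = small_scenario["truth_raster"].values[rows, cols]
        single = spearmanr(small_scenario["model"].cloglog(env), truth_vals).statistic
        reps = replicate_fit(small_scenario["presence_env"],
                             small_scenario["background_env"],
                             FeatureSpec("lqh", 1.0), n=3, seed=2, max_iter=200)
        mean, _ = reps.cloglog_stats(env)
        assert spearmanr(mean, truth_vals).statistic >= single - 0.02


class TestBackgroundSampling:
    def test_capped_and_seeded(self, small_scenario):
        stack = small_scenario["stack"]
        env, r, c = sample_background(stack, 100, seed=1)
        env2, r2, c2 = sample_background(stack, 100, seed=1)
        assert len(env) == 100
        assert np.array_equal(r, r2) and np.array_equal(c, c2)
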