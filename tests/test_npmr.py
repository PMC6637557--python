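"""Kernel regression core: weights, LOO fits, statistics, search, resampling."""

import numpy as np
import pandas as pd
import pytest

import _oracles as orc
import npmrtrack as nt
from npmrtrack.npmr import ModelSpec, NPMREngine


class TestKernelWeight:
    def test_identical_rows_weight_one(self):
        spec = ModelSpec.of({"x": 1.0, "z": 2.0})
        row = {"x": 3.0, "z": -1.0}
        assert nt.kernel_weight(row, dict(row), spec) == pytest.approx(1.0)

    def test_one_sigma_apart(self):
        spec = ModelSpec.of({"x": 2.0})
        w = nt.kernel_weight({"x": 0.0}, {"x": 2.0}, spec)
        assert w == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_multiplicative_combination(self):
        spec = ModelSpec.of({"x": 1.0, "z": 1.0})
        w = nt.kernel_weight({"x": 0.0, "z": 0.0}, {"x": 1.0, "z": 1.0}, spec)
        assert w == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_categorical_indicator(self):
        spec = ModelSpec(tolerances=(("x", 1.0),), categorical=("id",))
        same = nt.kernel_weight({"x": 0, "id": "a"}, {"x": 0, "id": "a"}, spec)
        diff = nt.kernel_weight({"x": 0, "id": "a"}, {"x": 0, "id": "b"}, spec)
        assert same == 1.0 and diff == 0.0

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec.of({"x": 0.0})


class TestLooEstimate:
    def test_unanimous_neighbors(self):
        t = pd.DataFrame({"y": [1.0, 1, 1, 1, 0], "x": [0.0, 0.1, 0.2, 0.3, 50.0]})
        est, ns = nt.loo_estimate(0, t, ModelSpec.of({"x": 0.2}))
        assert est == pytest.approx(1.0)

    def test_infinite_tolerance_gives_global_loo_mean(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"y": rng.integers(0, 2, 12).astype(float),
                          "x": rng.normal(size=12)})
        i = 4
        est, ns = nt.loo_estimate(i, t, ModelSpec.of({"x": 1e9}))
        others = np.delete(t["y"].to_numpy(), i)
        assert ns == pytest.approx(11.0, rel=1e-6)
        assert est == pytest.approx(others.mean(), rel=1e-6)

    def test_matches_bruteforce_on_toy(self, small_table):
        spec = ModelSpec.of({"x": 2.0})
        rows, est_o, ns_o, _ = orc.loo_table(small_table, {"x": 2.0})
        for k, i in enumerate(rows[:10]):
            est, ns = nt.loo_estimate(i, small_table, spec)
            assert ns == pytest.approx(ns_o[k], abs=1e-10)
            if np.isfinite(est_o[k]):
                assert est == pytest.approx(est_o[k], abs=1e-12)


class TestFitStatistics:
    def test_naive_model_is_exact_zero(self):
        y = np.array([1.0, 0, 1, 1, 0, 1])
        p_bar = y.mean()
        assert nt.log_likelihood_ratio(y, np.full(6, p_bar)) == pytest.approx(
            0.0, abs=1e-14)

    def test_logB_term_by_term_oracle(self):
        y = np.array([1.0, 0, 1, 1, 0, 1])
        yhat = np.array([0.9, 0.2, 0.7, 0.99, 0.4, 0.6])
        assert nt.log_likelihood_ratio(y, yhat) == pytest.approx(
            orc.logB(y, yhat), abs=1e-12)

    def test_b_ave_published_arithmetic(self):
        # logB 26.14 over 1444 sample units -> 1.04 per unit
        assert round(nt.b_ave(26.14, 1444), 2) == 1.04

    def test_chi2_and_xr2_relations(self, small_table):
        f = nt.fit(small_table, ModelSpec.of({"x": 1.0}))
        assert f.chi2 == pytest.approx(2 * np.log(10) * f.logB, rel=1e-12)
        assert np.isfinite(f.xr2) and f.xr2 <= 1.0
        assert 0 <= np.nanmin(f.estimates) and np.nanmax(f.estimates) <= 1.0

    def test_fit_matches_bruteforce(self, small_table):
        tol = {"x": 0.8, "w": 0.5}
        f = nt.fit(small_table, ModelSpec.of(tol))
        rows, est_o, ns_o, n_min_o = orc.loo_table(small_table, tol)
        assert f.n_min == pytest.approx(n_min_o, abs=1e-10)
        np.testing.assert_allclose(f.nstar, ns_o, atol=1e-10)
        np.testing.assert_allclose(f.estimates, est_o, atol=1e-10)
        ok = np.isfinite(est_o)
        y = small_table["y"].to_numpy()[rows]
        assert f.logB == pytest.approx(orc.logB(y[ok], est_o[ok]), abs=1e-10)

    def test_row_permutation_invariance(self, small_table):
        spec = ModelSpec.of({"x": 0.8})
        f1 = nt.fit(small_table, spec)
        shuffled = small_table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        f2 = nt.fit(shuffled, spec)
        for attr in ("logB", "n_ave", "n_min", "xr2", "su"):
            assert getattr(f1, attr) == pytest.approx(getattr(f2, attr), abs=1e-9)

    def test_ratio_precondition_enforced(self):
        t = pd.DataFrame({"y": [0.0, 1] * 4, "x": np.arange(8.0)})
        with pytest.raises(ValueError):
            nt.fit(t, ModelSpec.of({"x": 1.0}))


class TestTolerancePct:
    @pytest.mark.parametrize("sigma,rng,expected", [
        (0.30, 7.55, 4.0),        # chlorophyll
        (571.98, 1972.30, 29.0),  # depth
        (0.26, 8.60, 3.0),        # longitude
        (5.0, 5.0, 100.0),
    ])
    def test_published_percentages(self, sigma, rng, expected):
        assert nt.tolerance_pct(sigma, rng) == expected

    def test_rejects_nonpositive_range(self):
        with pytest.raises(ValueError):
            nt.tolerance_pct(1.0, 0.0)


class TestSensitivity:
    def test_inert_predictor_has_zero_sensitivity(self, small_table):
        # enormous tolerance: the estimate ignores the predictor entirely
        f = nt.fit(small_table, ModelSpec.of({"x": 0.8, "w": 1e9}))
        assert nt.sensitivity(f, small_table, "w") == pytest.approx(0.0, abs=1e-9)

    def test_proportional_interpretation(self):
        # a sensitivity of 0.71 means a 20% predictor change moves the
        # response by 14% of its range
        assert round(0.71 * 20) == 14

    def test_matches_bruteforce(self, small_table):
        tol = {"x": 1.0}
        f = nt.fit(small_table, ModelSpec.of(tol))
        q = nt.sensitivity(f, small_table, "x")
        q_o = orc.sensitivity_q(small_table, tol, "x", f.ranges["x"],
                                f.estimates, f.n_min)
        assert q == pytest.approx(q_o, abs=1e-10)

    def test_unknown_predictor_rejected(self, small_table):
        f = nt.fit(small_table, ModelSpec.of({"x": 1.0}))
        with pytest.raises(ValueError):
            nt.sensitivity(f, small_table, "nope")


class TestPredict:
    def test_identical_row_gets_inclusive_weighted_mean(self, small_table):
        f = nt.fit(small_table, ModelSpec.of({"x": 0.8}))
        new = small_table.head(5)
        out = nt.predict(f, small_table, new)
        est_o, ns_o, _ = orc.predict_rows({"x": 0.8}, small_table, new)
        np.testing.assert_allclose(out.estimates, est_o, atol=1e-12)
        np.testing.assert_allclose(out.nstar, ns_o, atol=1e-10)

    def test_sparse_new_rows_shrink_neighborhoods(self, small_table):
        f = nt.fit(small_table, ModelSpec.of({"x": 0.4}))
        # new rows at the fringe of predictor space see fewer neighbors
        fringe = pd.DataFrame({"y": [1.0] * 5,
                               "x": small_table["x"].max() + np.linspace(1, 3, 5)})
        out = nt.predict(f, small_table, fringe)
        assert out.n_ave < f.n_ave

    def test_missing_predictor_column_rejected(self, small_table):
        f = nt.fit(small_table, ModelSpec.of({"x": 0.8}))
        with pytest.raises(ValueError):
            nt.predict(f, small_table, pd.DataFrame({"y": [1.0]}))


class TestFreeSearch:
    def test_single_candidate_equals_grid_scan(self, logistic_table):
        cfg = nt.NPMRConfig()
        eng = NPMREngine(logistic_table, config=cfg)
        res = eng.free_search(["x"])
        rng = eng.predictor_range("x")
        best = max((eng.fit(ModelSpec.of({"x": f * rng})).logB
                    for f in cfg.tolerance_grid))
        assert res.fit.logB == pytest.approx(best, abs=1e-10)

    def test_informative_predictor_selected_over_noise(self, logistic_table):
        res = nt.free_search(logistic_table, ["z", "x"])
        assert "x" in res.fit.spec.predictors
        assert "z" not in res.fit.spec.predictors

    def test_duplicate_candidates_never_both_kept(self, logistic_table):
        t = logistic_table.assign(x_dup=logistic_table["x"])
        res = nt.free_search(t, ["x", "x_dup"])
        assert not {"x", "x_dup"} <= set(res.fit.spec.predictors)

    def test_categorical_covariate_offered(self, logistic_table):
        res = nt.free_search(logistic_table, ["x", "whale"],
                             categorical=("whale",))
        assert "x" in res.fit.spec.predictors  # signal survives the covariate

    def test_no_usable_candidate_raises(self):
        t = pd.DataFrame({"y": [0.0, 1] * 10, "x": [np.nan] * 20})
        with pytest.raises(ValueError):
            nt.free_search(t, ["x"])


class TestTune:
    def test_never_decreases_logB(self, logistic_table):
        res = nt.free_search(logistic_table, ["x"])
        tuned = nt.tune(res.fit, logistic_table)
        assert tuned.logB >= res.fit.logB - 1e-12

    def test_matches_exhaustive_fine_grid(self, small_table):
        eng = NPMREngine(small_table)
        coarse = eng.free_search(["x"]).fit
        tuned = eng.tune(coarse)
        rng = eng.predictor_range("x")
        sigma0 = dict(coarse.spec.tolerances)["x"]
        fine = np.arange(max(sigma0 - 0.05 * rng, 1e-6),
                         sigma0 + 0.0501 * rng, 0.01 * rng)
        vals = []
        for s in fine:
            try:
                vals.append(eng.fit(ModelSpec.of({"x": s})).logB)
            except ValueError:
                pass  # a very sharp kernel can empty every neighborhood
        best = max(vals)
        assert tuned.logB >= best - 1e-9
        sigma_t = dict(tuned.spec.tolerances)["x"]
        assert abs(sigma_t - sigma0) <= 0.1 * rng + 1e-9


class TestResampling:
    def test_bootstrap_deterministic_and_positive_on_separable(self):
        rng = np.random.default_rng(3)
        n = 40
        x = np.concatenate([rng.normal(-3, 0.3, n // 2), rng.normal(3, 0.3, n // 2)])
        y = (x > 0).astype(float)
        t = pd.DataFrame({"y": y, "x": x})
        spec = ModelSpec.of({"x": 1.0})
        cfg = nt.NPMRConfig(seed=5, n_boot=30)
        b1 = nt.bootstrap_logB(t, spec, cfg)
        b2 = nt.bootstrap_logB(t, spec, cfg)
        assert b1["p5"] == b2["p5"] and b1["p95"] == b2["p95"]
        vals = np.asarray(b1["logB"])
        assert np.all(vals[np.isfinite(vals)] > 0)

    def test_randomization_pvalue_floor(self, logistic_table):
        res = nt.free_search(logistic_table, ["x"])
        cfg = nt.NPMRConfig(seed=1, n_randomizations=19)
        out = nt.randomization_test(logistic_table, ["x"], res.fit.logB, cfg)
        assert out["p_value"] >= 1.0 / 20.0
        if out["n_exceed"] == 0:
            assert out["p_value"] == pytest.approx(1 / 20)

    def test_bootstrap_interval_covers_fresh_data_logB(self):
        """Nested check (reduced replicates): logB refitted on fresh draws
        from the same process falls inside the 90% bootstrap interval at
        roughly its nominal rate."""
        def gen(seed, n=400):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 10, n)
            p = 1 / (1 + np.exp(-(x - 5.0)))
            y = (rng.random(n) < p).astype(float)
            return pd.DataFrame({"y": y, "x": x})

        spec = ModelSpec.of({"x": 2.0})
        covered = 0
        for rep in range(20):
            eng = NPMREngine(gen(100 + rep))
            b = eng.bootstrap_logB(spec, n_boot=100, seed=rep)
            fresh = NPMREngine(gen(900 + rep)).fit(spec).logB
            if b["p5"] <= fresh <= b["p95"]:
                covered += 1
        assert covered >= 16, f"fresh-data logB covered in only {covered}/20"

    def test_single_randomization_null_beats_observed(self, small_table):
        cfg = nt.NPMRConfig(seed=2, n_randomizations=1)
        out = nt.randomization_test(small_table, ["x"], -1e9, cfg)
        assert out["p_value"] == 1.0


class TestResponseCurve:
    def test_estimates_stay_in_convex_hull(self, logistic_table):
        res = nt.free_search(logistic_table, ["x"])
        curve = nt.response_curve(logistic_table, res.fit, "x")
        est = curve["estimate"].dropna()
        assert est.between(0.0, 1.0).all()
        # logistic response: estimates increase from low to high x overall
        assert est.iloc[-1] > est.iloc[0]
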