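import numpy as np
import pandas as pd
import pytest

import murretrax as mt
from murretrax.inference import model_table, refit_reml


class TestDelta:
    def test_identity_and_log_unit(self):
        assert mt.delta(3.0, 3.0) == 0.0
        assert mt.delta(1.0, np.e) == pytest.approx(1.0)

    def test_halving(self):
        assert mt.delta(2.0, 1.0) == pytest.approx(-np.log(2), abs=1e-12)

    def test_antisymmetric(self):
        assert mt.delta(1.7, 4.2) == pytest.approx(-mt.delta(4.2, 1.7))

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            mt.delta(0.0, 1.0)
        with pytest.raises(ValueError):
            mt.delta(1.0, -2.0)


class TestAssayCV:
    def test_identical_replicates(self):
        assert mt.assay_cv({"p1": [5.0, 5.0], "p2": [5.0, 5.0]}) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        # within-plate {9,11}: SD = sqrt(2), mean 10 -> CV 14.142%; plate
        # means equal -> inter-assay CV 0
        intra, inter = mt.assay_cv({"p1": [9.0, 11.0], "p2": [9.0, 11.0]})
        assert intra == pytest.approx(100 * np.sqrt(2) / 10, abs=1e-9)
        assert inter == 0.0

    def test_scale_invariance(self):
        a = mt.assay_cv({"p1": [9.0, 11.0], "p2": [10.0, 12.0]})
        b = mt.assay_cv({"p1": [18.0, 22.0], "p2": [20.0, 24.0]})
        assert a == pytest.approx(b)

    def test_single_replicate_warns(self):
        with pytest.warns(UserWarning):
            intra, _ = mt.assay_cv({"p1": [5.0]})
        assert np.isnan(intra)


class TestAicc:
    def test_hand_arithmetic(self):
        # -2(-50) + 2*5 + 2*5*6/19 = 113.1578...
        assert mt.aicc(-50.0, 5, 25) == pytest.approx(100 + 10 + 60 / 19)

    def test_large_n_limit_is_aic(self):
        assert mt.aicc(-50.0, 5, 10**6) == pytest.approx(110.0, abs=1e-3)

    def test_k_zero(self):
        assert mt.aicc(-7.0, 0, 10) == 14.0

    def test_small_n_undefined(self):
        with pytest.raises(ValueError):
            mt.aicc(-10.0, 5, 6)

    def test_monotone_in_loglik_and_k(self):
        assert mt.aicc(-49.0, 5, 25) < mt.aicc(-50.0, 5, 25)
        assert mt.aicc(-50.0, 6, 25) > mt.aicc(-50.0, 5, 25)


class TestVifScreen:
    def test_orthogonal_all_retained(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (200, 3))
        q, _ = np.linalg.qr(X)
        df = pd.DataFrame(q, columns=["a", "b", "c"])
        kept, report = mt.vif_screen(df)
        assert set(kept) == {"a", "b", "c"}
        vals = report.loc[report["metric"] == "VIF", "value"]
        # QR columns are orthogonal but not centred: correlations are O(1/n)
        np.testing.assert_allclose(vals, 1.0, atol=1e-3)

    def test_r09_pair_triggers_removal(self):
        # closed form: VIF = 1/(1-0.9^2) = 5.263 > 5
        n = 100000
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, n)
        e = rng.normal(0, 1, n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * e
        df = pd.DataFrame({"x": x, "y": y, "z": rng.normal(0, 1, n)})
        kept, report = mt.vif_screen(df)
        assert len(kept) == 2
        worst = report.loc[report["metric"] == "VIF", "value"].max()
        assert worst == pytest.approx(1 / (1 - 0.81), rel=0.05)

    def test_perfect_collinearity_infinite_vif(self):
        x = np.arange(50.0)
        df = pd.DataFrame({"x": x, "x2": 2 * x, "z": np.random.default_rng(2).normal(0, 1, 50)})
        kept, report = mt.vif_screen(df)
        assert len(kept) == 2
        assert np.isinf(report["value"].max())

    def test_interactions_removed_before_main_effects(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 500)
        z = rng.normal(0, 1, 500)
        df = pd.DataFrame({"x": x, "z": z, "x:z": x * 0.98 + 0.02 * z})
        kept, _ = mt.vif_screen(df)
        assert "x:z" not in kept and "x" in kept


def _sim_lm(seed, n=150, slope=0.5, noise=0.3):
    rng = np.random.default_rng(seed)
    ice = rng.normal(0, 1, n)
    dur = rng.normal(48, 4, n)
    y = slope * ice + 0.0 * dur + rng.normal(0, noise, n)
    return pd.DataFrame({"y": y, "ice": ice, "dur": dur,
                         "bird_id": [f"b{i}" for i in range(n)]})


class TestFitCandidates:
    CANDS = ["1", "dur", "dur + ice"]

    def test_constant_response_prefers_null(self):
        df = _sim_lm(0)
        df["y"] = 3.14 + np.random.default_rng(99).normal(0, 1e-6, len(df))
        rows = mt.fit_candidates(df, "y", self.CANDS)
        assert rows[0].formula == "1"
        top = rows[0]
        assert abs(top.weight - max(r.weight for r in rows)) < 1e-12

    def test_weights_sum_to_one(self):
        rows = mt.fit_candidates(_sim_lm(1), "y", self.CANDS)
        assert sum(r.weight for r in rows) == pytest.approx(1.0)
        assert rows[0].delta_aicc == 0.0
        assert all(r.delta_aicc >= 0 for r in rows)

    def test_planted_slope_recovered_and_beats_null(self):
        hits_slope, hits_rank = 0, 0
        n_seeds = 20
        for seed in range(n_seeds):
            df = _sim_lm(100 + seed)
            rows = mt.fit_candidates(df, "y", self.CANDS)
            assert rows[0].formula == "dur + ice"
            est = rows[0].fit.params["ice"]
            hits_slope += abs(est - 0.5) <= 0.1
            hits_rank += rows[0].delta_aicc == 0.0
        assert hits_slope >= 0.9 * n_seeds
        assert hits_rank == n_seeds

    def test_random_intercept_sd_recovered(self):
        rng = np.random.default_rng(5)
        birds = np.repeat(np.arange(60), 3)
        u = rng.normal(0, 0.5, 60)[birds]
        x = rng.normal(0, 1, len(birds))
        y = 0.3 * x + u + rng.normal(0, 0.4, len(birds))
        df = pd.DataFrame({"y": y, "x": x,
                           "bird_id": [f"b{i}" for i in birds]})
        fit = refit_reml(df, "y", "x", random_effect="BIRD_ID")
        assert fit.random_intercept_sd == pytest.approx(0.5, abs=0.15)

    def test_model_table_shape(self):
        rows = mt.fit_candidates(_sim_lm(2), "y", self.CANDS)
        tab = model_table(rows)
        assert list(tab["formula"]) == [r.formula for r in rows]
        assert "fit" not in tab.columns


class TestCompareToNull:
    def test_identical_models(self):
        rows = mt.fit_candidates(_sim_lm(3), "y", ["dur"])
        stat, df, p = mt.compare_to_null(rows[0], rows[0])
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_lrt_matches_chi2_tail(self):
        from scipy import stats
        data = _sim_lm(4)
        rows = mt.fit_candidates(data, "y", ["1", "dur + ice"])
        by = {r.formula: r for r in rows}
        stat, df, p = mt.compare_to_null(by["dur + ice"], by["1"])
        assert stat == pytest.approx(2 * (by["dur + ice"].loglik - by["1"].loglik))
        assert p == pytest.approx(float(stats.chi2.sf(stat, df)))

    def test_non_nested_rejected(self):
        data = _sim_lm(5)
        rows = mt.fit_candidates(data, "y", ["dur", "ice"])
        by = {r.formula: r for r in rows}
        with pytest.raises(ValueError):
            mt.compare_to_null(by["dur"], by["ice"])


class TestR2Nakagawa:
    def test_ols_marginal_equals_conditional(self):
        rows = mt.fit_candidates(_sim_lm(6), "y", ["dur + ice"])
        r2m, r2c = mt.r2_nakagawa(rows[0].fit)
        assert r2m == pytest.approx(r2c)
        assert 0 <= r2m <= 1

    def test_null_model_marginal_zero(self):
        rows = mt.fit_candidates(_sim_lm(7), "y", ["1"])
        r2m, _ = mt.r2_nakagawa(rows[0].fit)
        assert r2m == pytest.approx(0.0, abs=1e-10)

    def test_planted_equal_thirds(self):
        rng = np.random.default_rng(8)
        n_birds, reps = 100, 3
        birds = np.repeat(np.arange(n_birds), reps)
        x = rng.normal(0, 1, n_birds * reps)
        u = rng.normal(0, 1.0, n_birds)[birds]
        y = 1.0 * x + u + rng.normal(0, 1.0, n_birds * reps)
        df = pd.DataFrame({"y": y, "x": x, "bird_id": [f"b{i}" for i in birds]})
        rows = mt.fit_candidates(df, "y", ["x"], random_effect="BIRD_ID")
        r2m, r2c = mt.r2_nakagawa(rows[0].fit)
        assert r2m == pytest.approx(1 / 3, abs=0.05)
        assert r2c == pytest.approx(2 / 3, abs=0.05)
        assert r2c >= r2m


class TestRefitReml:
    def test_no_random_effect_equals_ols(self):
        import statsmodels.formula.api as smf
        df = _sim_lm(9)
        fit = refit_reml(df, "y", "dur + ice")
        ols = smf.ols("y ~ dur + ice", df).fit()
        np.testing.assert_allclose(fit.coefficients["estimate"], ols.params, rtol=1e-12)
        np.testing.assert_allclose(fit.coefficients["se"], ols.bse, rtol=1e-12)

    def test_balanced_oneway_matches_anova_closed_form(self):
        """REML variance components equal the ANOVA estimators on a
        balanced one-way design: sigma2_e = MSW, sigma2_b = (MSB-MSW)/r."""
        rng = np.random.default_rng(10)
        g, r = 30, 5
        birds = np.repeat(np.arange(g), r)
        y = rng.normal(0, 0.7, g)[birds] + rng.normal(0, 1.1, g * r)
        df = pd.DataFrame({"y": y, "bird_id": [f"b{i}" for i in birds]})
        fit = refit_reml(df, "y", "1", random_effect="BIRD_ID")
        ybar_g = df.groupby("bird_id")["y"].mean().to_numpy()
        ybar = y.mean()
        msb = r * ((ybar_g - ybar) ** 2).sum() / (g - 1)
        msw = ((y - np.repeat(ybar_g[np.argsort(np.argsort(np.arange(g)))], r)
                if False else y - df.groupby("bird_id")["y"].transform("mean")) ** 2
               ).sum() / (g * (r - 1))
        assert fit.residual_sd ** 2 == pytest.approx(msw, rel=1e-4)
        assert fit.random_intercept_sd ** 2 == pytest.approx((msb - msw) / r, rel=1e-4)

    def test_singular_fit_falls_back_to_ols(self):
        rng = np.random.default_rng(11)
        n = 90
        df = pd.DataFrame({"y": rng.normal(0, 1, n), "x": rng.normal(0, 1, n),
                           "bird_id": [f"b{i % 30}" for i in range(n)]})
        fit = refit_reml(df, "y", "x", random_effect="BIRD_ID")
        if fit.singular:
            assert fit.random_intercept_sd == 0.0

    def test_null_slope_t_statistics_calibrated(self):
        """Planted slope 0 at n=200: |t| < 2 in >= 90% of 100 seeds."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            df = _sim_lm(2000 + seed, n=200, slope=0.0)
            fit = refit_reml(df, "y", "ice")
            t = float(fit.coefficients.set_index("term").loc["ice", "t"])
            hits += abs(t) < 2.0
        assert hits >= 0.90 * n_seeds
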