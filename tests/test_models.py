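"""Mixed-model suite: estimation, LRT, VIF, marginal R^2, bias check."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gazestruct.models import (
    ModelFit,
    aoi_count_model,
    build_model_table,
    fit_latency_lmm,
    fit_success_glmm,
    location_structure_lrt,
    lrt,
    marginal_r2,
    select_interactions,
    stimulus_bias_check,
    vif_check,
)
from gazestruct.synth import simulate_latency_table, simulate_success_table


class TestSuccessGlmm:
    def test_recovers_generative_coefficient(self):
        """beta(diff_deviation) = 0.55 log-odds at the study's n, 20 reps."""
        ests = []
        for s in range(20):
            df = simulate_success_table(coefs={"diff_deviation": 0.55}, seed=s)
            fit = fit_success_glmm(df, ["diff_deviation"])
            ests.append(fit.params[fit.terms.index("diff_deviation")])
        ests = np.array(ests)
        assert abs(ests.mean() - 0.55) <= 0.15
        assert np.sum(ests > 0) >= 19

    def test_ci_coverage_under_null(self):
        """95% Wald CI covers 0 in 90-99% of null replicates."""
        n_reps, covered = 200, 0
        for s in range(n_reps):
            df = simulate_success_table(
                coefs={"x": 0.0}, seed=10_000 + s,
                n_participants=20, trials_per_participant=24,
            )
            fit = fit_success_glmm(df, ["x"])
            i = fit.terms.index("x")
            lo, hi = fit.params[i] - 1.96 * fit.bse[i], fit.params[i] + 1.96 * fit.bse[i]
            covered += lo <= 0 <= hi
        assert 0.90 <= covered / n_reps <= 0.99

    def test_constant_response_raises_separation(self):
        df = simulate_success_table(seed=0)
        df["success"] = 1.0
        with pytest.raises(ValueError, match="separation"):
            fit_success_glmm(df, [])

    def test_zero_variance_agrees_with_plain_logistic(self):
        """Simulated sigma=0: GLMM collapses onto the ordinary GLM."""
        import statsmodels.api as sm

        df = simulate_success_table(
            coefs={"x": 0.8},
            re_sd={"participant_id": 0.0, "background_id": 0.0, "location_idx": 0.0},
            seed=3,
        )
        fit = fit_success_glmm(df, ["x"])
        glm = sm.GLM(df["success"], sm.add_constant(df["x"]), family=sm.families.Binomial()).fit()
        assert np.allclose(fit.params, glm.params.values, atol=1e-2)


class TestLatencyLmm:
    def test_recovers_generative_coefficient(self):
        """beta(diff_entropy) = -128 ms recovered within +-40 over 20 reps."""
        ests = []
        for s in range(20):
            df = simulate_latency_table(coefs={"diff_entropy": -128.0}, seed=s)
            fit = fit_latency_lmm(df, ["diff_entropy"])
            ests.append(fit.params[fit.terms.index("diff_entropy")])
        assert abs(np.mean(ests) - (-128.0)) <= 40.0

    def test_null_location_variance_gives_tiny_structure_chi2(self):
        df = simulate_latency_table(coefs={"x": 0.0}, seed=5)
        res = location_structure_lrt(df, ["x"])
        assert res.chi2 <= 0.5

    def test_lrt_type1_error_nominal(self):
        """Null LRT at alpha=.05 rejects in [3%, 8%] of 200 replicates."""
        n_reps, rejections = 200, 0
        for s in range(n_reps):
            df = simulate_latency_table(
                coefs={"x": 0.0}, seed=20_000 + s,
                n_participants=20, trials_per_participant=10,
            )
            full = fit_latency_lmm(df, ["x"])
            red = fit_latency_lmm(df, [])
            rejections += lrt(full, red).p < 0.05
        assert 0.03 <= rejections / n_reps <= 0.08


class TestLrt:
    def test_identical_models_chi2_zero(self):
        df = simulate_latency_table(seed=1)
        fit = fit_latency_lmm(df, [])
        fit2 = ModelFit(**{**vars(fit), "n_params": fit.n_params + 1})
        res = lrt(fit2, fit)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_chi2_384_df1_p_05(self):
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.050, abs=5e-4)

    def test_df_counts_dropped_coefficients(self):
        df = simulate_latency_table(coefs={"a": 10.0, "b": -5.0}, seed=2)
        full = fit_latency_lmm(df, ["a", "b"])
        red = fit_latency_lmm(df, [])
        assert lrt(full, red).df == 2

    def test_non_nested_raises(self):
        df = simulate_latency_table(coefs={"a": 10.0, "b": -5.0}, seed=2)
        fa = fit_latency_lmm(df, ["a"])
        fb = fit_latency_lmm(df, ["a", "b"])
        with pytest.raises(ValueError):
            lrt(fa, fb)

    def test_invariant_to_predictor_rescaling(self):
        df = simulate_latency_table(coefs={"a": 60.0}, seed=4)
        full = fit_latency_lmm(df, ["a"])
        red = fit_latency_lmm(df, [])
        chi_1 = lrt(full, red).chi2
        df2 = df.copy()
        df2["a"] = df2["a"] * 1000
        chi_2 = lrt(fit_latency_lmm(df2, ["a"]), fit_latency_lmm(df2, [])).chi2
        assert chi_1 == pytest.approx(chi_2, rel=1e-4)


class TestVif:
    def test_orthogonal_predictors_near_one(self, rng):
        df = pd.DataFrame(rng.standard_normal((500, 3)), columns=["a", "b", "c"])
        vifs, ok = vif_check(df, ["a", "b", "c"])
        assert ok
        assert all(abs(v - 1) < 0.1 for v in vifs.values())

    def test_correlated_pair_closed_form(self, rng):
        """r = .9 gives VIF ~ 1/(1-.81) ~ 5.26 and a failed screen."""
        n = 200_00
        a = rng.standard_normal(n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        df = pd.DataFrame({"a": a, "b": b})
        vifs, ok = vif_check(df, ["a", "b"])
        assert not ok
        assert vifs["a"] == pytest.approx(1 / (1 - 0.81), rel=0.05)

    def test_duplicated_column_unbounded(self, rng):
        a = rng.standard_normal(100)
        df = pd.DataFrame({"a": a, "b": a})
        vifs, ok = vif_check(df, ["a", "b"])
        assert not ok
        assert np.isinf(vifs["a"])


class TestMarginalR2:
    def _fit(self, family, terms, params, re_var, table):
        return ModelFit(terms=["(Intercept)"] + terms, params=np.array([0.0] + params),
                        bse=np.ones(len(terms) + 1), re_var=re_var, loglik=0.0,
                        scale="x", family=family, n=len(table), n_params=1, converged=True)

    def test_zero_fixed_effects_gives_zero(self, rng):
        table = pd.DataFrame({"x": rng.standard_normal(500)})
        fit = self._fit("gaussian", ["x"], [0.0], {"g": 1.0, "residual": 2.0}, table)
        assert marginal_r2(fit, table) == 0.0

    def test_gaussian_closed_form_quarter(self, rng):
        """var(fixed)=1, random=1, residual=2 -> R2 = 1/4."""
        x = rng.standard_normal(200_000)
        x = (x - x.mean()) / x.std()
        table = pd.DataFrame({"x": x})
        fit = self._fit("gaussian", ["x"], [1.0], {"g": 1.0, "residual": 2.0}, table)
        assert marginal_r2(fit, table) == pytest.approx(0.25, abs=1e-6)

    def test_logistic_denominator_uses_pi2_over_3(self, rng):
        x = rng.standard_normal(10_000)
        x = (x - x.mean()) / x.std()
        table = pd.DataFrame({"x": x})
        fit = self._fit("binomial", ["x"], [1.0], {"g": 1.0}, table)
        expect = 1.0 / (1.0 + 1.0 + np.pi**2 / 3.0)
        assert marginal_r2(fit, table) == pytest.approx(expect, abs=1e-6)


class TestInteractionSelection:
    def test_retained_when_simulated(self):
        """True diff_luminance x congruency interaction (0.83) is kept."""
        kept_count = 0
        for s in range(10):
            df = simulate_success_table(coefs={"diff_luminance": 0.6, "category_congruency": -0.6}, seed=s)
            rng2 = np.random.default_rng(s)
            df["category_congruency"] = (df["category_congruency"] > 0).astype(float)
            eta_extra = 0.83 * df["diff_luminance"] * df["category_congruency"]
            flip = rng2.random(len(df)) < (np.abs(np.tanh(eta_extra / 2)) / 2)
            target = (eta_extra > 0).astype(float)
            df.loc[flip, "success"] = target[flip]
            _, kept, _ = select_interactions(
                df, "success", ["diff_luminance", "category_congruency"], ["category_congruency"]
            )
            kept_count += kept
        assert kept_count >= 8

    def test_rarely_retained_under_null(self):
        kept_count = 0
        for s in range(10):
            df = simulate_success_table(coefs={"diff_luminance": 0.6, "z": 0.0}, seed=100 + s)
            _, kept, _ = select_interactions(df, "success", ["diff_luminance", "z"], ["z"])
            kept_count += kept
        assert kept_count <= 2

    def test_requires_diff_luminance(self):
        df = simulate_success_table(coefs={"z": 0.0}, seed=0)
        with pytest.raises(ValueError):
            select_interactions(df, "success", ["z"], ["z"])


class TestStimulusBiasCheck:
    def _trials(self, rng, shift=0.0, n=100):
        rows = []
        for cong in ("congruent", "incongruent"):
            for _ in range(n):
                rec = {"category_congruency": cong}
                for p in ("diff_luminance", "diff_alpha", "diff_deviation", "diff_entropy",
                          "diff_skew", "curvature", "depth", "regularity", "symmetry"):
                    rec[p] = rng.standard_normal() + (shift if cong == "incongruent" else 0.0)
                rows.append(rec)
        return pd.DataFrame(rows)

    def test_identical_groups_null(self):
        df = self._trials(np.random.default_rng(0), shift=0.0, n=50)
        half = df[df.category_congruency == "congruent"].copy()
        half2 = half.copy()
        half2["category_congruency"] = "incongruent"
        out = stimulus_bias_check(pd.concat([half, half2], ignore_index=True))
        assert np.allclose(out["d"], 0) and np.allclose(out["t"], 0)
        assert np.allclose(out["p"], 1)

    def test_unit_shift_recovered(self):
        out = stimulus_bias_check(self._trials(np.random.default_rng(1), shift=1.0))
        assert np.all(np.abs(out["d"] - 1.0) <= 0.35)

    def test_nine_property_rows(self):
        out = stimulus_bias_check(self._trials(np.random.default_rng(2)))
        assert len(out) == 9

    def test_empty_group_raises(self):
        df = self._trials(np.random.default_rng(3))
        with pytest.raises(ValueError):
            stimulus_bias_check(df[df.category_congruency == "congruent"])


class TestAoiCountModel:
    def test_uniform_counts_no_significant_contrast(self, rng):
        """Uniform AOI targeting: no empty-AOI contrast significant at .005."""
        rows = []
        for p in range(15):
            for t in range(12):
                counts = rng.poisson(1.0, 10)
                tloc = int(rng.integers(10))
                rec = {"participant_id": f"p{p}", "target_location": tloc,
                       "target_count": counts[tloc]}
                for i in range(10):
                    rec[f"aoi_{i}"] = counts[i]
                rows.append(rec)
        res = aoi_count_model(pd.DataFrame(rows))
        assert all(p > 0.005 for p in res["contrast_p"].values())

    def test_target_preference_detected(self, rng):
        rows = []
        for p in range(15):
            for t in range(12):
                counts = rng.poisson(0.5, 10)
                tloc = int(rng.integers(10))
                counts[tloc] += rng.poisson(3.0)
                rec = {"participant_id": f"p{p}", "target_location": tloc,
                       "target_count": counts[tloc]}
                for i in range(10):
                    rec[f"aoi_{i}"] = counts[i]
                rows.append(rec)
        res = aoi_count_model(pd.DataFrame(rows))
        assert res["lrt"].p < 0.001
        # all empty-AOI contrasts negative on the log scale
        assert all(c < 0 for c in res["fit"].params[1:])


class TestBuildModelTable:
    def test_standardizes_and_codes_factors(self, rng):
        df = pd.DataFrame(
            {
                "success": rng.integers(0, 2, 200).astype(float),
                "latency": rng.uniform(500, 3000, 200),
                "diff_luminance": rng.uniform(0, 5, 200),
                "movement": rng.uniform(0, 10, 200),
                "category_congruency": rng.choice(["congruent", "incongruent"], 200),
                "depth_congruency": rng.choice(["congruent", "incongruent"], 200),
            }
        )
        out = build_model_table(df)
        assert abs(out["diff_luminance"].mean()) < 1e-9
        assert out["diff_luminance"].std(ddof=0) == pytest.approx(1.0)
        assert set(out["category_congruency"].unique()) <= {0.0, 1.0}
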