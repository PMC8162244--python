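"""Engine tests against closed-form and independent-package oracles."""

import numpy as np
import pandas as pd
import pytest

import varpart as vp
from varpart.formula import parse_formula
from varpart.glmm import OLRE_COLUMN, RandomStructure, fit_mixed_model


def _one_way_data(g=10, m=5, s2a=1.0, s2e=0.5, seed=0):
    rng = np.random.default_rng(seed)
    group = np.repeat(np.arange(g), m)
    y = rng.normal(0, np.sqrt(s2a), g)[group] + rng.normal(0, np.sqrt(s2e), g * m)
    return pd.DataFrame({"y": y, "g": [f"g{i}" for i in group]})


class TestGaussianREML:
    def test_balanced_one_way_matches_anova_estimators(self):
        # closed-form oracle: REML on a balanced one-way design equals
        # sigma2_a = (MSB - MSW)/m, sigma2_e = MSW
        g, m = 10, 5
        data = _one_way_data(g, m, seed=3)
        y = data["y"].to_numpy()
        ybar_g = y.reshape(g, m).mean(axis=1)
        msb = m * np.sum((ybar_g - y.mean()) ** 2) / (g - 1)
        msw = np.sum((y.reshape(g, m) - ybar_g[:, None]) ** 2) / (g * (m - 1))
        spec = parse_formula("y ~ 1 + (1|g)")
        fit = fit_mixed_model(spec, data)
        assert fit.re_variances["g"] == pytest.approx(max((msb - msw) / m, 0), rel=1e-4)
        assert fit.resid_variance == pytest.approx(msw, rel=1e-4)

    def test_matches_statsmodels_mixedlm_with_covariate(self):
        rng = np.random.default_rng(8)
        data = _one_way_data(12, 6, seed=8)
        data["x"] = rng.normal(size=len(data))
        data["y"] = data["y"] + 0.7 * data["x"]
        spec = parse_formula("y ~ x + (1|g)")
        fit = fit_mixed_model(spec, data)
        sm = pytest.importorskip("statsmodels.formula.api")
        ref = sm.mixedlm("y ~ x", data, groups=data["g"]).fit(reml=True)
        np.testing.assert_allclose(fit.beta, ref.fe_params.to_numpy(), atol=1e-4)
        assert fit.re_variances["g"] == pytest.approx(float(ref.cov_re.iloc[0, 0]), abs=1e-4)
        assert fit.resid_variance == pytest.approx(ref.scale, rel=1e-3)

    def test_no_group_signal_hits_zero_boundary(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            {"y": rng.normal(size=80), "g": np.repeat([f"g{i}" for i in range(8)], 10)}
        )
        fit = fit_mixed_model(parse_formula("y ~ 1 + (1|g)"), data)
        assert fit.re_variances["g"] == 0.0
        assert any("boundary" in w for w in fit.warnings)

    def test_parameter_recovery_large_n(self):
        sc = vp.SimScenario(
            n_groups=100, group_size=50, beta=(0.0, 1.0),
            sigma2_group=0.5, sigma2_resid=0.5, seed=10,
        )
        data, _ = vp.simulate_dataset(sc)
        fit = fit_mixed_model(parse_formula("y ~ x1 + (1|group)"), data)
        assert fit.re_variances["group"] == pytest.approx(0.5, abs=0.05)
        assert fit.resid_variance == pytest.approx(0.5, abs=0.05)
        assert fit.beta[1] == pytest.approx(1.0, abs=0.05)
        # the intercept's SE is sqrt(s2_group/n_groups) ~ 0.07, not 1/sqrt(n)
        assert fit.beta[0] == pytest.approx(0.0, abs=0.25)

    def test_crossed_random_intercepts_recovered(self):
        rng = np.random.default_rng(5)
        n_a, n_b, reps = 30, 30, 4
        a = np.repeat(np.arange(n_a), n_b * reps // n_a)
        rng.shuffle(a)
        b = np.tile(np.arange(n_b), n_b * reps // n_b)
        y = (
            rng.normal(0, 1.0, n_a)[a]
            + rng.normal(0, 0.7, n_b)[b]
            + rng.normal(0, 0.5, len(a))
        )
        data = pd.DataFrame({"y": y, "A": a.astype(str), "B": b.astype(str)})
        fit = fit_mixed_model(parse_formula("y ~ 1 + (1|A) + (1|B)"), data)
        assert fit.re_variances["A"] == pytest.approx(1.0, abs=0.45)
        assert fit.re_variances["B"] == pytest.approx(0.49, abs=0.3)

    def test_rank_deficient_design_raises(self):
        data = _one_way_data(6, 4)
        data["x"] = 1.0  # duplicate of the intercept
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit_mixed_model(parse_formula("y ~ x + (1|g)"), data)


class TestLaplaceGLMM:
    def test_zero_group_variance_reduces_to_glm(self):
        sc = vp.SimScenario(
            n_groups=25, group_size=16, beta=(0.2, 0.9, -0.5),
            sigma2_group=0.0, family="binomial", seed=2,
        )
        data, _ = vp.simulate_dataset(sc)
        spec = vp.ModelSpec(response="y", fixed_terms=["x1", "x2"],
                            random_groups=["group"], family="binomial")
        fit = fit_mixed_model(spec, data)
        smapi = pytest.importorskip("statsmodels.api")
        X = smapi.add_constant(data[["x1", "x2"]].to_numpy())
        glm = smapi.GLM(data["y"].to_numpy(), X, family=smapi.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=1e-4)

    def test_binomial_group_variance_recovery(self):
        sc = vp.SimScenario(
            n_groups=50, group_size=40, beta=(0.0,), predictor_cov=np.eye(0),
            sigma2_group=1.0, family="binomial", seed=6,
        )
        data, _ = vp.simulate_dataset(sc)
        spec = vp.ModelSpec(response="y", fixed_terms=[], random_groups=["group"],
                            family="binomial")
        fit = fit_mixed_model(spec, data)
        assert fit.re_variances["group"] == pytest.approx(1.0, abs=0.25)

    def test_overdispersed_poisson_gets_positive_olre_variance(self):
        sc = vp.SimScenario(
            n_groups=30, group_size=15, beta=(0.5, 0.4),
            sigma2_group=0.3, sigma2_olre=0.5, family="poisson", seed=4,
        )
        data, _ = vp.simulate_dataset(sc)
        model = vp.VariancePartition.from_formula("y ~ x1 + (1|group)", data, family="poisson")
        assert model.olre_added
        res = model.fit()
        assert res.fitted.olre_added
        assert res.fitted.resid_variance > 0.2

    def test_probit_link_fits(self):
        sc = vp.SimScenario(
            n_groups=30, group_size=20, beta=(0.0, 0.8),
            sigma2_group=0.4, family="binomial", seed=9,
        )
        data, _ = vp.simulate_dataset(sc)
        spec = parse_formula("y ~ x1 + (1|group)")
        spec = vp.ModelSpec(
            response=spec.response, fixed_terms=spec.fixed_terms,
            random_groups=spec.random_groups, family="binomial", link="probit",
        )
        fit = fit_mixed_model(spec, data)
        assert fit.converged
        # probit slope of a logit-generated effect is roughly beta/1.7
        assert fit.beta[1] == pytest.approx(0.8 / 1.7, abs=0.2)

    def test_all_zero_counts_are_degenerate(self):
        data = pd.DataFrame({"y": np.zeros(40), "g": np.repeat(list("abcd"), 10)})
        spec = parse_formula("y ~ 1 + (1|g)")
        spec = vp.ModelSpec(response="y", fixed_terms=[], random_groups=["g"], family="poisson")
        with pytest.raises(Exception, match="degenerate"):
            fit_mixed_model(spec, data)


class TestEnsureOLRE:
    def _spec(self, family, response="y"):
        return vp.ModelSpec(
            response=response, fixed_terms=[], random_groups=["g"], family=family,
            link=None,
        )

    def test_proportion_binomial_gets_row_index_column(self):
        data = pd.DataFrame({"s": [3, 1, 2, 4], "f": [2, 4, 3, 1], "g": ["a", "b", "a", "b"]})
        spec = self._spec("binomial", response=("s", "f"))
        spec2, data2, added = vp.ensure_olre(spec, data)
        assert added and OLRE_COLUMN in spec2.random_groups
        assert list(data2[OLRE_COLUMN]) == [0, 1, 2, 3]

    def test_binary_binomial_unchanged(self):
        data = pd.DataFrame({"y": [0, 1, 1], "g": list("aab")})
        spec2, data2, added = vp.ensure_olre(self._spec("binomial"), data)
        assert not added and OLRE_COLUMN not in data2.columns

    def test_existing_row_level_group_is_respected(self):
        data = pd.DataFrame({"y": [1, 2, 3], "g": ["r1", "r2", "r3"]})
        spec2, data2, added = vp.ensure_olre(self._spec("poisson"), data)
        assert not added

    def test_gaussian_untouched(self):
        data = pd.DataFrame({"y": [1.0, 2.0], "g": list("ab")})
        _, _, added = vp.ensure_olre(self._spec("gaussian"), data)
        assert not added


class TestSimulateResponse:
    def test_all_variances_zero_returns_fitted_values(self, orthogonal_fit):
        fit, _ = orthogonal_fit
        frozen = vp.FittedGLMM(
            beta=fit.beta, re_variances={g: 0.0 for g in fit.re_variances},
            resid_variance=0.0, eta=fit.eta, design=fit.design, spec=fit.spec,
            random=fit.random, family=fit.family, y=fit.y, weights=fit.weights,
            converged=True, loglik=0.0,
        )
        sim = vp.simulate_response(frozen, np.random.default_rng(0))
        np.testing.assert_array_equal(sim, fit.eta)

    def test_simulation_mean_converges_to_linear_predictor(self, orthogonal_fit):
        fit, _ = orthogonal_fit
        rng = np.random.default_rng(1)
        sims = np.mean([vp.simulate_response(fit, rng) for _ in range(400)], axis=0)
        tot_sd = np.sqrt(fit.sum_re_variance + fit.resid_variance)
        mc_err = 5 * tot_sd / np.sqrt(400)
        assert np.max(np.abs(sims - fit.eta)) < mc_err

    def test_group_mean_variance_matches_variance_algebra(self):
        # var of simulated group means approx sigma2_a + sigma2_e/m
        data = _one_way_data(g=40, m=8, s2a=0.8, s2e=0.4, seed=12)
        fit = fit_mixed_model(parse_formula("y ~ 1 + (1|g)"), data)
        rng = np.random.default_rng(7)
        vars_ = []
        for _ in range(300):
            sim = vp.simulate_response(fit, rng)
            gm = sim.reshape(40, 8).mean(axis=1)
            vars_.append(np.var(gm, ddof=1))
        expected = fit.re_variances["g"] + fit.resid_variance / 8
        assert np.mean(vars_) == pytest.approx(expected, rel=0.15)

    def test_refit_on_simulated_data_recovers_parameters(self):
        sc = vp.SimScenario(n_groups=60, group_size=35, beta=(0.0, 1.0),
                            sigma2_group=0.5, sigma2_resid=0.5, seed=13)
        data, _ = vp.simulate_dataset(sc)
        spec = parse_formula("y ~ x1 + (1|group)")
        fit = fit_mixed_model(spec, data)
        sim = vp.simulate_response(fit, np.random.default_rng(3))
        refit = fit_mixed_model(spec, data, y_override=sim)
        assert refit.re_variances["group"] == pytest.approx(
            fit.re_variances["group"], abs=0.15
        )
        assert refit.resid_variance == pytest.approx(fit.resid_variance, abs=0.1)
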