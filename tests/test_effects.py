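import numpy as np
import pandas as pd
import pytest

import varpart as vp
from varpart.effects import beta_weights, inclusive_r2, structure_coefficients
from varpart.formula import parse_formula
from varpart.glmm import fit_mixed_model
from varpart.variance import decompose, total_r2


class TestStructureCoefficients:
    def test_single_predictor_model_has_sc_one(self):
        sc = vp.SimScenario(n_groups=25, group_size=20, beta=(0.0, 1.0),
                            sigma2_group=0.5, sigma2_resid=0.5, seed=1)
        data, _ = vp.simulate_dataset(sc)
        fit = fit_mixed_model(parse_formula("y ~ x1 + (1|group)"), data)
        assert structure_coefficients(fit)[0] == pytest.approx(1.0, abs=1e-8)

    def test_two_independent_predictors_closed_form(self, orthogonal_fit):
        fit, _ = orthogonal_fit
        sc_vec = structure_coefficients(fit)
        assert sc_vec[0] == pytest.approx(1 / np.sqrt(1.25), abs=0.03)
        assert sc_vec[1] == pytest.approx(0.5 / np.sqrt(1.25), abs=0.03)

    def test_null_uncorrelated_predictor_has_sc_near_zero(self):
        sc = vp.SimScenario(n_groups=40, group_size=20, beta=(0.0, 1.0, 0.0),
                            sigma2_group=0.3, sigma2_resid=0.5, seed=2)
        data, _ = vp.simulate_dataset(sc)
        fit = fit_mixed_model(parse_formula("y ~ x1 + x2 + (1|group)"), data)
        assert abs(structure_coefficients(fit)[1]) < 0.1

    def test_sc_sign_matches_direct_correlation(self, orthogonal_fit):
        fit, _ = orthogonal_fit
        sc_vec = structure_coefficients(fit)
        for j, col in enumerate(fit.design.noninterceptcolumns):
            x = fit.design.matrix[:, col]
            direct = np.corrcoef(x, fit.eta)[0, 1]
            assert sc_vec[j] == pytest.approx(direct, abs=1e-10)

    def test_exactly_uncorrelated_columns_fully_attribute_eta_variance(self):
        # when the realized design columns are orthogonal in-sample, the
        # squared structure coefficients partition var(eta) completely
        rng = np.random.default_rng(10)
        n = 600
        raw = rng.standard_normal((n, 2))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        data = pd.DataFrame(
            {
                "x1": q[:, 0] * np.sqrt(n),
                "x2": q[:, 1] * np.sqrt(n),
                "g": np.repeat([f"g{i}" for i in range(30)], n // 30),
            }
        )
        data["y"] = (
            1.0 * data["x1"] + 0.5 * data["x2"]
            + rng.normal(0, 0.7, 30)[pd.factorize(data["g"])[0]]
            + rng.normal(0, 0.7, n)
        )
        fit = fit_mixed_model(parse_formula("y ~ x1 + x2 + (1|g)"), data)
        sc_vec = structure_coefficients(fit)
        assert np.sum(sc_vec**2) == pytest.approx(1.0, abs=1e-10)

    def test_constant_eta_yields_missing_values_with_warning(self):
        data, _ = vp.simulate_dataset(
            vp.SimScenario(beta=(0.5,), predictor_cov=np.eye(0), seed=3)
        )
        fit = fit_mixed_model(parse_formula("y ~ 1 + (1|group)"), data)
        with pytest.warns(UserWarning, match="constant"):
            out = structure_coefficients(fit)
        assert out.size == 0


class TestInclusiveR2:
    def test_single_predictor_inclusive_equals_total(self):
        assert inclusive_r2(np.array([1.0]), 0.4)[0] == 0.4

    def test_zero_sc_gives_zero(self):
        assert inclusive_r2(np.array([0.0]), 0.9)[0] == 0.0

    def test_orthogonal_inclusive_matches_part_r2(self, orthogonal_fit, orthogonal_gaussian):
        fit, data = orthogonal_fit
        _, _, truth = orthogonal_gaussian
        vd = decompose(fit)
        ir2 = inclusive_r2(structure_coefficients(fit), total_r2(vd))
        assert ir2[0] == pytest.approx(truth["part_r2"]["x1"], abs=0.04)
        assert ir2[1] == pytest.approx(truth["part_r2"]["x2"], abs=0.04)

    def test_exact_identity_with_sc_and_total(self, orthogonal_fit):
        fit, _ = orthogonal_fit
        vd = decompose(fit)
        sc_vec = structure_coefficients(fit)
        np.testing.assert_array_equal(
            inclusive_r2(sc_vec, total_r2(vd)), sc_vec**2 * total_r2(vd)
        )


class TestBetaWeights:
    def test_standardized_data_returns_raw_slope(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        g = np.repeat([f"g{i}" for i in range(40)], n // 40)
        y = 0.3 * x + rng.standard_normal(n) * np.sqrt(1 - 0.09)
        y = (y - y.mean()) / y.std()
        data = pd.DataFrame({"y": y, "x": x, "g": g})
        fit = fit_mixed_model(parse_formula("y ~ x + (1|g)"), data)
        bw = beta_weights(fit)
        assert bw[0] == pytest.approx(fit.beta[1], abs=1e-10)
        assert bw[0] == pytest.approx(0.3, abs=0.07)

    def test_scale_invariance(self, orthogonal_fit):
        fit, data = orthogonal_fit
        bw = beta_weights(fit)
        data2 = data.copy()
        data2["x1"] = data2["x1"] * 2.0  # doubling units halves the slope
        fit2 = fit_mixed_model(parse_formula("y ~ x1 + x2 + (1|group)"), data2)
        assert fit2.beta[1] == pytest.approx(fit.beta[1] / 2.0, abs=1e-6)
        np.testing.assert_allclose(beta_weights(fit2), bw, atol=1e-6)

    def test_shift_invariance_of_all_effect_statistics(self, orthogonal_fit):
        fit, data = orthogonal_fit
        data2 = data.copy()
        data2["x1"] = data2["x1"] + 100.0
        fit2 = fit_mixed_model(parse_formula("y ~ x1 + x2 + (1|group)"), data2)
        np.testing.assert_allclose(
            structure_coefficients(fit2), structure_coefficients(fit), atol=1e-6
        )
        np.testing.assert_allclose(beta_weights(fit2), beta_weights(fit), atol=1e-6)

    def test_suppression_pattern_under_collinearity(self):
        # strongly correlated predictors with unequal effects: the weaker
        # one's beta weight flips sign while both SCs stay positive
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        sc = vp.SimScenario(n_groups=50, group_size=20, beta=(0.0, 0.8, 0.6),
                            predictor_cov=cov, sigma2_group=0.3,
                            sigma2_resid=0.4, seed=6)
        data, _ = vp.simulate_dataset(sc)
        # effects realized through x1 only: regenerate y with beta2 ~ 0
        rng = np.random.default_rng(7)
        eta = 0.8 * data["x1"].to_numpy() - 0.1 * data["x2"].to_numpy()
        g = pd.factorize(data["group"])[0]
        y = eta + rng.normal(0, 0.55, 50)[g] + rng.normal(0, 0.63, len(data))
        data["y"] = y
        fit = fit_mixed_model(parse_formula("y ~ x1 + x2 + (1|group)"), data)
        bw = beta_weights(fit)
        sc_vec = structure_coefficients(fit)
        assert sc_vec[0] > 0 and sc_vec[1] > 0  # both correlate with eta
        assert bw[0] > 0 and bw[1] < 0          # suppression sign flip

    def test_nongaussian_weights_use_latent_scale_sd(self):
        sc = vp.SimScenario(n_groups=30, group_size=15, beta=(0.0, 0.7),
                            family="binomial", sigma2_group=0.4, seed=8)
        data, _ = vp.simulate_dataset(sc)
        model = vp.VariancePartition.from_formula("y ~ x1 + (1|group)", data,
                                                  family="binomial")
        res = model.fit()
        fit, vd = res.fitted, res.decomposition
        bw = beta_weights(fit, vd)
        sd_x = np.std(fit.design.matrix[:, 1])
        assert bw[0] == pytest.approx(fit.beta[1] * sd_x / np.sqrt(vd.Y_Total))
        with pytest.raises(ValueError, match="decomposition"):
            beta_weights(fit)
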