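"""Moyal machinery, power-law fitting and diameter regressions."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

from poretrans import (
    EULER_GAMMA,
    fit_diameter_regression,
    fit_moyal,
    fit_power_law,
    gof_test,
    moyal_cdf,
    moyal_params_from_moments,
    moyal_moments_from_params,
    moyal_pdf,
    sample_moyal,
    anderson_darling_statistic,
    cramer_von_mises_statistic,
)
from poretrans.stats import FitError, moyal_moments_by_quadrature


class TestMoyalDensity:
    @pytest.mark.parametrize("s", [0.5, 1.0, 7.3])
    def test_peak_value_at_mode(self, s):
        # psi(m) = exp(-1/2) / (s * sqrt(2*pi)) ~= 0.241971 / s
        assert moyal_pdf(3.0, 3.0, s) == pytest.approx(0.2419707245191434 / s, rel=1e-12)

    def test_location_scale_family(self, rng):
        for _ in range(50):
            m = float(rng.normal(0, 10))
            s = float(rng.uniform(0.1, 5))
            tau = float(rng.normal(m, 4 * s))
            assert moyal_pdf(tau, m, s) == pytest.approx(
                moyal_pdf((tau - m) / s, 0.0, 1.0) / s, rel=1e-12
            )

    def test_integrates_to_one(self):
        val, err = integrate.quad(lambda t: moyal_pdf(t, 2.0, 1.5), -40, 400, limit=400)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_matches_scipy_moyal(self, rng):
        x = rng.normal(0, 5, 200)
        assert np.allclose(moyal_pdf(x, 1.0, 2.0), sps.moyal.pdf(x, loc=1.0, scale=2.0))
        assert np.allclose(moyal_cdf(x, 1.0, 2.0), sps.moyal.cdf(x, loc=1.0, scale=2.0))

    def test_stable_in_far_tails(self):
        assert moyal_pdf(-40.0, 0.0, 1.0) == 0.0  # underflows cleanly, no overflow
        assert moyal_pdf(40.0, 0.0, 1.0) > 0.0
        assert np.isfinite(moyal_cdf(-40.0, 0.0, 1.0))

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            moyal_pdf(0.0, 0.0, 0.0)


class TestMomentConversions:
    def test_worked_example(self):
        m, s = moyal_params_from_moments(0.0, math.pi / math.sqrt(2.0))
        assert s == pytest.approx(1.0, rel=1e-12)
        assert m == pytest.approx(-(math.log(2.0) + EULER_GAMMA), rel=1e-12)
        assert m == pytest.approx(-1.27036, abs=5e-6)

    def test_roundtrip(self, rng):
        for _ in range(50):
            mean = float(rng.normal(0, 100))
            sd = float(rng.uniform(0.01, 50))
            m, s = moyal_params_from_moments(mean, sd)
            mean2, sd2 = moyal_moments_from_params(m, s)
            assert mean2 == pytest.approx(mean, abs=1e-12 * max(1, abs(mean)))
            assert sd2 == pytest.approx(sd, rel=1e-12)

    def test_conversions_agree_with_quadrature_moments(self, rng):
        # validates the mean/sd <-> (m, s) relations themselves
        for _ in range(5):
            m = float(rng.normal(0, 5))
            s = float(rng.uniform(0.2, 4))
            mean_q, sd_q = moyal_moments_by_quadrature(m, s)
            mean_c, sd_c = moyal_moments_from_params(m, s)
            assert mean_c == pytest.approx(mean_q, abs=1e-6 * max(1, abs(mean_q)))
            assert sd_c == pytest.approx(sd_q, rel=1e-6)

    def test_sampler_matches_cdf(self, rng):
        x = sample_moyal(20_000, 3.0, 2.0, rng)
        res = sps.ks_1samp(x, lambda t: moyal_cdf(t, 3.0, 2.0))
        assert res.pvalue > 0.01


class TestFitMoyal:
    def test_equivariance_under_affine_maps(self, rng):
        x = sample_moyal(2_000, 0.0, 1.0, rng)
        base = fit_moyal(x)
        scaled = fit_moyal(3.0 * x + 7.0)
        assert scaled.m == pytest.approx(3.0 * base.m + 7.0, abs=2e-3 * 3)
        assert scaled.s == pytest.approx(3.0 * base.s, rel=2e-3)

    def test_parameterizations_consistent(self, rng):
        fit = fit_moyal(sample_moyal(500, 5.0, 2.0, rng))
        m, s = moyal_params_from_moments(fit.tau_mean, fit.sigma)
        assert m == pytest.approx(fit.m, rel=1e-10, abs=1e-10)
        assert s == pytest.approx(fit.s, rel=1e-10)

    def test_rmse_shrinks_with_sample_size(self):
        rng = np.random.default_rng(42)
        rmses = []
        for n in (200, 1_000, 5_000):
            errs = []
            for _ in range(30):
                x = sample_moyal(n, 10.0, 2.0, rng)
                f = fit_moyal(x)
                errs.append((f.m - 10.0) ** 2 + (f.s - 2.0) ** 2)
            rmses.append(math.sqrt(float(np.mean(errs))))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            fit_moyal(np.full(100, 3.0))
        with pytest.raises(FitError):
            fit_moyal(np.arange(5.0))


class TestGof:
    def test_cramer_von_mises_hand_example(self):
        # n = 3 uniforms against the uniform CDF, evaluated by hand
        w2 = cramer_von_mises_statistic([0.1, 0.5, 0.9])
        assert w2 == pytest.approx(1.0 / 36.0 + 2.0 * (1.0 / 15.0) ** 2, rel=1e-12)
        assert w2 == pytest.approx(0.0366667, abs=5e-7)

    def test_cramer_von_mises_matches_scipy(self, rng):
        x = rng.normal(0, 1, 200)
        ours = cramer_von_mises_statistic(sps.norm.cdf(x))
        theirs = sps.cramervonmises(x, sps.norm.cdf).statistic
        assert ours == pytest.approx(theirs, rel=1e-12)

    def test_anderson_darling_matches_direct_formula(self, rng):
        u = np.sort(rng.uniform(0.001, 0.999, 50))
        n = u.size
        total = 0.0
        for i in range(1, n + 1):  # independent elementwise evaluation
            total += (2 * i - 1) * (math.log(u[i - 1]) + math.log(1 - u[n - i]))
        assert anderson_darling_statistic(u) == pytest.approx(-n - total / n, rel=1e-12)

    def test_moyal_rejected_for_normal_data(self, rng):
        # a symmetric sample with matched moments is not Moyal (right-skewed)
        x = rng.normal(50.0, 5.0, 2_000)
        fit = fit_moyal(x)
        res = gof_test(x, fit, which="cramer_von_mises", n_bootstrap=199, rng=1)
        assert res.p_value < 0.01
        res_ad = gof_test(x, fit, which="anderson_darling", n_bootstrap=199, rng=1)
        assert res_ad.p_value < 0.01

    def test_moyal_not_rejected_for_moyal_data(self, rng):
        x = sample_moyal(500, 0.0, 1.0, rng)
        fit = fit_moyal(x)
        res = gof_test(x, fit, which="cramer_von_mises", n_bootstrap=199, rng=2)
        assert res.p_value > 0.05


class TestPowerLaw:
    def test_noiseless_recovery(self):
        L = np.array([5, 10, 15, 20, 25, 50, 75, 100], dtype=float)
        y = 5.0 + 2.0 * L**1.3
        fit = fit_power_law(L, y)
        assert fit.a == pytest.approx(5.0, abs=1e-6)
        assert fit.b == pytest.approx(2.0, abs=1e-6)
        assert fit.xi == pytest.approx(1.3, abs=1e-6)
        assert fit.residual_sse < 1e-12

    def test_linear_limit(self):
        L = np.array([5, 10, 15, 20, 25], dtype=float)
        y = 3.0 + 0.5 * L
        fit = fit_power_law(L, y)
        assert fit.xi == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(fit.predict(L), y, atol=1e-8)

    def test_too_few_distinct_points(self):
        with pytest.raises(FitError):
            fit_power_law([5, 5, 10, 10], [1, 1, 2, 2])


def _table1_l100_response(pc, pt):
    # generating truth taken from a published fitted model at L=100
    return 70436.7 - 2700.8 * pc - 1266.1 * pt + 4632.9 * pc / pt


def _ols_oracle(X, y):
    """Textbook OLS: normal equations, t statistics, two-sided p-values."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    n, p = X.shape
    s2 = float(resid @ resid) / (n - p)
    se = np.sqrt(np.diag(XtX_inv) * s2)
    t = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(t), df=n - p)
    return beta, pvals


class TestDiameterRegression:
    @staticmethod
    def _frame(values, responses, sds=None):
        pcs, pts = zip(*values)
        df = pd.DataFrame({"phi_cis": pcs, "phi_trans": pts, "tau_mean": responses})
        df["tau_sd"] = sds if sds is not None else 1.0
        return df

    def test_exact_recovery_of_generating_coefficients(self):
        pairs = [(pc, pt) for pc in (3, 4, 6, 8, 12) for pt in (3, 4, 6, 8, 12)]
        y = [_table1_l100_response(pc, pt) for pc, pt in pairs]
        fit = fit_diameter_regression(self._frame(pairs, y))
        assert fit.coefficients == pytest.approx((70436.7, -2700.8, -1266.1, 4632.9), abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_response(self):
        pairs = [(pc, pt) for pc in (3, 4, 6) for pt in (3, 4)]
        fit = fit_diameter_regression(self._frame(pairs, [7.0] * len(pairs)))
        assert fit.coefficients[0] == pytest.approx(7.0, abs=1e-10)
        assert fit.coefficients[1:] == pytest.approx((0.0, 0.0, 0.0), abs=1e-10)
        assert fit.r_squared == 0.0

    def test_p_values_match_textbook_ols(self, rng):
        pairs = [(3, 3), (3, 8), (6, 4), (8, 3), (8, 8), (12, 6)]
        y = [100.0 - 2 * pc - pt + 5 * pc / pt + e for (pc, pt), e in
             zip(pairs, rng.normal(0, 3, 6))]
        fit = fit_diameter_regression(self._frame(pairs, y))
        pc = np.array([p for p, _ in pairs], dtype=float)
        pt = np.array([t for _, t in pairs], dtype=float)
        X = np.column_stack([np.ones(6), pc, pt, pc / pt])
        beta, pvals = _ols_oracle(X, np.asarray(y))
        assert fit.coefficients == pytest.approx(tuple(beta), rel=1e-10)
        assert fit.p_values == pytest.approx(tuple(pvals), rel=1e-8)

    def test_matches_normal_equations_on_random_designs(self, rng):
        for _ in range(20):
            pc = rng.integers(2, 15, 12).astype(float)
            pt = rng.integers(2, 15, 12).astype(float)
            if np.unique(pc).size < 3 or np.unique(pt).size < 3:
                continue
            y = rng.normal(0, 1, 12) + pc - pt
            X = np.column_stack([np.ones(12), pc, pt, pc / pt])
            if np.linalg.matrix_rank(X) < 4:
                continue
            df = pd.DataFrame({"phi_cis": pc, "phi_trans": pt, "tau_mean": y, "tau_sd": 1.0})
            fit = fit_diameter_regression(df)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert fit.coefficients == pytest.approx(tuple(beta), abs=1e-10)

    def test_log_sigma_response_uses_log_of_sd(self):
        pairs = [(pc, pt) for pc in (3, 6, 12) for pt in (3, 6, 12)]
        sds = [math.exp(2.0 - 0.1 * pc + 0.05 * pt) for pc, pt in pairs]
        fit = fit_diameter_regression(
            self._frame(pairs, [0.0] * len(pairs), sds), response="LOG_SIGMA"
        )
        assert fit.coefficients == pytest.approx((2.0, -0.1, 0.05, 0.0), abs=1e-9)
        fit10 = fit_diameter_regression(
            self._frame(pairs, [0.0] * len(pairs), sds), response="LOG_SIGMA", log_base="10"
        )
        assert fit10.coefficients[1] == pytest.approx(-0.1 / math.log(10), abs=1e-9)

    def test_model_std_error_and_cov_definitions(self, rng):
        pairs = [(pc, pt) for pc in (3, 4, 6, 8) for pt in (3, 4, 6)]
        y = np.array([_table1_l100_response(pc, pt) for pc, pt in pairs])
        y = y + rng.normal(0, 500, len(y))
        fit = fit_diameter_regression(self._frame(pairs, y))
        X = np.column_stack(
            [np.ones(len(pairs))]
            + [np.array(v, dtype=float) for v in zip(*[(pc, pt, pc / pt) for pc, pt in pairs])]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        sse = float(np.sum((y - X @ beta) ** 2))
        assert fit.model_std_error == pytest.approx(math.sqrt(sse / (len(pairs) - 4)), rel=1e-10)
        assert fit.cov == pytest.approx(fit.model_std_error / np.mean(y), rel=1e-10)

    def test_rank_deficient_design_names_columns(self):
        pairs = [(6, pt) for pt in (3, 4, 6, 8, 12, 5)]
        with pytest.raises(FitError, match="phi_cis"):
            fit_diameter_regression(self._frame(pairs, list(range(6))))

    def test_too_few_rows(self):
        pairs = [(3, 3), (4, 4), (6, 6), (8, 8), (12, 12)]
        with pytest.raises(FitError):
            fit_diameter_regression(self._frame(pairs, [1, 2, 3, 4, 5]))
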