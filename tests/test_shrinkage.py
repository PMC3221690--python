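"""Log-chi-square moments, the additive log-variance fit, and the
positive-part shrinkage estimators against a literal transcription oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shrinkf import (
    LogChiSquareMoments,
    additive_fit,
    center_log_variances,
    log_chisq_moments,
    shrink,
    shrink_cui,
)

EULER = 0.5772156649015329
PI2_6 = math.pi**2 / 6


class TestMoments:
    def test_df2_closed_form(self):
        m = log_chisq_moments(2)
        assert m.m == pytest.approx(-EULER, abs=1e-12)
        assert m.s2 == pytest.approx(PI2_6, abs=1e-12)

    def test_df4_closed_form(self):
        m = log_chisq_moments(4)
        assert m.m == pytest.approx(-0.2703628, abs=1e-6)
        assert m.s2 == pytest.approx(PI2_6 - 1.0, abs=1e-12)

    def test_limits_monotone_to_zero(self):
        dfs = [2, 10, 1e3, 1e6]
        ms = [log_chisq_moments(df).m for df in dfs]
        s2s = [log_chisq_moments(df).s2 for df in dfs]
        assert all(a < b < 0 for a, b in zip(ms, ms[1:]))
        assert all(a > b > 0 for a, b in zip(s2s, s2s[1:]))

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError):
            log_chisq_moments(0)


class TestCenterLogVariances:
    def test_exp_m_maps_to_zero(self):
        mom = log_chisq_moments(2)
        X = center_log_variances(np.full((3, 2), math.exp(mom.m)), mom)
        np.testing.assert_allclose(X, 0.0, atol=1e-12)

    def test_unit_variance_df2(self):
        mom = log_chisq_moments(2)
        X = center_log_variances(np.ones((2, 2)), mom)
        np.testing.assert_allclose(X, EULER, atol=1e-9)

    def test_unbiased_on_log_scale(self):
        # many chi-square draws with true sigma^2 = 4, nu = 2
        rng = np.random.default_rng(5)
        nu, sigma2 = 2, 4.0
        gv = sigma2 * rng.chisquare(nu, size=(20000, 1)) / nu
        mom = log_chisq_moments(nu)
        X = center_log_variances(gv, mom)
        se = np.sqrt(mom.s2 / X.size)
        assert abs(X.mean() - math.log(sigma2)) < 4 * se


class TestAdditiveFit:
    def test_constant_matrix(self):
        fit = additive_fit(np.full((4, 3), 2.5))
        assert fit.mu_hat == pytest.approx(2.5)
        np.testing.assert_allclose(fit.alpha_hat, 0.0, atol=1e-12)
        np.testing.assert_allclose(fit.beta_hat, 0.0, atol=1e-12)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-20)

    def test_worked_two_by_two(self):
        fit = additive_fit(np.array([[0.0, 2.0], [1.0, 5.0]]))
        assert fit.mu_hat == pytest.approx(2.0)
        np.testing.assert_allclose(fit.alpha_hat, [-1.0, 1.0])
        np.testing.assert_allclose(fit.beta_hat, [-1.5, 1.5])
        assert fit.residual_ss == pytest.approx(1.0)

    def test_exactly_additive_has_zero_residual(self):
        a = np.array([0.3, -1.0, 2.0])[:, None]
        b = np.array([1.0, -0.5])[None, :]
        fit = additive_fit(a + b)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-20)
        assert np.sum(fit.alpha_hat) == pytest.approx(0.0, abs=1e-12)
        assert np.sum(fit.beta_hat) == pytest.approx(0.0, abs=1e-12)


def transcription_oracle(target, gv, mom):
    """Literal term-by-term transcription of the published estimators."""
    I, K = gv.shape
    X = np.log(gv) - mom.m
    mu = X.mean()
    alpha = X.mean(axis=1) - mu
    beta = X.mean(axis=0) - mu
    out = np.empty((I, K))
    if target == "gen":
        c = I * K - (I + K - 1) - 2
        S = sum((X[i, k] - mu - alpha[i] - beta[k]) ** 2 for i in range(I) for k in range(K))
        f = max(0.0, 1.0 - c * mom.s2 / S)
        for i in range(I):
            for k in range(K):
                xhat = mu + alpha[i] + beta[k]
                out[i, k] = math.exp(mom.m + xhat + f * (X[i, k] - xhat))
    elif target == "gene":
        c = I * K - (I - 1) - 2
        S = sum((X[i, k] - mu - alpha[i]) ** 2 for i in range(I) for k in range(K))
        f = max(0.0, 1.0 - c * mom.s2 / S)
        for i in range(I):
            for k in range(K):
                out[i, k] = math.exp(mom.m + mu + alpha[i]) * math.exp(f * (X[i, k] - mu - alpha[i]))
    elif target == "group":
        c = I * K - (K - 1) - 2
        S = sum((X[i, k] - mu - beta[k]) ** 2 for i in range(I) for k in range(K))
        f = max(0.0, 1.0 - c * mom.s2 / S)
        for i in range(I):
            for k in range(K):
                out[i, k] = math.exp(mom.m + mu + beta[k]) * math.exp(f * (X[i, k] - mu - beta[k]))
    elif target == "common":
        c = I * K - 3
        S = sum((X[i, k] - mu) ** 2 for i in range(I) for k in range(K))
        f = max(0.0, 1.0 - c * mom.s2 / S)
        for i in range(I):
            for k in range(K):
                out[i, k] = math.exp(mom.m + mu) * math.exp(f * (X[i, k] - mu))
    return out


def cui_transcription_oracle(mse, mom):
    I = len(mse)
    X = np.log(mse) - mom.m
    xbar = X.mean()
    S = sum((x - xbar) ** 2 for x in X)
    f = max(0.0, 1.0 - (I - 3) * mom.s2 / S)
    return np.array([math.exp(mom.m + xbar) * math.exp(f * (x - xbar)) for x in X])


class TestShrink:
    @pytest.mark.parametrize("target", ["gen", "gene", "group", "common"])
    def test_matches_transcription_oracle(self, target):
        rng = np.random.default_rng(3)
        mom = log_chisq_moments(2)
        for I, K in [(6, 2), (5, 3), (4, 2)]:
            gv = rng.lognormal(0.0, 1.0, size=(I, K))
            table = shrink(target, gv, mom)
            np.testing.assert_allclose(table.values, transcription_oracle(target, gv, mom),
                                       rtol=1e-12)

    def test_full_shrinkage_collapses_to_target(self):
        # nearly additive table: S below c*s2 forces f = 0
        mom = log_chisq_moments(2)
        gv = np.exp(np.add.outer(np.linspace(-0.1, 0.1, 6), [0.0, 0.2]) + mom.m)
        table = shrink("gen", gv, mom)
        assert table.shrinkage_factor == 0.0
        X = np.log(gv) - mom.m
        mu = X.mean()
        fitted = X.mean(1, keepdims=True) + X.mean(0, keepdims=True) - mu
        np.testing.assert_allclose(table.values, np.exp(mom.m + fitted), rtol=1e-12)

    def test_zero_s2_limit_is_identity(self):
        # with s2 = 0 the factor is 1 and the raw estimates come back
        mom = LogChiSquareMoments(df=np.inf, m=0.0, s2=0.0)
        rng = np.random.default_rng(9)
        gv = rng.lognormal(0.0, 1.0, size=(8, 2))
        for target in ("gen", "gene", "group", "common"):
            table = shrink(target, gv, mom)
            assert table.shrinkage_factor == pytest.approx(1.0)
            np.testing.assert_allclose(table.values, gv, rtol=1e-12)

    def test_log_scale_between_target_and_raw(self):
        rng = np.random.default_rng(21)
        mom = log_chisq_moments(2)
        gv = rng.lognormal(0.0, 2.0, size=(30, 2))
        table = shrink("common", gv, mom)
        X = np.log(gv) - mom.m
        mu = X.mean()
        lo = np.minimum(mom.m + mu, mom.m + X)
        hi = np.maximum(mom.m + mu, mom.m + X)
        logv = np.log(table.values)
        assert np.all(logv >= lo - 1e-12) and np.all(logv <= hi + 1e-12)

    def test_shrinkage_dominates_raw_under_common_truth(self):
        """With all true variances equal, shrunken log variances have
        smaller mean squared error than the raw ones (Stein dominance)."""
        rng = np.random.default_rng(14)
        mom = log_chisq_moments(2)
        wins = 0
        for _ in range(100):
            gv = rng.chisquare(2, size=(100, 2)) / 2
            table = shrink("gen", gv, mom)
            mse_shrunk = np.mean(np.log(table.values) ** 2)  # true log sigma^2 = 0
            mse_raw = np.mean(np.log(gv) ** 2)
            wins += mse_shrunk < mse_raw
        assert wins > 95

    def test_zero_variance_guard(self):
        mom = log_chisq_moments(2)
        gv = np.ones((6, 2))
        gv[0, 0] = 0.0
        table = shrink("gen", gv, mom)
        assert np.all(np.isfinite(table.values)) and np.all(table.values > 0)


class TestShrinkCui:
    def test_matches_transcription_oracle(self):
        rng = np.random.default_rng(8)
        mom = log_chisq_moments(8)
        mse = rng.lognormal(0.0, 1.5, size=6)
        table = shrink_cui(mse, mom)
        np.testing.assert_allclose(table.values, cui_transcription_oracle(mse, mom), rtol=1e-12)

    def test_equal_mse_returns_raw(self):
        mom = log_chisq_moments(8)
        table = shrink_cui(np.full(10, 3.7), mom)
        np.testing.assert_allclose(table.values, 3.7, rtol=1e-12)

    def test_small_dispersion_full_shrinkage(self):
        mom = log_chisq_moments(8)
        mse = np.exp(np.linspace(-0.01, 0.01, 10))
        table = shrink_cui(mse, mom)
        assert table.shrinkage_factor == 0.0
        assert np.ptp(table.values) == pytest.approx(0.0, abs=1e-12)

    def test_tracks_true_variances_better_than_full_shrinkage(self):
        rng = np.random.default_rng(30)
        mom = log_chisq_moments(8)
        true = rng.lognormal(0.0, 2.0, size=100)
        mse = true * rng.chisquare(8, size=100) / 8
        table = shrink_cui(mse, mom)
        corr = np.corrcoef(np.log(table.values), np.log(true))[0, 1]
        assert corr > 0.8  # full shrinkage would give corr = nan/0

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            shrink_cui(np.ones(3), log_chisq_moments(8))


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 10_000), st.sampled_from(["gen", "gene", "group", "common"]))
def test_positive_part_property(seed, target):
    """Shrinkage factor always lies in [0, 1]; outputs strictly positive."""
    rng = np.random.default_rng(seed)
    gv = rng.lognormal(0.0, rng.uniform(0.1, 3.0), size=(rng.integers(4, 12), 2))
    table = shrink(target, gv, log_chisq_moments(2))
    assert 0.0 <= table.shrinkage_factor <= 1.0
    assert np.all(table.values > 0)
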