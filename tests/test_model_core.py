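import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seasonfit.exceptions import SingularDesignError
from seasonfit.model_core import (
    BayesianHarmonicAR,
    ModelParams,
    PosteriorDraws,
    SamplerConfig,
    ar_transform,
    coef_posterior_mean,
    credible_interval,
    design_matrix,
    design_row,
    deviance,
    dic,
    gibbs_fit,
)
from seasonfit.synthetic_data import GeneratorSpec, generate_series, mean_curve


# --------------------------------------------------------------------------
# design matrix
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "t, expected",
    [
        (12, [1, 12, 0, 1]),
        (3, [1, 3, 1, 0]),
        (6, [1, 6, 0, -1]),
        (9, [1, 9, -1, 0]),
    ],
)
def test_design_row_harmonic_values(t, expected):
    assert design_row(t) == pytest.approx(expected, abs=1e-12)


def test_design_matrix_periodicity():
    t = np.arange(1, 25)
    X = design_matrix(t)
    assert X[:12, 2:] == pytest.approx(X[12:, 2:], abs=1e-12)


# --------------------------------------------------------------------------
# Prais-Winsten transform
# --------------------------------------------------------------------------

def test_ar_transform_identity_at_zero_rho():
    rng = np.random.default_rng(0)
    y = rng.normal(size=10)
    X = design_matrix(np.arange(1, 11))
    ys, Xs = ar_transform(y, X, 0.0)
    assert ys == pytest.approx(y)
    assert Xs == pytest.approx(X)


def test_ar_transform_constant_series_halves():
    y = np.full(8, 4.0)
    X = np.ones((8, 2)) * 3.0
    ys, Xs = ar_transform(y, X, 0.5)
    assert ys[1:] == pytest.approx(0.5 * y[1:])
    assert Xs[1:] == pytest.approx(0.5 * X[1:])
    # first row untransformed (dropped later by the conditional fitter)
    assert ys[0] == 4.0 and Xs[0] == pytest.approx(X[0])


def test_ar_transform_matches_elementwise_formula():
    rng = np.random.default_rng(7)
    y = rng.normal(size=6)
    X = rng.normal(size=(6, 3))
    rho = -0.37
    ys, Xs = ar_transform(y, X, rho)
    for t in range(1, 6):
        assert ys[t] == pytest.approx(y[t] - rho * y[t - 1])
        assert Xs[t] == pytest.approx(X[t] - rho * X[t - 1])


def test_ar_transform_rejects_nonstationary_rho():
    y = np.zeros(5)
    X = np.zeros((5, 2))
    with pytest.raises(ValueError):
        ar_transform(y, X, 1.0)


# --------------------------------------------------------------------------
# credible intervals
# --------------------------------------------------------------------------

def test_credible_interval_constant_draws():
    assert credible_interval(np.full(100, 3.5)) == (3.5, 3.5)


def test_credible_interval_standard_normal():
    draws = np.random.default_rng(1).standard_normal(100_000)
    lo, hi = credible_interval(draws, 0.95)
    assert lo == pytest.approx(-1.96, abs=0.02)
    assert hi == pytest.approx(1.96, abs=0.02)


def test_credible_interval_uniform_half_level():
    draws = np.random.default_rng(2).uniform(size=100_000)
    lo, hi = credible_interval(draws, 0.5)
    assert lo == pytest.approx(0.25, abs=0.01)
    assert hi == pytest.approx(0.75, abs=0.01)


def test_credible_interval_rejects_empty():
    with pytest.raises(ValueError):
        credible_interval(np.array([]))


# --------------------------------------------------------------------------
# Gibbs sampler
# --------------------------------------------------------------------------

def test_gibbs_vanishing_noise_recovers_exact_curve():
    """With near-zero noise and rho=0 the posterior collapses on the truth."""
    params = ModelParams(10.0, 0.05, 1.2, -0.8, 0.0, 1e-4)
    series = generate_series(GeneratorSpec(params, n_months=48, seed=3))
    draws = gibbs_fit(series, SamplerConfig(n_iterations=2000, burn_in=200, seed=0))
    means = draws.theta().mean(axis=0)
    assert means == pytest.approx(params.theta, abs=1e-2)


def test_gibbs_recovery_within_three_posterior_sd(men_params, men_series, men_draws):
    truth = {
        "beta0": men_params.beta0,
        "beta1": men_params.beta1,
        "eta1": men_params.eta1,
        "eta2": men_params.eta2,
        "rho": men_params.rho,
    }
    for name, value in truth.items():
        col = men_draws.draws[name]
        assert abs(col.mean() - value) < 3 * col.std(), name


def test_gibbs_reproducible_from_seed(men_series):
    config = SamplerConfig(n_iterations=300, burn_in=50, seed=123)
    d1 = gibbs_fit(men_series, config)
    d2 = gibbs_fit(men_series, config)
    pd.testing.assert_frame_equal(d1.draws, d2.draws)


def test_gibbs_draws_respect_support(men_draws):
    rho = men_draws.draws["rho"].to_numpy()
    assert np.all(np.abs(rho) < 1.0)
    assert np.all(men_draws.draws["sigma2_eps"].to_numpy() > 0.0)
    assert len(men_draws) == men_draws.config.n_iterations


def test_gibbs_rejects_short_and_nonfinite_series():
    with pytest.raises(ValueError):
        gibbs_fit(np.ones(10), SamplerConfig(n_iterations=10, burn_in=0))
    bad = np.ones(30)
    bad[5] = np.nan
    with pytest.raises(ValueError):
        gibbs_fit(bad, SamplerConfig(n_iterations=10, burn_in=0))


def test_gibbs_constant_series_is_singular():
    with pytest.raises(SingularDesignError):
        gibbs_fit(np.full(36, 7.0), SamplerConfig(n_iterations=10, burn_in=0))


def test_ols_limit_posterior_mean_matches_normal_equations():
    """Fixed rho=0 and a flat prior make the coefficient posterior mean the
    full-sample least-squares solution, independent of sigma^2."""
    params = ModelParams(20.0, 0.1, 1.0, -2.0, 0.0, 1.5)
    series = generate_series(GeneratorSpec(params, n_months=60, seed=9))
    t = series.t_index
    exact = coef_posterior_mean(series.y, t, rho=0.0, prior_coef_sd=np.inf)
    X = design_matrix(t.astype(float))
    ols, *_ = np.linalg.lstsq(X, series.y, rcond=None)
    assert exact == pytest.approx(ols, rel=1e-6)
    # sigma^2 does not move the conditional mean under a flat prior
    assert coef_posterior_mean(series.y, t, 0.0, np.inf, sigma2=42.0) == pytest.approx(
        exact, rel=1e-12
    )
    # and the sampled posterior mean agrees at Monte Carlo accuracy
    config = SamplerConfig(
        n_iterations=4000, burn_in=400, seed=4, fix_rho=0.0, prior_coef_sd=np.inf
    )
    draws = gibbs_fit(series, config)
    sampled = draws.theta().mean(axis=0)
    scale = np.maximum(np.abs(ols), 0.05)
    assert np.all(np.abs(sampled - ols) / scale < 0.05)


# --------------------------------------------------------------------------
# DIC
# --------------------------------------------------------------------------

def _degenerate_draws(theta, rho, sigma2, n=50):
    df = pd.DataFrame(
        np.tile(np.r_[theta, rho, sigma2], (n, 1)),
        columns=["beta0", "beta1", "eta1", "eta2", "rho", "sigma2_eps"],
    )
    return PosteriorDraws(draws=df, config=SamplerConfig(n_iterations=n, burn_in=0))


def test_dic_degenerate_posterior_has_zero_pd(men_series):
    theta = np.array([29.0, 0.03, -1.5, -1.6])
    draws = _degenerate_draws(theta, 0.3, 1.1)
    dic_val, p_d = dic(draws, men_series)
    assert p_d == pytest.approx(0.0, abs=1e-8)
    point = np.r_[theta, 0.3, 1.1]
    assert dic_val == pytest.approx(deviance(point, men_series), rel=1e-12)


def test_deviance_matches_gaussian_log_density(men_series):
    """Deviance equals -2x the exact stationary AR(1) Gaussian log
    likelihood: a N(0, sigma^2/(1-rho^2)) term for the first residual plus
    N(0, sigma^2) terms for the quasi-differenced innovations."""
    theta = np.array([28.5, 0.03, -1.4, -1.7])
    rho, sigma2 = 0.4, 1.3
    y = men_series.y
    u = y - design_matrix(men_series.t_index.astype(float)) @ theta
    eps = u[1:] - rho * u[:-1]
    expected = -2.0 * (
        stats.norm.logpdf(u[0], scale=np.sqrt(sigma2 / (1 - rho**2)))
        + stats.norm.logpdf(eps, scale=np.sqrt(sigma2)).sum()
    )
    assert deviance(np.r_[theta, rho, sigma2], men_series) == pytest.approx(
        expected, rel=1e-10
    )
    # conditional variant drops the stationary term
    expected_cond = -2.0 * stats.norm.logpdf(eps, scale=np.sqrt(sigma2)).sum()
    assert deviance(
        np.r_[theta, rho, sigma2], men_series, conditional_on=1
    ) == pytest.approx(expected_cond, rel=1e-10)


# --------------------------------------------------------------------------
# sklearn estimator surface
# --------------------------------------------------------------------------

def test_estimator_fits_and_predicts(men_params, men_series):
    est = BayesianHarmonicAR(n_iterations=800, burn_in=100, random_state=0)
    t = men_series.t_index.reshape(-1, 1).astype(float)
    fitted = est.fit(t, men_series.y)
    assert fitted is est
    assert est.coef_.shape == (3,)
    assert abs(est.rho_[0]) < 1.0
    pred = est.predict(t)
    truth = mean_curve(men_params, men_series.t_index)
    assert np.sqrt(np.mean((pred - truth) ** 2)) < 1.0
    # params round-trip through the sklearn interface
    clone_params = est.get_params()
    assert clone_params["n_iterations"] == 800
    est.set_params(n_iterations=500)
    assert est.n_iterations == 500


def test_estimator_requires_fit_before_predict():
    est = BayesianHarmonicAR()
    with pytest.raises(AttributeError):
        est.predict(np.arange(1, 25.0))


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

def test_model_params_validation():
    with pytest.raises(ValueError):
        ModelParams(0, 0, 0, 0, rho=1.2, sigma_eps=1.0)
    with pytest.raises(ValueError):
        ModelParams(0, 0, 0, 0, rho=0.5, sigma_eps=-1.0)
    with pytest.raises(ValueError):
        ModelParams(0, 0, 0, 0, rho=0.6, sigma_eps=1.0, rho2=0.7)  # outside triangle


def test_sampler_config_validation():
    with pytest.raises(ValueError):
        SamplerConfig(n_iterations=0)
    with pytest.raises(ValueError):
        SamplerConfig(ar_order=3)
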