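"""Bayesian linear-trend + annual-harmonic regression with AR(p) errors.

The model for a monthly per-day average series y_t, t = 1..n, is

    y_t = beta0 + beta1 * t + eta1 * sin(2*pi*t/12) + eta2 * cos(2*pi*t/12) + e_t
    e_t = rho * e_{t-1} + eps_t,        eps_t ~ Normal(0, sigma_eps^2)

(optionally an AR(2) recursion e_t = rho1 e_{t-1} + rho2 e_{t-2} + eps_t).
Estimation follows the Prais-Winsten idea of quasi-differencing the data by
the AR coefficient, embedded in a Gibbs sampler with three blocks:

1. regression coefficients theta = (beta0, beta1, eta1, eta2) from their
   conjugate Gaussian conditional on the quasi-differenced data,
2. the AR coefficient(s) from the Gaussian conditional of the lag regression
   of the residuals u_t = y_t - x_t' theta, truncated to the stationarity
   region by rejection,
3. the innovation variance sigma_eps^2 from its inverse-gamma conditional.

For AR(1) errors the first observation is kept with the full Prais-Winsten
weight sqrt(1-rho^2) (the exact stationary likelihood).  Dropping it
instead leaves a spurious posterior ridge at rho -> 1 where
quasi-differencing destroys the identifiability of the intercept under a
vague prior; the stationary term removes that ridge and pins the level.
The rho block then needs a Metropolis correction for the first-observation
factor, with the truncated Gaussian lag-regression conditional as the
proposal.  For AR(2) the likelihood conditions on the first two
observations (pure Gibbs).  The deviance used for DIC matches the fitted
likelihood; cross-order comparisons evaluate both models on a common
conditioning set (see :func:`dic` and :func:`compare_ar_orders`).

Priors are deliberately vague: independent Normal(0, prior_coef_sd^2) on the
coefficients (default SD 1000), Inverse-Gamma(0.001, 0.001) on sigma_eps^2,
and uniform over the stationarity region on the AR coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import RhoSamplingError, SingularDesignError
from .ingest import MonthlySeries

OMEGA = 2.0 * np.pi / 12.0  # annual angular frequency on a monthly grid

_MIN_SERIES_LENGTH = 24  # two full seasonal cycles
_RHO_REJECTION_CAP = 1000


@dataclass(frozen=True)
class ModelParams:
    """Generative parameter set: intercept and trend (events/day and
    events/day per month), harmonic coefficients, AR coefficient(s) and
    innovation SD."""

    beta0: float
    beta1: float
    eta1: float
    eta2: float
    rho: float
    sigma_eps: float
    rho2: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be non-negative")
        if not _is_stationary(np.array([self.rho, self.rho2])[: 2 if self.rho2 else 1]):
            raise ValueError("AR coefficients outside the stationarity region")

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.eta1, self.eta2])


@dataclass(frozen=True)
class SamplerConfig:
    """Gibbs sampler settings.

    Defaults are desk-scale (20,000 draws after 2,000 burn-in); the
    long-run protocol of 500,000 draws after 10,000 burn-in is available
    via :func:`longrun_protocol`.  ``fix_rho`` pins the AR coefficient
    (e.g. 0.0 for the independent-errors limit) instead of sampling it.
    """

    n_iterations: int = 20_000
    burn_in: int = 2_000
    seed: int = 0
    ar_order: int = 1
    prior_coef_sd: float = 1000.0
    prior_sigma2_shape: float = 0.001
    prior_sigma2_rate: float = 0.001
    fix_rho: float | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.ar_order not in (1, 2):
            raise ValueError("ar_order must be 1 or 2")
        if self.prior_coef_sd <= 0:
            raise ValueError("prior_coef_sd must be positive (np.inf allowed)")
        if self.prior_sigma2_shape <= 0 or self.prior_sigma2_rate <= 0:
            raise ValueError("inverse-gamma prior parameters must be positive")


def longrun_protocol(seed: int = 0, ar_order: int = 1) -> SamplerConfig:
    """The long-run sampler protocol: 500,000 draws after 10,000 burn-in."""
    return SamplerConfig(n_iterations=500_000, burn_in=10_000, seed=seed, ar_order=ar_order)


@dataclass
class PosteriorDraws:
    """Post-burn-in joint draws, one row per iteration.

    Columns: beta0, beta1, eta1, eta2, rho (and rho2 for AR(2)), sigma2_eps.
    """

    draws: pd.DataFrame
    config: SamplerConfig

    def __len__(self) -> int:
        return len(self.draws)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.draws.columns)

    def theta(self) -> np.ndarray:
        return self.draws[["beta0", "beta1", "eta1", "eta2"]].to_numpy()

    def rho(self) -> np.ndarray:
        cols = ["rho", "rho2"] if "rho2" in self.draws else ["rho"]
        return self.draws[cols].to_numpy()

    def sigma2(self) -> np.ndarray:
        return self.draws["sigma2_eps"].to_numpy()


@dataclass
class FitSummary:
    """Posterior means, equal-tailed 95% intervals and derived summaries."""

    mean: dict[str, float]
    ci: dict[str, tuple[float, float]]
    amplitude_plugin: float
    amplitude_posterior: float
    peak_month: float
    dic: float
    p_d: float
    config: SamplerConfig

    def to_dict(self) -> dict:
        return {
            "parameters": {
                name: {
                    "mean": self.mean[name],
                    "ci_lower": self.ci[name][0],
                    "ci_upper": self.ci[name][1],
                }
                for name in self.mean
            },
            "amplitude_plugin": self.amplitude_plugin,
            "amplitude_posterior": self.amplitude_posterior,
            "peak_month": self.peak_month,
            "dic": self.dic,
            "p_d": self.p_d,
            "config": {
                "n_iterations": self.config.n_iterations,
                "burn_in": self.config.burn_in,
                "seed": self.config.seed,
                "ar_order": self.config.ar_order,
                "prior_coef_sd": self.config.prior_coef_sd,
                "prior_sigma2_shape": self.config.prior_sigma2_shape,
                "prior_sigma2_rate": self.config.prior_sigma2_rate,
                "fix_rho": self.config.fix_rho,
            },
        }


def _is_stationary(rho: np.ndarray) -> bool:
    rho = np.atleast_1d(rho)
    if rho.size == 1:
        return abs(rho[0]) < 1.0
    r1, r2 = rho
    return (r2 + r1 < 1.0) and (r2 - r1 < 1.0) and (abs(r2) < 1.0)


def design_row(t: float) -> np.ndarray:
    """Design vector [1, t, sin(2*pi*t/12), cos(2*pi*t/12)]."""
    return np.array([1.0, t, np.sin(OMEGA * t), np.cos(OMEGA * t)])


def design_matrix(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.column_stack(
        [np.ones_like(t), t, np.sin(OMEGA * t), np.cos(OMEGA * t)]
    )


def ar_transform(y: np.ndarray, X: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Prais-Winsten quasi-differencing by a single AR(1) coefficient.

    Rows t >= 2 become y_t - rho*y_{t-1} (and likewise for X); the first
    row is returned untransformed — the sampler applies the stationary
    sqrt(1-rho^2) weight to it separately.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if abs(rho) >= 1.0:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of rows")
    y_star = y.copy()
    X_star = X.copy()
    y_star[1:] = y[1:] - rho * y[:-1]
    X_star[1:] = X[1:] - rho * X[:-1]
    return y_star, X_star


def _quasi_diff(v: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Quasi-difference by AR coefficients and drop the first len(rho) rows."""
    p = len(rho)
    out = v[p:].astype(float).copy()
    for j, r in enumerate(rho, start=1):
        out -= r * v[p - j : v.shape[0] - j]
    return out


def _pw_transform(y: np.ndarray, X: np.ndarray, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Transformed regression rows for the AR error model.

    AR(1): full Prais-Winsten — first row weighted by sqrt(1-rho^2), the
    rest quasi-differenced.  AR(2): conditional — first two rows dropped.
    """
    if len(rho) == 1:
        r = rho[0]
        w = np.sqrt(1.0 - r * r)
        ys = np.concatenate([[w * y[0]], y[1:] - r * y[:-1]])
        Xs = np.vstack([w * X[0], X[1:] - r * X[:-1]])
        return ys, Xs
    return _quasi_diff(y, rho), _quasi_diff(X, rho)


def coef_posterior_mean(
    y: np.ndarray,
    t: np.ndarray,
    rho: float | Sequence[float] = 0.0,
    prior_coef_sd: float = np.inf,
    sigma2: float = 1.0,
) -> np.ndarray:
    """Exact conditional posterior mean of (beta0, beta1, eta1, eta2).

    Computed on the Prais-Winsten-transformed data exactly as inside the
    Gibbs sweep (for AR(1) the first row carries the stationary
    sqrt(1-rho^2) weight, so rho=0 reduces to ordinary least squares on the
    full sample).  With a flat prior (``prior_coef_sd=inf``) the mean is
    the normal-equations solution and is independent of ``sigma2``; when
    rho is held fixed this is the exact marginal posterior mean of the
    coefficients.
    """
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    X = design_matrix(np.asarray(t, dtype=float))
    ys, Xs = _pw_transform(np.asarray(y, dtype=float), X, rho_arr)
    prior_prec = 0.0 if np.isinf(prior_coef_sd) else 1.0 / prior_coef_sd**2
    A = Xs.T @ Xs / sigma2 + prior_prec * np.eye(X.shape[1])
    b = Xs.T @ ys / sigma2
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError("transformed design is rank-deficient") from exc
    return solve_triangular(L.T, solve_triangular(L, b, lower=True), lower=False)


def _run_gibbs(t: np.ndarray, y: np.ndarray, config: SamplerConfig) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed)
    n = y.size
    p = config.ar_order
    X = design_matrix(t)
    k = X.shape[1]

    if np.linalg.matrix_rank(X) < k:
        raise SingularDesignError("design matrix is rank-deficient")

    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    if float(resid @ resid) <= 1e-12 * max(1.0, float(y @ y)):
        # e.g. a constant series: zero residual variance degenerates every
        # conditional, so fail loudly rather than regularise
        raise SingularDesignError("response is perfectly fit by the mean curve")
    sigma2 = float(resid @ resid) / max(n - k, 1)
    rho = np.zeros(p)
    if config.fix_rho is not None:
        rho[:] = config.fix_rho
        if not _is_stationary(rho):
            raise ValueError("fix_rho outside the stationarity region")

    prior_prec = 0.0 if np.isinf(config.prior_coef_sd) else config.prior_coef_sd**-2
    a0 = config.prior_sigma2_shape
    b0 = config.prior_sigma2_rate
    eye = np.eye(k)

    total = config.burn_in + config.n_iterations
    names = ["beta0", "beta1", "eta1", "eta2", "rho"] + (["rho2"] if p == 2 else [])
    out = np.empty((config.n_iterations, k + p + 1))

    def log_first_obs_factor(r: float, u0: float, s2: float) -> float:
        # stationary density factor of the first observation as a function
        # of rho: sqrt(1-r^2) * exp(-(1-r^2) u0^2 / (2 s2))
        return 0.5 * np.log1p(-r * r) - (1.0 - r * r) * u0 * u0 / (2.0 * s2)

    for it in range(total):
        # -- block 1: regression coefficients ---------------------------
        ys, Xs = _pw_transform(y, X, rho)
        A = Xs.T @ Xs / sigma2 + prior_prec * eye
        b = Xs.T @ ys / sigma2
        try:
            L = np.linalg.cholesky(A)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError("transformed design is rank-deficient") from exc
        m = solve_triangular(L.T, solve_triangular(L, b, lower=True), lower=False)
        theta = m + solve_triangular(L.T, rng.standard_normal(k), lower=False)

        # -- block 2: AR coefficient(s) ---------------------------------
        u = y - X @ theta
        Z = np.column_stack([u[p - j : n - j] for j in range(1, p + 1)])
        target = u[p:]
        if config.fix_rho is None:
            G = Z.T @ Z
            if np.linalg.cond(G) > 1e12 or not np.all(np.isfinite(G)):
                raise SingularDesignError("degenerate residual lag regression")
            mean_rho = np.linalg.solve(G, Z.T @ target)
            Lr = np.linalg.cholesky(np.linalg.inv(G) * sigma2)
            for attempt in range(_RHO_REJECTION_CAP):
                cand = mean_rho + Lr @ rng.standard_normal(p)
                if _is_stationary(cand):
                    break
            else:
                raise RhoSamplingError(
                    f"no stationary AR draw in {_RHO_REJECTION_CAP} attempts"
                )
            if p == 1:
                # Metropolis step: the truncated Gaussian lag-regression
                # conditional is the proposal; the stationary
                # first-observation factor is the correction.
                log_ratio = log_first_obs_factor(
                    cand[0], u[0], sigma2
                ) - log_first_obs_factor(rho[0], u[0], sigma2)
                if np.log(rng.uniform()) < log_ratio:
                    rho = cand
            else:
                rho = cand

        # -- block 3: innovation variance -------------------------------
        eps = target - Z @ rho
        ss = float(eps @ eps)
        n_terms = n - p
        if p == 1:
            ss += (1.0 - rho[0] ** 2) * u[0] ** 2
            n_terms = n
        shape = a0 + 0.5 * n_terms
        rate = b0 + 0.5 * ss
        sigma2 = rate / rng.gamma(shape)

        if it >= config.burn_in:
            out[it - config.burn_in, :k] = theta
            out[it - config.burn_in, k : k + p] = rho
            out[it - config.burn_in, k + p] = sigma2

    return pd.DataFrame(out, columns=names + ["sigma2_eps"])


def gibbs_fit(series: MonthlySeries | np.ndarray, config: SamplerConfig | None = None) -> PosteriorDraws:
    """Fit the model by Gibbs sampling; fully reproducible from config.seed."""
    config = config or SamplerConfig()
    y = series.y if isinstance(series, MonthlySeries) else np.asarray(series, dtype=float)
    if y.size < _MIN_SERIES_LENGTH:
        raise ValueError(
            f"series must span at least {_MIN_SERIES_LENGTH} months, got {y.size}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    t = np.arange(1, y.size + 1, dtype=float)
    draws = _run_gibbs(t, y, config)
    return PosteriorDraws(draws=draws, config=config)


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed posterior interval at quantiles (1-level)/2, 1-(1-level)/2."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("draws must be non-empty")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _deviance_matrix(
    theta: np.ndarray,
    rho: np.ndarray,
    sigma2: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    conditional_on: int,
) -> np.ndarray:
    """Gaussian AR deviance (-2 log L) for each draw, vectorised.

    ``conditional_on`` is the number of leading observations conditioned
    on; 0 is allowed for AR(1) only and adds the exact stationary term for
    the first observation (matching the fitted likelihood).
    """
    n = y.size
    p = rho.shape[1]
    c = conditional_on
    if c < 0 or (c < p and not (c == 0 and p == 1)):
        raise ValueError(f"conditional_on={c} invalid for AR({p})")
    start = max(c, p)
    U = y[None, :] - theta @ X.T  # draws x n residuals
    eps = U[:, start:].copy()
    for j in range(1, p + 1):
        eps -= rho[:, j - 1 : j] * U[:, start - j : n - j]
    ss = np.einsum("ij,ij->i", eps, eps)
    dev = (n - start) * np.log(2.0 * np.pi * sigma2) + ss / sigma2
    if c == 0 and p == 1:
        v = sigma2 / (1.0 - rho[:, 0] ** 2)
        dev += np.log(2.0 * np.pi * v) + U[:, 0] ** 2 / v
    return dev


def _default_conditioning(ar_order: int) -> int:
    # AR(1) uses the exact stationary likelihood; AR(2) conditions on the
    # first two observations, matching the fitter
    return 0 if ar_order == 1 else 2


def deviance(
    params: ModelParams | Sequence[float],
    series: MonthlySeries | np.ndarray,
    ar_order: int = 1,
    conditional_on: int | None = None,
) -> float:
    """Deviance -2 log L at a single parameter point."""
    y = series.y if isinstance(series, MonthlySeries) else np.asarray(series, dtype=float)
    if isinstance(params, ModelParams):
        theta = params.theta
        rho = np.array([params.rho, params.rho2])[:ar_order]
        sigma2 = params.sigma_eps**2
    else:
        arr = np.asarray(params, dtype=float)
        theta, rho, sigma2 = arr[:4], arr[4 : 4 + ar_order], arr[4 + ar_order]
    if conditional_on is None:
        conditional_on = _default_conditioning(ar_order)
    X = design_matrix(np.arange(1, y.size + 1, dtype=float))
    return float(
        _deviance_matrix(
            theta[None, :], np.atleast_2d(rho), np.atleast_1d(sigma2), y, X,
            conditional_on,
        )[0]
    )


def dic(
    draws: PosteriorDraws,
    series: MonthlySeries | np.ndarray,
    conditional_on: int | None = None,
) -> tuple[float, float]:
    """Deviance information criterion: DIC = mean deviance + pD,
    pD = mean deviance - deviance at the posterior means.

    ``conditional_on`` overrides the number of leading observations
    conditioned on; pass the same value for two fits of different AR order
    to compare them on an identical data window (see
    :func:`compare_ar_orders`).
    """
    y = series.y if isinstance(series, MonthlySeries) else np.asarray(series, dtype=float)
    X = design_matrix(np.arange(1, y.size + 1, dtype=float))
    theta = draws.theta()
    rho = draws.rho()
    sigma2 = draws.sigma2()
    if conditional_on is None:
        conditional_on = _default_conditioning(rho.shape[1])
    dev = _deviance_matrix(theta, rho, sigma2, y, X, conditional_on)
    dev_bar = float(dev.mean())
    dev_at_mean = float(
        _deviance_matrix(
            theta.mean(axis=0, keepdims=True),
            rho.mean(axis=0, keepdims=True),
            np.atleast_1d(sigma2.mean()),
            y,
            X,
            conditional_on,
        )[0]
    )
    p_d = dev_bar - dev_at_mean
    return dev_bar + p_d, p_d


def compare_ar_orders(
    series: MonthlySeries | np.ndarray, config: SamplerConfig | None = None
) -> dict[int, tuple[float, float]]:
    """Fit AR(1) and AR(2) error models and return {order: (DIC, pD)}.

    Both deviances condition on the first two observations so the
    criteria are computed over the same data window.
    """
    config = config or SamplerConfig()
    out: dict[int, tuple[float, float]] = {}
    for order in (1, 2):
        draws = gibbs_fit(series, replace(config, ar_order=order))
        out[order] = dic(draws, series, conditional_on=2)
    return out


def summarize(draws: PosteriorDraws, series: MonthlySeries | np.ndarray, level: float = 0.95) -> FitSummary:
    """Posterior means, credible intervals, seasonal summaries and DIC."""
    from . import seasonality  # local import to avoid a cycle

    mean = {name: float(draws.draws[name].mean()) for name in draws.parameter_names}
    ci = {
        name: credible_interval(draws.draws[name].to_numpy(), level)
        for name in draws.parameter_names
    }
    amp_plugin = seasonality.amplitude(mean["eta1"], mean["eta2"])
    amp_post = float(
        np.hypot(draws.draws["eta1"].to_numpy(), draws.draws["eta2"].to_numpy()).mean()
    )
    peak = seasonality.peak_month(mean["eta1"], mean["eta2"])
    dic_val, p_d = dic(draws, series)
    return FitSummary(
        mean=mean,
        ci=ci,
        amplitude_plugin=amp_plugin,
        amplitude_posterior=amp_post,
        peak_month=peak,
        dic=dic_val,
        p_d=p_d,
        config=draws.config,
    )


class BayesianHarmonicAR(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the harmonic + AR(p) errors model.

    Parameters
    ----------
    ar_order : 1 or 2
        Order of the autoregressive error process.
    n_iterations, burn_in : int
        Post-burn-in Gibbs draws and discarded warm-up iterations.
    prior_coef_sd : float
        SD of the vague Gaussian prior on the regression coefficients
        (np.inf gives a flat prior).
    prior_sigma2_shape, prior_sigma2_rate : float
        Inverse-gamma prior on the innovation variance.
    fix_rho : float or None
        Pin the AR(1) coefficient instead of sampling it.
    random_state : int or None
        Seed for the sampler; identical inputs and seed give bit-identical
        draws.

    Attributes
    ----------
    draws_ : PosteriorDraws
    summary_ : FitSummary
    intercept_, coef_ : posterior means (coef_ = [beta1, eta1, eta2])
    rho_, sigma2_ : posterior means of the error-process parameters
    dic_, p_d_ : model-comparison summaries

    Examples
    --------
    >>> from seasonfit.synthetic_data import GeneratorSpec, generate_series
    >>> from seasonfit.model_core import BayesianHarmonicAR, ModelParams
    >>> spec = GeneratorSpec(ModelParams(29.0, 0.03, -1.5, -1.7, 0.36, 1.0), seed=1)
    >>> s = generate_series(spec)
    >>> est = BayesianHarmonicAR(n_iterations=2000, burn_in=200, random_state=0)
    >>> fitted = est.fit(s.t_index.reshape(-1, 1), s.y)
    """

    def __init__(
        self,
        ar_order: int = 1,
        n_iterations: int = 20_000,
        burn_in: int = 2_000,
        prior_coef_sd: float = 1000.0,
        prior_sigma2_shape: float = 0.001,
        prior_sigma2_rate: float = 0.001,
        fix_rho: float | None = None,
        random_state: int | None = None,
    ) -> None:
        self.ar_order = ar_order
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.prior_coef_sd = prior_coef_sd
        self.prior_sigma2_shape = prior_sigma2_shape
        self.prior_sigma2_rate = prior_sigma2_rate
        self.fix_rho = fix_rho
        self.random_state = random_state

    def _config(self) -> SamplerConfig:
        return SamplerConfig(
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            seed=self.random_state if self.random_state is not None else 0,
            ar_order=self.ar_order,
            prior_coef_sd=self.prior_coef_sd,
            prior_sigma2_shape=self.prior_sigma2_shape,
            prior_sigma2_rate=self.prior_sigma2_rate,
            fix_rho=self.fix_rho,
        )

    @staticmethod
    def _validate_t(X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise ValueError("X must be a single column of time indices")
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("X must be 1-d or a single column")
        if not np.all(np.isfinite(t)):
            raise ValueError("time indices must be finite")
        return t

    def fit(self, X, y):
        """Fit to a monthly series; X holds the 1-based time index t."""
        t = self._validate_t(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValueError("X and y must have the same length")
        if y.size < _MIN_SERIES_LENGTH:
            raise ValueError(
                f"series must span at least {_MIN_SERIES_LENGTH} months, got {y.size}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("series contains non-finite values")

        config = self._config()
        draws = PosteriorDraws(draws=_run_gibbs(t, y, config), config=config)
        self.draws_ = draws
        self.summary_ = summarize(draws, y)
        mean = self.summary_.mean
        self.intercept_ = mean["beta0"]
        self.coef_ = np.array([mean["beta1"], mean["eta1"], mean["eta2"]])
        self.rho_ = np.array(
            [mean["rho"]] + ([mean["rho2"]] if "rho2" in mean else [])
        )
        self.sigma2_ = mean["sigma2_eps"]
        self.dic_ = self.summary_.dic
        self.p_d_ = self.summary_.p_d
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Posterior-mean trend + seasonal curve at the given time indices."""
        if not hasattr(self, "summary_"):
            raise AttributeError("estimator is not fitted")
        t = self._validate_t(X)
        theta = np.array([self.intercept_, *self.coef_])
        return design_matrix(t) @ theta
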