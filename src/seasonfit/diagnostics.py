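"""Residual diagnostics: PACF and an augmented Dickey-Fuller test.

Residuals are taken against the posterior-mean *mean curve*
(beta0 + beta1*t + S(t)), so they estimate the autocorrelated error
process e_t — the AR structure is deliberately left in for the
stationarity checks.  Whitened innovations r_t - rho_hat * r_{t-1} are
available for whiteness checks.

The ADF regression includes a constant and no deterministic trend (the
model already removes the trend); rejection uses the fixed asymptotic
constant-only critical values -3.43 / -2.86 / -2.57 at the 1 / 5 / 10
percent levels.  The PACF significance band is the conventional
+/- 2/sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ingest import MonthlySeries
from .model_core import FitSummary, design_matrix

ADF_CRITICAL_VALUES = {0.01: -3.43, 0.05: -2.86, 0.10: -2.57}


@dataclass
class DiagnosticsReport:
    residuals: np.ndarray
    innovations: np.ndarray | None
    pacf: np.ndarray                  # residual PACF at lags 1..max_lag
    pacf_innovations: np.ndarray | None
    pacf_bound: float                 # approximate 95% threshold 2/sqrt(n)
    adf_statistic: float
    adf_lags: int
    adf_reject_unit_root: bool
    serial_corr_flag: bool


def residuals(series: MonthlySeries | np.ndarray, fit: FitSummary | dict) -> np.ndarray:
    """y_t minus the posterior-mean curve beta0 + beta1*t + S(t).

    These estimate the AR error process e_t; they are *not* innovations.
    """
    y = series.y if isinstance(series, MonthlySeries) else np.asarray(series, dtype=float)
    mean = fit.mean if isinstance(fit, FitSummary) else fit
    theta = np.array([mean["beta0"], mean["beta1"], mean["eta1"], mean["eta2"]])
    X = design_matrix(np.arange(1, y.size + 1, dtype=float))
    return y - X @ theta


def innovations(resid: np.ndarray, rho: float) -> np.ndarray:
    """AR(1)-whitened residuals r_t - rho * r_{t-1} (length n-1)."""
    resid = np.asarray(resid, dtype=float)
    return resid[1:] - rho * resid[:-1]


def pacf(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Partial autocorrelations at lags 1..max_lag.

    Durbin-Levinson recursion on biased sample autocovariances (the
    Yule-Walker convention, denominators of n).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if max_lag >= n / 2:
        raise ValueError("max_lag must be < length/2")
    xc = x - x.mean()
    c0 = float(xc @ xc) / n
    if c0 == 0.0:
        raise ValueError("PACF undefined for a constant series (zero variance)")
    acov = np.array([float(xc[: n - k] @ xc[k:]) / n for k in range(max_lag + 1)])
    r = acov / c0

    phi_prev = np.zeros(0)
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        if k == 1:
            phi_kk = r[1]
            phi = np.array([phi_kk])
        else:
            num = r[k] - phi_prev @ r[k - 1 : 0 : -1]
            den = 1.0 - phi_prev @ r[1:k]
            phi_kk = num / den
            phi = np.empty(k)
            phi[: k - 1] = phi_prev - phi_kk * phi_prev[::-1]
            phi[k - 1] = phi_kk
        out[k - 1] = phi_kk
        phi_prev = phi
    return out


def adf_test(series: np.ndarray, lags: int = 1, alpha: float = 0.05) -> tuple[float, bool]:
    """Augmented Dickey-Fuller unit-root test (constant, no trend).

    Regresses dx_t on (1, x_{t-1}, dx_{t-1}, ..., dx_{t-lags}); the
    statistic is the t-ratio on x_{t-1} and the null of a unit root is
    rejected when it falls below the tabulated asymptotic critical value.
    Rejection indicates the series is stationary.
    """
    x = np.asarray(series, dtype=float)
    if alpha not in ADF_CRITICAL_VALUES:
        raise ValueError(f"alpha must be one of {sorted(ADF_CRITICAL_VALUES)}")
    if lags < 0:
        raise ValueError("lags must be >= 0")
    if x.size < lags + 10:
        raise ValueError(f"series too short for ADF with {lags} lags")

    dx = np.diff(x)
    # rows t = lags+1 .. n-1 of the differenced series
    target = dx[lags:]
    cols = [np.ones_like(target), x[lags:-1]]
    for j in range(1, lags + 1):
        cols.append(dx[lags - j : dx.size - j])
    Z = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(Z, target, rcond=None)
    if rank < Z.shape[1]:
        raise ValueError("ADF regression design is rank-deficient")
    resid = target - Z @ coef
    dof = target.size - Z.shape[1]
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(Z.T @ Z)
    stat = float(coef[1] / np.sqrt(cov[1, 1]))
    return stat, stat < ADF_CRITICAL_VALUES[alpha]


def diagnose(
    series: MonthlySeries | np.ndarray,
    fit: FitSummary | dict,
    max_lag: int = 20,
    adf_lags: int = 1,
    alpha: float = 0.05,
    include_innovations: bool = True,
) -> DiagnosticsReport:
    """Full residual diagnostics for a fitted model.

    The serial-correlation flag is raised when the lag-1 partial
    autocorrelation of the whitened innovations exceeds the 2/sqrt(n)
    band — i.e. when AR(1) whitening at the posterior-mean rho fails to
    remove the first-order dependence the model claims to capture.
    """
    resid = residuals(series, fit)
    n = resid.size
    bound = 2.0 / np.sqrt(n)
    pacf_resid = pacf(resid, max_lag)
    stat, reject = adf_test(resid, lags=adf_lags, alpha=alpha)

    innov = None
    pacf_innov = None
    if include_innovations:
        mean = fit.mean if isinstance(fit, FitSummary) else fit
        innov = innovations(resid, mean["rho"])
        pacf_innov = pacf(innov, max_lag)
        flag = bool(abs(pacf_innov[0]) > 2.0 / np.sqrt(innov.size))
    else:
        flag = bool(abs(pacf_resid[0]) > bound)

    return DiagnosticsReport(
        residuals=resid,
        innovations=innov,
        pacf=pacf_resid,
        pacf_innovations=pacf_innov,
        pacf_bound=bound,
        adf_statistic=stat,
        adf_lags=adf_lags,
        adf_reject_unit_root=reject,
        serial_corr_flag=flag,
    )
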