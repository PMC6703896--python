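"""Posterior summaries of the annual seasonal signal.

The seasonal component is a single annual harmonic

    S(t) = eta1 * sin(2*pi*t/12) + eta2 * cos(2*pi*t/12),

so its amplitude is sqrt(eta1^2 + eta2^2) and its phase fixes the peak
month.  Two significance readings are provided:

* coefficient rule — both 95% credible intervals for eta1 and eta2 exclude
  zero;
* band rule — the pointwise 95% band around the posterior S(t) curve
  excludes zero for at least one calendar month (equivalently: the effect
  is *not* significant when the zero line lies entirely inside the band).

The band rule is the primary flag for stratified reporting; both are
returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedPeakError
from .model_core import OMEGA, PosteriorDraws, credible_interval

MONTH_NAMES = [
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
]


@dataclass
class SeasonalCurve:
    """Per-month posterior mean of S(t) with a pointwise credible band."""

    months: np.ndarray
    mean_S: np.ndarray
    lower_S: np.ndarray
    upper_S: np.ndarray
    significant: bool
    rule: str = "band"

    def __post_init__(self) -> None:
        for name in ("months", "mean_S", "lower_S", "upper_S"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (
            self.months.shape == self.mean_S.shape == self.lower_S.shape == self.upper_S.shape
        ):
            raise ValueError("months, mean_S, lower_S, upper_S must share a shape")
        tol = 1e-9 * (1.0 + np.abs(self.mean_S))
        if np.any(self.lower_S > self.mean_S + tol) or np.any(
            self.mean_S > self.upper_S + tol
        ):
            raise ValueError("band must bracket the mean at every month")


def seasonal_value(eta1: float, eta2: float, t) -> float | np.ndarray:
    """Evaluate S(t) = eta1*sin(2*pi*t/12) + eta2*cos(2*pi*t/12)."""
    t = np.asarray(t, dtype=float)
    out = eta1 * np.sin(OMEGA * t) + eta2 * np.cos(OMEGA * t)
    return float(out) if out.ndim == 0 else out


def amplitude(eta1: float, eta2: float) -> float:
    """Seasonal amplitude sqrt(eta1^2 + eta2^2)."""
    return float(np.hypot(eta1, eta2))


def peak_month(eta1: float, eta2: float) -> float:
    """The t in (0, 12] at which S(t) attains its maximum.

    Writing S(t) = A*sin(2*pi*t/12 + phi) with phi = atan2(eta2, eta1), the
    peak sits where the argument is pi/2.  Returned as a real month (e.g.
    7.43 falls in July); use :func:`peak_month_name` for the calendar label.
    """
    if eta1 == 0.0 and eta2 == 0.0:
        raise UndefinedPeakError("peak month undefined for a zero seasonal vector")
    phi = np.arctan2(eta2, eta1)
    t = ((np.pi / 2.0 - phi) / OMEGA) % 12.0
    return 12.0 if t == 0.0 else float(t)


def peak_month_name(eta1: float, eta2: float) -> str:
    """Calendar month nearest the peak; exact half-months round down."""
    t = peak_month(eta1, eta2)
    m = int(np.ceil(t - 0.5))  # round to nearest, halves toward the earlier month
    if m == 0:
        m = 12
    elif m == 13:
        m = 1
    return MONTH_NAMES[m - 1]


def seasonal_curve(draws: PosteriorDraws, level: float = 0.95) -> SeasonalCurve:
    """Posterior mean and pointwise equal-tailed band of S(m), m = 1..12."""
    if len(draws) == 0:
        raise ValueError("draws must be non-empty")
    eta1 = draws.draws["eta1"].to_numpy()
    eta2 = draws.draws["eta2"].to_numpy()
    months = np.arange(1, 13)
    sin_m = np.sin(OMEGA * months)
    cos_m = np.cos(OMEGA * months)
    S = eta1[:, None] * sin_m[None, :] + eta2[:, None] * cos_m[None, :]
    lower = np.empty(12)
    upper = np.empty(12)
    for i in range(12):
        lower[i], upper[i] = credible_interval(S[:, i], level)
    curve = SeasonalCurve(
        months=months,
        mean_S=S.mean(axis=0),
        lower_S=lower,
        upper_S=upper,
        significant=False,
        rule="band",
    )
    curve.significant = significance_by_band(curve)
    return curve


def significance_by_coefficients(draws: PosteriorDraws, level: float = 0.95) -> bool:
    """True iff the credible intervals for *both* eta1 and eta2 exclude zero."""
    if len(draws) == 0:
        raise ValueError("draws must be non-empty")
    for name in ("eta1", "eta2"):
        lo, hi = credible_interval(draws.draws[name].to_numpy(), level)
        if lo <= 0.0 <= hi:
            return False
    return True


def significance_by_band(curve: SeasonalCurve) -> bool:
    """True iff the pointwise band excludes zero for at least one month.

    Equivalently, the seasonal effect is read as non-significant when the
    zero line lies entirely inside the credible band.
    """
    return bool(np.any((curve.lower_S > 0.0) | (curve.upper_S < 0.0)))
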