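"""Generate monthly series with exactly the model's statistical structure.

The simulator draws

    y_t = beta0 + beta1*t + eta1*sin(2*pi*t/12) + eta2*cos(2*pi*t/12) + e_t
    e_t = rho * e_{t-1} + eps_t,   eps_t ~ Normal(0, sigma_eps^2)

with e_1 initialised from the stationary distribution
Normal(0, sigma_eps^2 / (1 - rho^2)), so the errors are strictly stationary
from the first month.  Integer monthly counts are obtained by multiplying
the per-day average by the number of days in the calendar month and
rounding half away from zero, which round-trips through the ingest module
within half a count per month.

Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import MonthlySeries
from .model_core import ModelParams, design_matrix


@dataclass(frozen=True)
class GeneratorSpec:
    """Simulation settings: parameters, length, calendar anchor and seed."""

    params: ModelParams
    n_months: int = 120
    start_year: int = 2008
    start_month: int = 1
    seed: int = 0
    emit_counts: bool = False

    def __post_init__(self) -> None:
        if self.n_months < 1:
            raise ValueError("n_months must be >= 1")
        if not 1 <= self.start_month <= 12:
            raise ValueError("start_month must be in 1..12")


def mean_curve(params: ModelParams, t: np.ndarray) -> np.ndarray:
    """Deterministic part beta0 + beta1*t + S(t)."""
    return design_matrix(np.asarray(t, dtype=float)) @ params.theta


def generate_series(spec: GeneratorSpec) -> MonthlySeries:
    """Simulate a monthly per-day average series from the generative model."""
    p = spec.params
    if p.rho2 != 0.0:
        raise ValueError("the generator supports AR(1) errors only (rho2 must be 0)")
    if abs(p.rho) >= 1.0:
        raise ValueError(f"|rho| must be < 1, got {p.rho}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_months
    t = np.arange(1, n + 1, dtype=float)

    e = np.zeros(n)
    if p.sigma_eps > 0:
        e[0] = rng.normal(0.0, p.sigma_eps / np.sqrt(1.0 - p.rho**2))
        eps = rng.normal(0.0, p.sigma_eps, size=n - 1)
        for i in range(1, n):
            e[i] = p.rho * e[i - 1] + eps[i - 1]

    series = MonthlySeries(
        start_year=spec.start_year,
        start_month=spec.start_month,
        y=mean_curve(p, t) + e,
        counts=None,
    )
    if spec.emit_counts:
        counts = generate_counts(series)
        days = series.days()
        series = MonthlySeries(
            start_year=spec.start_year,
            start_month=spec.start_month,
            y=counts / days,
            counts=counts,
        )
    return series


def generate_counts(series: MonthlySeries) -> np.ndarray:
    """Integer monthly counts: round(y_t * days_in_month), half away from zero.

    Requires non-negative y; a negative draw means the simulation scale is
    too small (raise beta0 or lower sigma_eps).
    """
    y = series.y
    if np.any(y < 0):
        raise ValueError(
            "negative per-day averages cannot be discretised to counts; "
            "use a larger beta0 or smaller sigma_eps"
        )
    days = series.days()
    return np.floor(y * days + 0.5).astype(np.int64)


def counts_frame(series: MonthlySeries, sex: str = "all", age_group: str = "all") -> pd.DataFrame:
    """Counts in the ingest CSV schema (year, month, sex, age_group, count)."""
    counts = series.counts if series.counts is not None else generate_counts(series)
    months = series.months()
    return pd.DataFrame(
        {
            "year": [y for y, _ in months],
            "month": [m for _, m in months],
            "sex": sex,
            "age_group": age_group,
            "count": counts,
        }
    )
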