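"""Read monthly count and population tables and build per-day average series.

The modelled response is the monthly average number of events per day:
the calendar-month count divided by the number of days in that month
(29 for a leap February).  Time is indexed t = 1, 2, ..., n from the first
month of the analysis window, so a ten-year window starting January 2008
ends at t = 120.

Input tables are plain CSV:

``counts.csv``      columns ``year,month,sex,age_group,count``
``population.csv``  columns ``year,sex,age_group,population``

Incidence rates are reported per 100,000 population per year.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DuplicateMonthError, MissingMonthError

COUNT_COLUMNS = ["year", "month", "sex", "age_group", "count"]
POPULATION_COLUMNS = ["year", "sex", "age_group", "population"]


def days_in_month(year: int, month: int) -> int:
    """Number of days in a Gregorian calendar month (leap rule included)."""
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return calendar.monthrange(int(year), int(month))[1]


def monthly_average_per_day(count: float, year: int, month: int) -> float:
    """Monthly count divided by the number of days of that calendar month."""
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return count / days_in_month(year, month)


def incidence_per_100k(cases: float, population: float) -> float:
    """Cases per 100,000 population."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    if cases < 0:
        raise ValueError(f"cases must be non-negative, got {cases}")
    return 100_000.0 * cases / population


def _month_range(start: tuple[int, int], end: tuple[int, int]) -> list[tuple[int, int]]:
    sy, sm = start
    ey, em = end
    if (ey, em) < (sy, sm):
        raise ValueError(f"end {end} precedes start {start}")
    out = []
    y, m = sy, sm
    while (y, m) <= (ey, em):
        out.append((y, m))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


def parse_month(value) -> tuple[int, int]:
    """Parse a month given as ``(year, month)`` or a ``"YYYY-MM"`` string."""
    if isinstance(value, str):
        y, m = value.split("-")
        value = (int(y), int(m))
    y, m = int(value[0]), int(value[1])
    if not 1 <= m <= 12:
        raise ValueError(f"month must be in 1..12, got {m}")
    return y, m


@dataclass
class MonthlySeries:
    """An evenly spaced monthly series for one sex/age stratum.

    ``y`` holds the per-day averages actually modelled; ``counts`` holds the
    integer monthly totals when the series came from a count table (it is
    None for simulator output that was never discretised).  ``t_index`` is
    always 1-based and gap-free.
    """

    start_year: int
    start_month: int
    y: np.ndarray
    counts: np.ndarray | None = None
    sex: str = "all"
    age_group: str = "all"

    def __post_init__(self) -> None:
        if not 1 <= self.start_month <= 12:
            raise ValueError(f"start_month must be in 1..12, got {self.start_month}")
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1 or self.y.size == 0:
            raise ValueError("y must be a non-empty 1-d array")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != self.y.shape:
                raise ValueError("counts and y must have the same length")
            if np.any(self.counts < 0):
                raise ValueError("counts must be non-negative")
            days = self.days()
            if not np.allclose(self.y, self.counts / days, rtol=0, atol=1e-12):
                raise ValueError("y must equal counts / days_in_month exactly")

    def __len__(self) -> int:
        return self.y.size

    @property
    def t_index(self) -> np.ndarray:
        return np.arange(1, self.y.size + 1)

    def months(self) -> list[tuple[int, int]]:
        """Consecutive (year, month) pairs covered by the series."""
        y, m = self.start_year, self.start_month
        out = []
        for _ in range(self.y.size):
            out.append((y, m))
            m += 1
            if m == 13:
                y, m = y + 1, 1
        return out

    def days(self) -> np.ndarray:
        """Days in each calendar month of the series."""
        return np.array([days_in_month(y, m) for y, m in self.months()], dtype=float)


def _normalise_rows(count_rows) -> pd.DataFrame:
    if isinstance(count_rows, pd.DataFrame):
        df = count_rows.copy()
    else:
        df = pd.DataFrame(list(count_rows), columns=COUNT_COLUMNS)
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count rows lack columns: {sorted(missing)}")
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    if (df["month"] < 1).any() or (df["month"] > 12).any():
        raise ValueError("month values must be in 1..12")
    if (df["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    return df


def build_series(
    count_rows,
    start,
    end,
    sex: str = "all",
    age_group: str = "all",
) -> MonthlySeries:
    """Assemble a :class:`MonthlySeries` for one stratum over [start, end].

    ``sex``/``age_group`` equal to ``"all"`` aggregate (sum counts) over that
    dimension before dividing by days.  Every month in the window must be
    present exactly once per constituent stratum: a gap raises
    :class:`MissingMonthError` (no imputation), a duplicated stratum-month
    raises :class:`DuplicateMonthError`.
    """
    df = _normalise_rows(count_rows)
    start = parse_month(start)
    end = parse_month(end)

    if sex != "all":
        df = df[df["sex"] == sex]
    if age_group != "all":
        df = df[df["age_group"] == age_group]

    dup = df.duplicated(subset=["year", "month", "sex", "age_group"])
    if dup.any():
        bad = df.loc[dup, ["year", "month"]].iloc[0]
        raise DuplicateMonthError(
            f"duplicate count row for {int(bad['year'])}-{int(bad['month']):02d}"
        )

    grouped = df.groupby(["year", "month"], as_index=True)["count"].sum()
    months = _month_range(start, end)
    counts = np.empty(len(months), dtype=np.int64)
    for i, (y, m) in enumerate(months):
        if (y, m) not in grouped.index:
            raise MissingMonthError(f"no count row for {y}-{m:02d}")
        counts[i] = int(grouped.loc[(y, m)])

    days = np.array([days_in_month(y, m) for y, m in months], dtype=float)
    return MonthlySeries(
        start_year=start[0],
        start_month=start[1],
        y=counts / days,
        counts=counts,
        sex=sex,
        age_group=age_group,
    )


def read_counts(path) -> pd.DataFrame:
    """Read a ``counts.csv`` table and validate its schema."""
    df = pd.read_csv(path)
    return _normalise_rows(df)


def read_population(path) -> pd.DataFrame:
    """Read a ``population.csv`` table; population must be positive and
    (year, sex, age_group) unique."""
    df = pd.read_csv(path)
    missing = set(POPULATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"population table lacks columns: {sorted(missing)}")
    if (df["population"] <= 0).any():
        raise ValueError("population must be positive")
    if df.duplicated(subset=["year", "sex", "age_group"]).any():
        raise ValueError("(year, sex, age_group) must be unique in population table")
    return df


def rates_table(counts: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Annual incidence per 100,000 by year, sex and age group.

    Counts are summed over the months of each year and divided by that
    year's population for the same stratum.
    """
    counts = _normalise_rows(counts)
    yearly = (
        counts.groupby(["year", "sex", "age_group"], as_index=False)["count"].sum()
    )
    merged = yearly.merge(population, on=["year", "sex", "age_group"], how="inner")
    merged["rate_per_100k"] = [
        incidence_per_100k(c, p)
        for c, p in zip(merged["count"], merged["population"])
    ]
    return merged[["year", "sex", "age_group", "count", "population", "rate_per_100k"]]
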