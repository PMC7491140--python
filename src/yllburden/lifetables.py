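"""Abridged life tables and conversion of death records to daily YLLs.

A death's years of life lost (YLL) is the remaining life expectancy e_x of
the life-table age group matching the decedent's age and sex.  Daily YLLs
are the sum of individual YLLs on the day; the YLL rate normalises by the
population of the stratum, per 1e5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "build_life_table",
    "yll_for_death",
    "daily_yll_rates",
    "CAUSES",
]

CAUSES = ("non-accidental", "CVD", "RESP")
SEXES = ("male", "female")


@dataclass(frozen=True)
class LifeTable:
    """Remaining life expectancy by age group for one sex.

    ``age_starts`` are the lower bounds of contiguous age groups, the last
    group open-ended; ``ex`` is remaining life expectancy (years).
    """

    sex: str
    age_starts: np.ndarray
    ex: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "age_starts", np.asarray(self.age_starts, dtype=float))
        object.__setattr__(self, "ex", np.asarray(self.ex, dtype=float))
        if self.age_starts.size != self.ex.size:
            raise ValueError("age_starts and ex must align")
        if np.any(np.diff(self.age_starts) <= 0):
            raise ValueError("age groups must be increasing")
        if np.any(self.ex <= 0):
            raise ValueError("ex must be positive")
        # small tolerance admits the infant-mortality hump at age group 1
        adult = self.age_starts >= 1
        ex_adult = self.ex[adult]
        if np.any(np.diff(ex_adult) > 1e-6):
            raise ValueError("ex must be non-increasing beyond age 1")

    def lookup(self, age: float) -> float:
        if age < 0:
            raise ValueError("age must be non-negative")
        idx = int(np.searchsorted(self.age_starts, age, side="right") - 1)
        return float(self.ex[max(idx, 0)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sex": self.sex, "age_start": self.age_starts, "ex": self.ex}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sex: str) -> "LifeTable":
        sub = df[df["sex"] == sex].sort_values("age_start")
        if sub.empty:
            raise KeyError(f"sex {sex!r} absent from life table")
        return cls(sex, sub["age_start"].to_numpy(), sub["ex"].to_numpy())


def build_life_table(
    age_starts,
    mx,
    sex: str = "total",
    a0: float = 0.1,
) -> LifeTable:
    """Standard abridged life table from age-specific mortality rates.

    Uses nqx = n * nmx / (1 + (n - nax) * nmx) with nax = n/2 (``a0``
    configurable for the infant group), the usual lx / nLx / Tx chain, and
    ex = Tx / lx; the open-ended terminal group has ex = 1 / nmx.
    """
    age_starts = np.asarray(age_starts, dtype=float)
    mx = np.asarray(mx, dtype=float)
    if age_starts.size != mx.size:
        raise ValueError("age_starts and mx must align")
    if np.any(mx <= 0):
        raise ValueError("mortality rates must be positive")
    k = age_starts.size
    n = np.empty(k)
    n[:-1] = np.diff(age_starts)
    n[-1] = np.inf

    nax = n / 2.0
    if age_starts[0] == 0 and k > 1:
        nax[0] = a0
    qx = np.empty(k)
    qx[:-1] = n[:-1] * mx[:-1] / (1.0 + (n[:-1] - nax[:-1]) * mx[:-1])
    qx[-1] = 1.0
    bad = np.where((qx <= 0) | (qx > 1))[0]
    if bad.size:
        raise ValueError(
            f"nqx out of (0, 1] for age group(s) starting at {age_starts[bad]}"
        )

    radix = 1e5
    lx = np.empty(k)
    lx[0] = radix
    for i in range(k - 1):
        lx[i + 1] = lx[i] * (1.0 - qx[i])
    dx = np.empty(k)
    dx[:-1] = lx[:-1] - lx[1:]
    dx[-1] = lx[-1]
    nLx = np.empty(k)
    nLx[:-1] = n[:-1] * lx[1:] + nax[:-1] * dx[:-1]
    nLx[-1] = lx[-1] / mx[-1]
    tx = np.cumsum(nLx[::-1])[::-1]
    ex = tx / lx
    return LifeTable(sex, age_starts, ex)


def yll_for_death(record, table: LifeTable) -> float:
    """Years of life lost for one death: e_x of the matching age group."""
    sex = record["sex"] if isinstance(record, (dict, pd.Series)) else record.sex
    age = record["age"] if isinstance(record, (dict, pd.Series)) else record.age
    if sex != table.sex:
        raise KeyError(f"record sex {sex!r} does not match table sex {table.sex!r}")
    return table.lookup(float(age))


def daily_yll_rates(
    records: pd.DataFrame,
    tables: dict[str, LifeTable],
    population: float,
    date_range: pd.DatetimeIndex | None = None,
    cause: str | None = None,
    sex: str | None = None,
    age_band: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Daily (yll, yll_rate, deaths) series from individual death records.

    ``records`` needs columns date, age, sex, cause.  Days with no deaths
    contribute zeros, keeping the series dense for regression.  The
    stratum selectors restrict by cause (non-accidental keeps all rows),
    sex, or an [lo, hi) age band.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    if date_range is None:
        if rec.empty:
            raise ValueError("empty date range: no records and no date_range given")
        date_range = pd.date_range(rec["date"].min(), rec["date"].max(), freq="D")
    if len(date_range) == 0:
        raise ValueError("empty date range")

    if cause is not None and cause != "non-accidental":
        rec = rec[rec["cause"] == cause]
    if sex is not None:
        rec = rec[rec["sex"] == sex]
    if age_band is not None:
        lo, hi = age_band
        rec = rec[(rec["age"] >= lo) & (rec["age"] < hi)]

    if rec.empty:
        yll = pd.Series(0.0, index=date_range)
        deaths = pd.Series(0, index=date_range)
    else:
        ylls = np.array(
            [tables[s].lookup(a) for s, a in zip(rec["sex"], rec["age"])]
        )
        rec = rec.assign(yll=ylls)
        grouped = rec.groupby("date")
        yll = grouped["yll"].sum().reindex(date_range, fill_value=0.0)
        deaths = grouped.size().reindex(date_range, fill_value=0)
    return pd.DataFrame(
        {
            "date": date_range,
            "yll": yll.to_numpy(),
            "yll_rate": yll.to_numpy() / population * 1e5,
            "deaths": deaths.to_numpy(),
        }
    )
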