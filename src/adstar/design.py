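"""Fixed-effect design assembly for the district-day count model.

The linear predictor of the model is

    log mu_st = alpha + delta . DOW_t + beta . DSI_t + gamma PM_t
                + f(TP_t) + f(T_t) + u_s + eta_s + log(pop_s)

This module assembles the linear block (intercept, six day-of-week dummies
with Sunday as reference, three dust-storm-index dummies with pre-ADS days as
reference, and same-day PM10), the log-population offset, and the raw inputs
of the two smoothers, in a deterministic row order: districts in sorted
order, days in calendar order within each district.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import DayClassification, WindowLabel, dsi_dummies

__all__ = ["DesignBundle", "dow_dummies", "build_design", "LINEAR_COLUMNS"]

logger = logging.getLogger(__name__)

LINEAR_COLUMNS = [
    "intercept",
    "dow_mon", "dow_tue", "dow_wed", "dow_thu", "dow_fri", "dow_sat",
    "dsi_event", "dsi_post", "dsi_other",
    "pm10",
]


def dow_dummies(date: dt.date) -> tuple[int, ...]:
    """Six day-of-week indicators (Monday .. Saturday); Sunday is reference."""
    wd = date.weekday()  # Monday == 0 .. Sunday == 6
    return tuple(int(wd == i) for i in range(6))


@dataclass
class DesignBundle:
    """Stacked district-day design for the sampler.

    Rows are ordered district-major: all T days of the first district, then
    the second, etc.  ``day_index`` maps each row to its position in
    ``dates`` so day-level smoother bases need only T rows.
    """

    X: np.ndarray                      # (n, 11) linear block
    y: np.ndarray                      # (n,) counts
    offset: np.ndarray                 # (n,) log population
    temperature: np.ndarray            # (T,) daily mean temperature, deg C
    pm10: np.ndarray                   # (T,) daily PM10, ug/m3
    dates: list                        # (T,) calendar dates
    districts: list                    # (S,) district identifiers, sorted
    day_index: np.ndarray              # (n,) row -> day position
    district_index: np.ndarray         # (n,) row -> district position
    labels: list = field(repr=False, default_factory=list)  # (T,) WindowLabel

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_districts(self) -> int:
        return len(self.districts)

    @property
    def n_days(self) -> int:
        return len(self.dates)


def _interpolate_short_gaps(series: pd.Series, name: str, max_gap: int) -> pd.Series:
    n_missing = int(series.isna().sum())
    if n_missing == 0:
        return series
    filled = series.interpolate(limit=max_gap, limit_area="inside")
    if filled.isna().any():
        raise ValueError(
            f"{name} has missing values in runs longer than {max_gap} days "
            "(or at the series ends); supply complete data"
        )
    logger.warning("interpolated %d missing %s values (gaps <= %d days)",
                   n_missing, name, max_gap)
    return filled


def build_design(
    counts: pd.DataFrame,
    environment: pd.DataFrame,
    population: pd.Series | dict,
    labels: list[DayClassification],
    interpolate_missing: bool = False,
) -> DesignBundle:
    """Assemble the linear design, offset and smoother inputs.

    Parameters
    ----------
    counts
        Long table with columns ``date``, ``district``, ``count``; one row per
        district-day, counts nonnegative.
    environment
        Table with columns ``date``, ``pm10``, ``temperature`` covering every
        study day (single monitoring station, so indexed by day only).
    population
        District -> person count; strictly positive, time-constant.
    labels
        One :class:`~adstar.windows.DayClassification` per study day.
    interpolate_missing
        If true, linearly interpolate runs of at most 2 missing environmental
        days instead of raising.
    """
    counts = counts.copy()
    counts["date"] = pd.to_datetime(counts["date"]).dt.date
    if counts.duplicated(["date", "district"]).any():
        dup = counts[counts.duplicated(["date", "district"], keep=False)]
        raise ValueError(f"duplicate (date, district) rows:\n{dup.head()}")
    if (counts["count"] < 0).any():
        raise ValueError("negative counts")

    dates = sorted(counts["date"].unique())
    districts = sorted(counts["district"].unique())
    S, T = len(districts), len(dates)

    label_map = {c.date: c.label for c in labels}
    missing_lab = [d for d in dates if d not in label_map]
    if missing_lab:
        raise ValueError(f"no window label for {len(missing_lab)} days, "
                         f"first: {missing_lab[0]}")
    day_labels = [WindowLabel(label_map[d]) for d in dates]

    env = environment.copy()
    env["date"] = pd.to_datetime(env["date"]).dt.date
    env = env.set_index("date").reindex(dates)
    max_gap = 2 if interpolate_missing else 0
    if env[["pm10", "temperature"]].isna().any().any() and not interpolate_missing:
        bad = env.index[env[["pm10", "temperature"]].isna().any(axis=1)]
        raise ValueError(f"missing environmental values on {len(bad)} days, "
                         f"first: {bad[0]}")
    pm10 = _interpolate_short_gaps(env["pm10"], "pm10", max_gap).to_numpy(float)
    temp = _interpolate_short_gaps(env["temperature"], "temperature",
                                   max_gap).to_numpy(float)

    pop = pd.Series(population).astype(float)
    missing_pop = [s for s in districts if s not in pop.index]
    if missing_pop:
        raise ValueError(f"no population for districts: {missing_pop}")
    if (pop <= 0).any():
        raise ValueError("populations must be strictly positive")

    # day-level linear covariates (T, 11 minus offset handling)
    day_block = np.empty((T, len(LINEAR_COLUMNS)))
    for t, d in enumerate(dates):
        day_block[t] = (1.0, *dow_dummies(d), *dsi_dummies(day_labels[t]), pm10[t])

    wide = (
        counts.pivot(index="date", columns="district", values="count")
        .reindex(index=dates, columns=districts)
    )
    if wide.isna().any().any():
        raise ValueError("count table is not a complete district x day panel")

    day_index = np.tile(np.arange(T), S)
    district_index = np.repeat(np.arange(S), T)
    X = day_block[day_index]
    y = wide.to_numpy(float).T.reshape(-1)  # district-major
    offset = np.log(pop.loc[districts].to_numpy())[district_index]

    return DesignBundle(
        X=X, y=y, offset=offset,
        temperature=temp, pm10=pm10,
        dates=list(dates), districts=list(districts),
        day_index=day_index, district_index=district_index,
        labels=day_labels,
    )
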