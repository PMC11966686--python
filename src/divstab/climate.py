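"""Degree-day climate summaries from daily mean temperatures.

Growing degree days (GDD) accumulate warmth above a 5 degC base as the sum
of daily exceedances ``max(T - 5, 0)``; freezing degree days (FDD) sum the
(negative) daily means on days strictly below 0 degC.  FDD is kept signed,
so a larger (closer to zero) FDD means a *warmer* winter — the convention
under which both variables increase with warming.  Per-site temporal mean
(mT) and sample standard deviation (sdT) over the sampled years of a site's
selected window are the environmental covariates of the downstream
structural equation models.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateWindowError, MissingDataError
from .sites import SamplingWindow

__all__ = [
    "ClimateSummary",
    "compute_gdd",
    "compute_fdd",
    "annual_degree_days",
    "summarize_climate",
    "climate_table",
    "read_daily_climate",
]

logger = logging.getLogger(__name__)

#: Tolerated fraction of missing days within a calendar year before the
#: year is dropped from the annual table (interpolated series are complete;
#: this guards against truncated inputs).
MAX_MISSING_DAY_FRACTION = 0.10


@dataclass(frozen=True)
class ClimateSummary:
    """Windowed summary of one degree-day variable at one site."""

    site_id: str
    variable: str       # "GDD" or "FDD"
    mT: float           # temporal mean over window years, degree-days
    sdT: float          # temporal sample SD over window years, degree-days
    n_years: int


def _year_values(series: pd.DataFrame, year: int) -> np.ndarray:
    dates = pd.to_datetime(series["date"])
    vals = series.loc[dates.dt.year == year, "tmean_c"].to_numpy(dtype=float)
    if vals.size == 0:
        site = series["site_id"].iloc[0] if len(series) else "?"
        raise MissingDataError(f"no daily temperatures for site {site!r}, year {year}")
    return vals


def compute_gdd(series: pd.DataFrame, year: int, base_c: float = 5.0) -> float:
    """Growing degree days: sum of ``max(tmean - base, 0)`` over the year's days.

    `series` holds one site's daily records with columns
    ``site_id, date, tmean_c``.  Non-negative; monotone in every daily value.
    """
    vals = _year_values(series, year)
    return float(np.maximum(vals - base_c, 0.0).sum())


def compute_fdd(series: pd.DataFrame, year: int, threshold_c: float = 0.0) -> float:
    """Freezing degree days: sum of daily means on days strictly below `threshold_c`.

    Non-positive; a mild winter gives a value closer to zero than a harsh
    one, so FDD — like GDD — never decreases under warming.
    """
    vals = _year_values(series, year)
    return float(vals[vals < threshold_c].sum())


def annual_degree_days(series: pd.DataFrame, variable: str, *,
                       base_c: float = 5.0, threshold_c: float = 0.0,
                       max_missing: float = MAX_MISSING_DAY_FRACTION,
                       ) -> dict[int, float]:
    """Per-year degree-day values for one site, dropping too-gappy years.

    A calendar year with more than `max_missing` of its days absent is
    dropped with a logged warning rather than summed over a truncated span.
    """
    dates = pd.to_datetime(series["date"])
    out: dict[int, float] = {}
    for year, grp in series.groupby(dates.dt.year):
        n_expected = 366 if calendar.isleap(int(year)) else 365
        if len(grp) < (1.0 - max_missing) * n_expected:
            logger.warning("dropping year %s for site %r: only %d of %d days present",
                           year, grp["site_id"].iloc[0], len(grp), n_expected)
            continue
        if variable == "GDD":
            out[int(year)] = compute_gdd(grp, int(year), base_c=base_c)
        elif variable == "FDD":
            out[int(year)] = compute_fdd(grp, int(year), threshold_c=threshold_c)
        else:
            raise ValueError(f"unknown climate variable {variable!r}")
    return out


def summarize_climate(per_year: Mapping[int, float], window: SamplingWindow,
                      variable: str = "GDD") -> ClimateSummary:
    """Temporal mean and sample SD over the sampled years of a site's window.

    Only years the site was actually sampled contribute, mirroring how the
    community series itself is summarised.  Requires at least two such
    years with climate values.
    """
    years = [y for y in window.sampled_years if y in per_year]
    if len(years) < 2:
        raise DegenerateWindowError(
            f"site {window.site_id!r}: {len(years)} climate year(s) inside window "
            f"{window.start_year}-{window.end_year}; need >= 2")
    vals = np.array([per_year[y] for y in years], dtype=float)
    return ClimateSummary(site_id=window.site_id, variable=variable,
                          mT=float(vals.mean()), sdT=float(vals.std(ddof=1)),
                          n_years=len(years))


def climate_table(daily: pd.DataFrame, windows: Iterable[SamplingWindow], *,
                  variables: tuple[str, ...] = ("GDD", "FDD"),
                  base_c: float = 5.0, threshold_c: float = 0.0) -> pd.DataFrame:
    """Windowed GDD/FDD summaries for every retained site.

    Returns a tidy frame ``site_id, variable, mT, sdT, n_years`` with one
    row per site x variable.
    """
    rows = []
    by_site = dict(tuple(daily.groupby("site_id")))
    for w in windows:
        if w.site_id not in by_site:
            raise MissingDataError(f"no daily climate for site {w.site_id!r}")
        series = by_site[w.site_id]
        for var in variables:
            per_year = annual_degree_days(series, var, base_c=base_c,
                                          threshold_c=threshold_c)
            s = summarize_climate(per_year, w, variable=var)
            rows.append({"site_id": s.site_id, "variable": s.variable,
                         "mT": s.mT, "sdT": s.sdT, "n_years": s.n_years})
    return pd.DataFrame(rows, columns=["site_id", "variable", "mT", "sdT", "n_years"])


def read_daily_climate(path) -> pd.DataFrame:
    """Read a daily climate CSV (``site_id, date, tmean_c``; ISO dates)."""
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = {"site_id", "date", "tmean_c"} - set(df.columns)
    if missing:
        raise ValueError(f"climate CSV missing columns: {sorted(missing)}")
    return df
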