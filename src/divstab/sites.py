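"""Moving-window site selection for irregularly sampled monitoring series.

Long-term monitoring sites are rarely sampled every year.  To obtain
comparable time series, each site's record is reduced to its fullest
20-year stretch: a window of fixed calendar length is slid over every
possible placement, the placement holding the most sampled years wins
(earliest placement on ties), and the window is then trimmed so that its
endpoints coincide with sampled years.  Sites with fewer than 5 sampled
years, or whose first and last sample are less than 15 years apart, are
excluded; the survivors carry 15-20-year series with sampling frequency
of at least 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidArgumentError

__all__ = ["SamplingWindow", "best_window", "filter_sites", "select_sites",
           "windows_to_frame"]

DEFAULT_WINDOW_LEN = 20
DEFAULT_MIN_SAMPLED = 5
DEFAULT_MIN_SPAN = 15


@dataclass(frozen=True)
class SamplingWindow:
    """The selected (trimmed) sampling window of one site."""

    site_id: str
    start_year: int                 # first sampled year inside the window
    end_year: int                   # last sampled year inside the window
    sampled_years: tuple[int, ...]  # sorted, all within [start_year, end_year]
    retained: bool = True
    exclusion_rule: str | None = None

    @property
    def n_sampled(self) -> int:
        return len(self.sampled_years)

    @property
    def span(self) -> int:
        """Years between first and last sampling event."""
        return self.end_year - self.start_year

    @property
    def length(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def frequency(self) -> float:
        return self.n_sampled / self.length


def best_window(sampled_years: Iterable[int], window_len: int = DEFAULT_WINDOW_LEN,
                site_id: str = "") -> SamplingWindow:
    """Fullest `window_len`-year calendar window over a site's sampled years.

    Every integer start year from ``min(sampled) - window_len + 1`` to
    ``max(sampled)`` is evaluated; the window covering the most sampled
    years wins, with ties broken to the earliest start.  The returned
    window is trimmed to the first/last sampled year it contains, so its
    calendar length never exceeds `window_len` and its endpoints are
    sampled years.
    """
    years = sorted(set(int(y) for y in sampled_years))
    if not years:
        raise InvalidArgumentError("sampled_years is empty")
    if window_len < 1:
        raise InvalidArgumentError(f"window_len must be >= 1, got {window_len}")

    best_start, best_count = None, -1
    for start in range(years[0] - window_len + 1, years[-1] + 1):
        count = sum(1 for y in years if start <= y <= start + window_len - 1)
        if count > best_count:
            best_start, best_count = start, count
    inside = tuple(y for y in years if best_start <= y <= best_start + window_len - 1)
    return SamplingWindow(site_id=site_id, start_year=inside[0],
                          end_year=inside[-1], sampled_years=inside)


def filter_sites(windows: Sequence[SamplingWindow],
                 min_sampled: int = DEFAULT_MIN_SAMPLED,
                 min_span: int = DEFAULT_MIN_SPAN,
                 ) -> tuple[list[SamplingWindow], list[SamplingWindow]]:
    """Split windows into (retained, excluded) by the sampling-quality rules.

    A window is retained iff ``n_sampled >= min_sampled`` and
    ``span >= min_span``.  Excluded windows carry the rule that fired.
    Idempotent: re-filtering the retained list changes nothing.
    """
    retained, excluded = [], []
    for w in windows:
        if w.n_sampled < min_sampled:
            rule = f"< {min_sampled} years sampled"
        elif w.span < min_span:
            rule = f"span < {min_span}"
        else:
            retained.append(SamplingWindow(w.site_id, w.start_year, w.end_year,
                                           w.sampled_years, True, None))
            continue
        excluded.append(SamplingWindow(w.site_id, w.start_year, w.end_year,
                                       w.sampled_years, False, rule))
    return retained, excluded


def select_sites(abundance: pd.DataFrame, *, window_len: int = DEFAULT_WINDOW_LEN,
                 min_sampled: int = DEFAULT_MIN_SAMPLED,
                 min_span: int = DEFAULT_MIN_SPAN,
                 ) -> tuple[list[SamplingWindow], list[SamplingWindow]]:
    """Best window + quality filter for every site in a long abundance table.

    `abundance` has columns ``site_id, year, species_id, abundance``; a year
    counts as sampled at a site if any record (including zeros) exists.
    """
    windows = [best_window(grp["year"].unique(), window_len, site_id=str(site))
               for site, grp in abundance.groupby("site_id")]
    return filter_sites(windows, min_sampled=min_sampled, min_span=min_span)


def windows_to_frame(windows: Iterable[SamplingWindow]) -> pd.DataFrame:
    """Tabulate windows in the pipeline's site-selection report layout."""
    rows = [{"site_id": w.site_id, "start_year": w.start_year,
             "end_year": w.end_year, "n_sampled": w.n_sampled, "span": w.span,
             "frequency": w.frequency, "retained": w.retained,
             "exclusion_rule": w.exclusion_rule or ""} for w in windows]
    return pd.DataFrame(rows, columns=["site_id", "start_year", "end_year",
                                       "n_sampled", "span", "frequency",
                                       "retained", "exclusion_rule"])
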