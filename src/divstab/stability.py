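"""Community-stability decomposition from windowed abundance matrices.

Community stability is the inverse coefficient of variation of the total
community abundance over time, S_com = mu_com / sigma_com.  It factors
exactly into a synchrony term and a population-stability term:

    log S_com = log phi + log S_pop

where phi = (sum_j sigma_j) / sigma_com >= 1 is the community asynchrony
(how much species-level fluctuations cancel in the total; 1 under perfect
proportional synchrony) and S_pop = mu_com / sum_j sigma_j is the
abundance-weighted average population stability,
1 / sum_j (mu_j/mu_com)(sigma_j/mu_j).  All temporal SDs are sample SDs
(n-1 denominator) over the site's sampled window years; zeros recorded in
sampled years are genuine observations and enter the moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateStabilityError, DegenerateWindowError
from .sites import SamplingWindow

__all__ = ["StabilityDecomposition", "decompose_stability", "stability_table"]


@dataclass(frozen=True)
class StabilityDecomposition:
    """Per-site stability decomposition; all identities hold exactly."""

    site_id: str
    mu_com: float
    sigma_com: float
    mu_j: dict[str, float]
    sigma_j: dict[str, float]
    S_com: float
    S_pop: float
    phi: float
    n_years: int

    @property
    def log_S_com(self) -> float:
        return float(np.log(self.S_com))

    @property
    def log_S_pop(self) -> float:
        return float(np.log(self.S_pop))

    @property
    def log_phi(self) -> float:
        return float(np.log(self.phi))


def decompose_stability(matrix: pd.DataFrame, min_years: int = 2,
                        site_id: str = "") -> StabilityDecomposition:
    """Decompose one site's years x species abundance matrix.

    Rows are sampled years, columns species.  Species recorded as zero in
    every sampled year are dropped (they carry no signal); remaining zeros
    are genuine lows.  Raises :class:`DegenerateWindowError` with fewer
    than `min_years` rows and :class:`DegenerateStabilityError` when the
    community total never varies (sigma_com = 0).
    """
    if len(matrix) < min_years:
        raise DegenerateWindowError(
            f"site {site_id!r}: {len(matrix)} sampled years < min_years={min_years}")
    mat = matrix.loc[:, (matrix != 0).any(axis=0)]
    values = mat.to_numpy(dtype=float)
    species = list(mat.columns)

    totals = values.sum(axis=1)
    mu_com = float(totals.mean())
    sigma_com = float(totals.std(ddof=1))
    if sigma_com == 0.0:
        raise DegenerateStabilityError(
            f"site {site_id!r}: community total is constant; S_com undefined")

    mu_j = values.mean(axis=0)
    sigma_j = values.std(axis=0, ddof=1)
    sum_sigma = float(sigma_j.sum())

    return StabilityDecomposition(
        site_id=site_id,
        mu_com=mu_com,
        sigma_com=sigma_com,
        mu_j=dict(zip(species, mu_j.astype(float))),
        sigma_j=dict(zip(species, sigma_j.astype(float))),
        S_com=mu_com / sigma_com,
        S_pop=mu_com / sum_sigma,
        phi=sum_sigma / sigma_com,
        n_years=len(matrix),
    )


def site_matrix(abundance: pd.DataFrame, window: SamplingWindow) -> pd.DataFrame:
    """Years x species matrix of one site restricted to its window's sampled years.

    Years sampled at the site but lacking a record for some species are
    filled with zero: a sampled year with no record of a species is an
    observed absence.
    """
    sub = abundance[(abundance["site_id"].astype(str) == window.site_id)
                    & abundance["year"].isin(window.sampled_years)]
    mat = sub.pivot_table(index="year", columns="species_id", values="abundance",
                          aggfunc="sum", fill_value=0.0)
    return mat.reindex(sorted(window.sampled_years), fill_value=0.0)


def stability_table(abundance: pd.DataFrame, windows: list[SamplingWindow],
                    min_years: int = 2,
                    ) -> tuple[pd.DataFrame, list[dict]]:
    """Per-site decomposition table over the retained windows.

    Returns ``(table, exclusions)`` where the table has one row per
    non-degenerate site (mu_com, sigma_com, S_com, S_pop, phi and their
    natural logs) and `exclusions` lists sites whose decomposition was
    undefined, with the reason.
    """
    rows, exclusions = [], []
    for w in windows:
        mat = site_matrix(abundance, w)
        try:
            d = decompose_stability(mat, min_years=min_years, site_id=w.site_id)
        except (DegenerateStabilityError, DegenerateWindowError) as exc:
            exclusions.append({"site_id": w.site_id, "reason": str(exc)})
            continue
        rows.append({"site_id": d.site_id, "mu_com": d.mu_com,
                     "sigma_com": d.sigma_com, "S_com": d.S_com,
                     "S_pop": d.S_pop, "phi": d.phi,
                     "log_S_com": d.log_S_com, "log_S_pop": d.log_S_pop,
                     "log_phi": d.log_phi, "n_years_used": d.n_years})
    cols = ["site_id", "mu_com", "sigma_com", "S_com", "S_pop", "phi",
            "log_S_com", "log_S_pop", "log_phi", "n_years_used"]
    return pd.DataFrame(rows, columns=cols), exclusions
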