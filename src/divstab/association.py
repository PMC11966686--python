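"""Spearman rank-correlation screening between stability and its covariates.

Bivariate screening precedes the structural equation models: each
diversity or climate variable is correlated with each stability variable
using Spearman's rank correlation (average ranks for ties, Pearson
correlation of the ranks) with the usual t-approximation for the two-sided
p-value.  Stars follow the conventional 0.05 / 0.01 / 0.001 coding.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, UndefinedStatisticError

__all__ = ["CorrelationResult", "spearman", "correlation_matrix", "significance_stars"]


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    r: float
    p: float
    n: int
    stars: str


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def spearman(x: Sequence[float], y: Sequence[float], *, exact: bool = False,
             var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Spearman correlation with t-approximate (or exact permutation) p-value.

    Requires at least 4 complete pairs.  `exact=True` computes the
    permutation p-value by full enumeration (only sensible for n < 10) and
    is offered for very small samples where the t-approximation is rough.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise InvalidArgumentError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("constant vector: Spearman r undefined")

    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    r = float(np.corrcoef(rx, ry)[0, 1])

    if exact:
        from itertools import permutations
        if n > 9:
            raise InvalidArgumentError("exact permutation p only supported for n <= 9")
        obs = abs(r)
        count = total = 0
        for perm in permutations(ry):
            rp = float(np.corrcoef(rx, np.array(perm))[0, 1])
            count += abs(rp) >= obs - 1e-12
            total += 1
        p = count / total
    else:
        r_c = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
        t = r_c * np.sqrt((n - 2) / (1.0 - r_c * r_c))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(var_x=var_x, var_y=var_y, r=r, p=p, n=n,
                             stars=significance_stars(p))


def correlation_matrix(metrics: pd.DataFrame, targets: Sequence[str],
                       ) -> list[CorrelationResult]:
    """All pairwise Spearman correlations among `targets`, pairwise-complete."""
    unknown = [t for t in targets if t not in metrics.columns]
    if unknown:
        raise InvalidArgumentError(f"unknown variable name(s): {unknown}")
    out = []
    for a, b in combinations(targets, 2):
        out.append(spearman(metrics[a].to_numpy(), metrics[b].to_numpy(),
                            var_x=a, var_y=b))
    return out


def correlations_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([{"var_x": c.var_x, "var_y": c.var_y, "r": c.r,
                          "p": c.p, "n": c.n, "stars": c.stars} for c in results],
                        columns=["var_x", "var_y", "r", "p", "n", "stars"])
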