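"""Piecewise structural equation models on a DAG of Gaussian submodels.

A piecewise SEM replaces the single joint covariance fit of classical SEM
with one local regression per endogenous vertex of a directed acyclic
graph.  Global topology is then judged by the conditional independences
the DAG implies but the submodels do not estimate:

* the *basis set* contains one claim per non-adjacent vertex pair
  (excluding pairs tied by a correlated-error term and pairs of two
  exogenous vertices, whose covariance the model leaves free), each
  conditioned on the union of the pair's parents;
* each claim is tested by regressing the later vertex (in a fixed
  topological order) on its conditioning set plus the other vertex, taking
  the two-sided t-test p-value of that extra coefficient;
* Fisher's C = -2 sum(ln p_i) is chi-square with 2k degrees of freedom
  under the causal model, and a likelihood-ratio chi-square against the
  *saturated* model (the causal model with every basis-set constraint
  freed, so df equals the number of claims) tests the model against an
  unconstrained alternative;
* candidate models (e.g. a growing-degree-day versus a freezing-degree-day
  environment) are ranked by small-sample-corrected AICc over the summed
  submodel likelihoods, and a model counts as *supported* only when both
  goodness-of-fit p-values exceed 0.05.

Indirect effects are products of standardized coefficients along directed
paths, summed over paths.  Model modification is deliberately manual: the
engine only *suggests* edges or correlated errors for failed independence
claims; the caller chooses and refits.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import (CycleError, InvalidArgumentError, ModelSpecError,
                     UndefinedStatisticError)
from .linmod import OlsFit, fit_ols

__all__ = [
    "DagModel", "IndependenceClaim", "GofStats", "FittedSem", "PathEffect",
    "parse_dag", "fit_submodels", "basis_set", "dsep_tests", "fishers_c",
    "chisq_vs_saturated", "model_aicc", "correlated_errors",
    "indirect_effects", "suggest_modifications", "compare_models", "fit_sem",
    "DEFAULT_MODEL_SPEC",
]

logger = logging.getLogger(__name__)

#: Default causal topology for the diversity-stability analysis: species
#: richness (SR) drives the three trait-structure variables; mean and SD of
#: the temperature variable (mT, sdT) drive traits and both stability
#: components; traits drive population stability (logSpop) and asynchrony
#: (logPhi), whose sum is community stability (logScom).  The three trait
#: variables share correlated errors.
DEFAULT_MODEL_SPEC = """\
# Diversity-stability causal model (one temperature variable at a time).
FDis ~ SR + mT + sdT
MPD ~ SR + mT + sdT
CWPoL ~ SR + mT + sdT
logSpop ~ FDis + MPD + CWPoL + mT + sdT
logPhi ~ FDis + MPD + CWPoL + mT + sdT
logScom ~ logSpop + logPhi
FDis ~~ MPD
FDis ~~ CWPoL
MPD ~~ CWPoL
"""

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_P_CLAMP = 1e-16  # floor for d-sep p-values entering Fisher's C


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DagModel:
    """A causal DAG plus free correlated-error pairs."""

    graph: nx.DiGraph
    correlated: frozenset[frozenset[str]] = frozenset()

    @property
    def vertices(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    @property
    def exogenous(self) -> set[str]:
        return {v for v in self.graph.nodes if self.graph.in_degree(v) == 0}

    @property
    def endogenous(self) -> list[str]:
        return [v for v in self.topological_order() if self.graph.in_degree(v) > 0]

    def parents(self, v: str) -> set[str]:
        return set(self.graph.predecessors(v))

    def topological_order(self) -> list[str]:
        """Deterministic topological order (ties broken by vertex name)."""
        return list(nx.lexicographical_topological_sort(self.graph))

    def adjacent(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b) or self.graph.has_edge(b, a)

    def with_edge(self, u: str, v: str) -> "DagModel":
        g = self.graph.copy()
        g.add_edge(u, v)
        if not nx.is_directed_acyclic_graph(g):
            raise CycleError(f"adding {u} -> {v} creates a cycle")
        return replace(self, graph=g)

    def with_correlated(self, a: str, b: str) -> "DagModel":
        if self.adjacent(a, b):
            raise ModelSpecError(f"{a} ~~ {b}: vertices are joined by a directed edge")
        return replace(self, correlated=self.correlated | {frozenset((a, b))})


def _check_name(name: str, line: str) -> str:
    if not _NAME_RE.match(name):
        raise ModelSpecError(f"bad variable name {name!r} in line: {line!r}")
    return name


def parse_dag(spec_text: str) -> DagModel:
    """Parse a model-DSL text into a validated :class:`DagModel`.

    Lines are either ``Y ~ X1 + X2`` (directed parents of Y) or ``A ~~ B``
    (a correlated-error pair, allowed only between non-adjacent vertices).
    ``#`` starts a comment.  Cycles and self-pairs are rejected.
    """
    g = nx.DiGraph()
    corr: set[frozenset[str]] = set()
    directed_lines, corr_lines = [], []
    for raw in spec_text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "~~" in line:
            corr_lines.append(line)
        elif "~" in line:
            directed_lines.append(line)
        else:
            raise ModelSpecError(f"cannot parse line: {line!r}")

    for line in directed_lines:
        lhs, rhs = (part.strip() for part in line.split("~", 1))
        child = _check_name(lhs, line)
        g.add_node(child)
        for parent in (p.strip() for p in rhs.split("+")):
            _check_name(parent, line)
            if parent == child:
                raise ModelSpecError(f"self-loop {child} ~ {child}")
            g.add_edge(parent, child)

    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        path = " -> ".join(u for u, _ in cycle) + f" -> {cycle[0][0]}"
        raise CycleError(f"model is cyclic: {path}")

    model = DagModel(graph=g)
    for line in corr_lines:
        a, b = (part.strip() for part in line.split("~~", 1))
        _check_name(a, line), _check_name(b, line)
        if a == b:
            raise ModelSpecError(f"correlated error of a variable with itself: {a}")
        if a not in g or b not in g:
            missing = [v for v in (a, b) if v not in g]
            raise ModelSpecError(f"correlated-error vertices not in model: {missing}")
        model = model.with_correlated(a, b)
        corr.add(frozenset((a, b)))
    return model


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class Submodel:
    """One endogenous vertex's regression plus standardized slopes."""

    fit: OlsFit
    std_coef: dict[str, float]   # predictor -> raw * SD(x)/SD(y)

    @property
    def response(self) -> str:
        return self.fit.response

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.fit.predictors, self.fit.coef))


@dataclass(frozen=True)
class IndependenceClaim:
    """One d-separation claim: ``response _||_ other | conditioning_set``."""

    response: str
    other: str
    conditioning_set: tuple[str, ...]
    p_value: float | None = None
    coefficient: float | None = None


@dataclass(frozen=True)
class GofStats:
    fisher_c: float
    fisher_df: int
    fisher_p: float
    chisq: float
    chisq_df: int
    chisq_p: float
    aicc: float
    k_params: int


@dataclass
class FittedSem:
    """A piecewise SEM fitted to one data table."""

    dag: DagModel
    data: pd.DataFrame           # analysis rows (listwise-complete)
    submodels: dict[str, Submodel]
    name: str = "model"
    claims: list[IndependenceClaim] = field(default_factory=list)
    gof: GofStats | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    def loglik(self) -> float:
        return sum(s.fit.loglik for s in self.submodels.values())

    def k_params(self) -> int:
        return sum(s.fit.n_params for s in self.submodels.values())


def _analysis_rows(dag: DagModel, data: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [v for v in dag.vertices if v not in data.columns]
    if missing_cols:
        raise InvalidArgumentError(f"data lacks model variables: {missing_cols}")
    sub = data[dag.vertices].apply(pd.to_numeric)
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        logger.info("dropped %d row(s) with missing values in model variables", dropped)
    return complete


def fit_submodels(dag: DagModel, data: pd.DataFrame, name: str = "model") -> FittedSem:
    """Fit one OLS regression per endogenous vertex on its DAG parents.

    Rows with a missing value in any model variable are dropped (logged),
    so every submodel — and the saturated comparison — uses one common row
    set.  Standardized slopes are computed post hoc as raw * SD(x)/SD(y)
    with sample SDs from the analysis rows.
    """
    rows = _analysis_rows(dag, data)
    max_parents = max((len(dag.parents(v)) for v in dag.endogenous), default=0)
    if len(rows) < max_parents + 2:
        raise InvalidArgumentError(
            f"n={len(rows)} rows < largest submodel ({max_parents} parents) + 2")
    sds = rows.std(ddof=1)
    submodels: dict[str, Submodel] = {}
    for v in dag.endogenous:
        parents = sorted(dag.parents(v))
        fit = fit_ols(rows[v].to_numpy(), rows[parents].to_numpy(),
                      response=v, predictors=parents)
        std = {p: float(c * sds[p] / sds[v]) if sds[v] > 0 else 0.0
               for p, c in zip(parents, fit.coef)}
        submodels[v] = Submodel(fit=fit, std_coef=std)
    return FittedSem(dag=dag, data=rows, submodels=submodels, name=name)


# ---------------------------------------------------------------------------
# d-separation and goodness of fit
# ---------------------------------------------------------------------------

def basis_set(dag: DagModel) -> list[IndependenceClaim]:
    """Union basis set of testable independence claims implied by the DAG.

    One claim per unordered non-adjacent pair, skipping pairs joined by a
    correlated-error term and pairs of two exogenous vertices (their
    covariance is unconstrained by the model).  The conditioning set is the
    union of both vertices' parents; the response is whichever vertex comes
    later in the deterministic topological order.
    """
    order = {v: i for i, v in enumerate(dag.topological_order())}
    exo = dag.exogenous
    claims = []
    for a, b in combinations(sorted(dag.graph.nodes), 2):
        if dag.adjacent(a, b):
            continue
        if frozenset((a, b)) in dag.correlated:
            continue
        if a in exo and b in exo:
            continue
        response, other = (a, b) if order[a] > order[b] else (b, a)
        if response in exo:
            # An exogenous vertex can always be ordered first; keep the
            # endogenous vertex as the regression response.
            response, other = other, response
        cond = tuple(sorted((dag.parents(a) | dag.parents(b)) - {a, b}))
        claims.append(IndependenceClaim(response=response, other=other,
                                        conditioning_set=cond))
    return claims


def dsep_tests(fitted: FittedSem) -> list[IndependenceClaim]:
    """Test every basis-set claim on the fitted model's analysis rows.

    Each claim regresses the response on its conditioning set plus the
    other vertex; the claim's p-value is the two-sided t-test of the other
    vertex's coefficient.  Claims are stored on the fit and returned.
    """
    rows = fitted.data
    tested = []
    for claim in basis_set(fitted.dag):
        predictors = list(claim.conditioning_set) + [claim.other]
        fit = fit_ols(rows[claim.response].to_numpy(),
                      rows[predictors].to_numpy(),
                      response=claim.response, predictors=predictors)
        tested.append(replace(claim, p_value=float(fit.p_values[-1]),
                              coefficient=float(fit.coef[-1])))
    fitted.claims = tested
    return tested


def fishers_c(p_values: Sequence[float], clamp: float = _P_CLAMP,
              ) -> tuple[float, int, float]:
    """Fisher's C = -2 sum(ln p) with df = 2k and its upper-tail chi-square p.

    An empty claim list (saturated topology) gives ``(0, 0, 1)`` by
    convention.  Zero p-values are clamped at `clamp` with a warning so the
    statistic stays finite.
    """
    ps = list(p_values)
    if not ps:
        return 0.0, 0, 1.0
    if any(p < clamp for p in ps):
        logger.warning("clamping %d d-sep p-value(s) at %g for Fisher's C",
                       sum(p < clamp for p in ps), clamp)
    ps = [max(float(p), clamp) for p in ps]
    if any(p > 1 for p in ps):
        raise InvalidArgumentError("p-values must lie in (0, 1]")
    c = -2.0 * float(np.sum(np.log(ps)))
    df = 2 * len(ps)
    return c, df, float(stats.chi2.sf(c, df))


def _saturated_loglik(fitted: FittedSem) -> tuple[float, int]:
    """Log-likelihood and parameter count of the saturated comparison model.

    The saturated model frees exactly the constraints the causal model
    imposes: each endogenous vertex is regressed on its parents *plus*
    every vertex it forms a basis-set independence claim with.  Pairs
    joined by a correlated-error term carry a free parameter in both
    models and therefore cancel, so the chi-square degrees of freedom
    equal the number of independence claims.
    """
    rows = fitted.data
    dag = fitted.dag
    extra: dict[str, set[str]] = {}
    for claim in basis_set(dag):
        extra.setdefault(claim.response, set()).add(claim.other)
    loglik, k = 0.0, 0
    for v in dag.endogenous:
        preds = sorted(dag.parents(v) | extra.get(v, set()))
        fit = fit_ols(rows[v].to_numpy(), rows[preds].to_numpy(),
                      response=v, predictors=preds)
        loglik += fit.loglik
        k += fit.n_params
    return loglik, k


def chisq_vs_saturated(fitted: FittedSem) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square of the model against the saturated model.

    chi2 = -2 (lnL_model - lnL_saturated), df = difference in free-parameter
    counts; non-negative by nesting.  df = 0 (model already saturated)
    returns ``(0, 0, 1)``.
    """
    ll_sat, k_sat = _saturated_loglik(fitted)
    ll_mod, k_mod = fitted.loglik(), fitted.k_params()
    df = k_sat - k_mod
    if df == 0:
        return 0.0, 0, 1.0
    chisq = max(-2.0 * (ll_mod - ll_sat), 0.0)
    return float(chisq), int(df), float(stats.chi2.sf(chisq, df))


def model_aicc(fitted: FittedSem) -> float:
    """Small-sample-corrected AIC over the summed submodel likelihoods.

    K counts every slope, intercept and residual variance across the
    submodels; AICc = -2 lnL + 2K + 2K(K+1)/(n-K-1).
    """
    n, k = fitted.n, fitted.k_params()
    if n <= k + 1:
        raise UndefinedStatisticError(f"AICc undefined: n={n} <= K+1={k + 1}")
    ll = fitted.loglik()
    return float(-2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1))


def correlated_errors(fitted: FittedSem) -> list[dict]:
    """Residual Pearson correlation (with t-test p) for each ``~~`` pair.

    Endogenous vertices contribute their submodel residuals; exogenous
    vertices their centered raw values.
    """
    rows = fitted.data
    n = len(rows)

    def _resid(v: str) -> np.ndarray:
        if v in fitted.submodels:
            return fitted.submodels[v].fit.residuals
        vals = rows[v].to_numpy(dtype=float)
        return vals - vals.mean()

    out = []
    for pair in sorted(fitted.dag.correlated, key=sorted):
        a, b = sorted(pair)
        ra, rb = _resid(a), _resid(b)
        denom = np.sqrt((ra @ ra) * (rb @ rb))
        r = float(ra @ rb / denom) if denom > 0 else 0.0
        r_c = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
        t = r_c * np.sqrt((n - 2) / (1.0 - r_c * r_c))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
        out.append({"var_a": a, "var_b": b, "r": r, "p": p, "n": n})
    return out


# ---------------------------------------------------------------------------
# effects, modification, comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathEffect:
    """Direct and indirect (path-product) effects of source on target."""

    source: str
    target: str
    paths: tuple[tuple[tuple[str, ...], float], ...]  # (vertex path, effect)
    direct: float          # standardized coefficient of the length-1 path, else 0
    total_indirect: float  # sum of path products over paths of length >= 2

    @property
    def total(self) -> float:
        return self.direct + self.total_indirect


def indirect_effects(fitted: FittedSem, source: str, target: str) -> PathEffect:
    """Enumerate all directed source->target paths and multiply standardized
    coefficients along each; indirect effects sum over paths of length >= 2."""
    for v in (source, target):
        if v not in fitted.dag.graph:
            raise InvalidArgumentError(f"unknown vertex {v!r}")
    paths = []
    direct = 0.0
    indirect = 0.0
    for path in nx.all_simple_paths(fitted.dag.graph, source, target):
        effect = 1.0
        for u, v in zip(path, path[1:]):
            effect *= fitted.submodels[v].std_coef[u]
        paths.append((tuple(path), float(effect)))
        if len(path) == 2:
            direct += effect
        else:
            indirect += effect
    return PathEffect(source=source, target=target, paths=tuple(paths),
                      direct=float(direct), total_indirect=float(indirect))


def suggest_modifications(claims: Iterable[IndependenceClaim],
                          alpha: float = 0.05) -> list[dict]:
    """Rank failed independence claims as one-step modification suggestions.

    Each failed claim (p < alpha) yields two alternative repairs — add the
    directed edge other -> response, or add a correlated-error term — in
    ascending p order.  Nothing is ever applied automatically.
    """
    failed = sorted((c for c in claims if c.p_value is not None and c.p_value < alpha),
                    key=lambda c: c.p_value)
    return [{"response": c.response, "other": c.other, "p_value": c.p_value,
             "coefficient": c.coefficient,
             "add_edge": f"{c.other} -> {c.response}",
             "add_correlation": f"{c.other} ~~ {c.response}"} for c in failed]


def fit_sem(dag: DagModel, data: pd.DataFrame, name: str = "model") -> FittedSem:
    """Fit submodels, run the d-separation tests and attach goodness of fit."""
    fitted = fit_submodels(dag, data, name=name)
    claims = dsep_tests(fitted)
    c, cdf, cp = fishers_c([cl.p_value for cl in claims])
    x2, xdf, xp = chisq_vs_saturated(fitted)
    try:
        aicc = model_aicc(fitted)
    except UndefinedStatisticError as exc:
        logger.warning("model %r: %s; reporting AICc as NaN", name, exc)
        aicc = float("nan")
    fitted.gof = GofStats(fisher_c=c, fisher_df=cdf, fisher_p=cp,
                          chisq=x2, chisq_df=xdf, chisq_p=xp,
                          aicc=aicc, k_params=fitted.k_params())
    return fitted


def compare_models(fits: Sequence[FittedSem], alpha: float = 0.05) -> pd.DataFrame:
    """Rank fitted models by AICc with the both-tests support rule.

    A model is *supported* when both its Fisher's C p and its chi-square p
    exceed `alpha`.  Models fitted to different row sets are compared with
    a warning (their likelihoods are not strictly commensurable).
    """
    if not fits:
        raise InvalidArgumentError("no fitted models to compare")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        logger.warning("comparing models fitted to different row counts: %s", sorted(ns))
    rows = []
    for f in fits:
        g = f.gof
        if g is None:
            raise InvalidArgumentError(f"model {f.name!r} lacks goodness-of-fit stats; "
                                       "fit it with fit_sem()")
        rows.append({"model": f.name, "fisher_c": g.fisher_c, "fisher_df": g.fisher_df,
                     "fisher_p": g.fisher_p, "chisq": g.chisq, "chisq_df": g.chisq_df,
                     "chisq_p": g.chisq_p, "aicc": g.aicc, "n": f.n,
                     "supported": bool(g.fisher_p > alpha and g.chisq_p > alpha)})
    table = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    cols = ["model", "fisher_c", "fisher_df", "fisher_p", "chisq", "chisq_df",
            "chisq_p", "aicc", "delta_aicc", "n", "supported"]
    return table[cols]
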