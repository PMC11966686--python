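"""Synthetic inputs with the statistical structure the analysis assumes.

Real long-term monitoring data — community time series, trait tables,
phylogenies and daily temperatures — cannot ship with a desk-scale
package, so this module generates stand-ins whose *controllable* structure
matches what the downstream estimators assume:

* a pure-birth phylogeny with unique tip labels;
* traits evolving as Brownian motion on that tree, with a tunable shared
  latent axis (the planted pace-of-life continuum);
* per-site community series with log-normal abundances, a planted
  pairwise synchrony, per-species coefficients of variation in a chosen
  range, and Bernoulli year sampling (irregular coverage);
* daily temperatures as a sinusoidal annual cycle plus a monotone
  cross-site offset (the latitudinal gradient) and day-to-day noise;
* linear-Gaussian SEM tables generated from an arbitrary DAG with planted
  path coefficients, for parameter-recovery and calibration studies.

Everything is driven by explicit integer seeds: the same configuration
and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .diversity import Phylogeny, TraitTable, TraitType
from .errors import InvalidArgumentError
from .psem import DagModel, parse_dag

__all__ = [
    "SimulationConfig", "PlantedSemConfig", "simulate_phylogeny",
    "simulate_traits", "simulate_abundances", "simulate_daily_temperature",
    "simulate_sem_dataset", "default_sem_config",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the community-series generator.

    `richness_gradient` gives the expected per-site richness as a
    ``(low, high)`` pair interpolated linearly over the site index (sites
    are ordered warm to cold, so richness usually declines), or an
    explicit per-site sequence.  `synchrony_rho` is the common pairwise
    correlation of species' log-abundance fluctuations and must keep the
    equicorrelation matrix positive semi-definite, i.e. lie in
    ``[-1/(S-1), 1]``.  `cv_range` bounds the per-species coefficient of
    variation of abundance; `mean_log_sd` spreads species' baseline
    abundances on the log scale (0 makes all species equally abundant).
    """

    n_sites: int = 30
    n_species_pool: int = 60
    n_years: int = 20
    richness_gradient: tuple[float, float] | Sequence[float] = (25.0, 10.0)
    synchrony_rho: float = 0.3
    cv_range: tuple[float, float] = (0.2, 0.8)
    sampling_prob: float = 0.85
    start_year: int = 2000
    mean_log_abundance: float = math.log(50.0)
    mean_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_sites", "n_species_pool", "n_years"):
            if getattr(self, name) < 1:
                raise InvalidArgumentError(f"{name} must be >= 1")
        lo, hi = self.cv_range
        if not (0 < lo <= hi):
            raise InvalidArgumentError("cv_range must satisfy 0 < min <= max")
        if not (0 < self.sampling_prob <= 1):
            raise InvalidArgumentError("sampling_prob must lie in (0, 1]")

    def site_richness(self) -> np.ndarray:
        g = self.richness_gradient
        if len(g) == 2 and self.n_sites != 2:
            vals = np.linspace(g[0], g[1], self.n_sites)
        else:
            vals = np.asarray(g, dtype=float)
            if vals.size != self.n_sites:
                raise InvalidArgumentError(
                    f"richness_gradient has {vals.size} entries for {self.n_sites} sites")
        vals = np.clip(np.round(vals), 1, self.n_species_pool)
        return vals.astype(int)


@dataclass(frozen=True)
class PlantedSemConfig:
    """A linear-Gaussian system on a DAG with planted edge coefficients."""

    dag: DagModel
    coefficients: Mapping[tuple[str, str], float]
    noise_sd: Mapping[str, float] = field(default_factory=dict)
    n: int = 500
    seed: int = 0

    def __post_init__(self):
        for (u, v) in self.coefficients:
            if not self.dag.graph.has_edge(u, v):
                raise InvalidArgumentError(f"coefficient for non-edge {u} -> {v}")
        for v, sd in self.noise_sd.items():
            if sd < 0:
                raise InvalidArgumentError(f"noise_sd[{v!r}] must be >= 0")


# ---------------------------------------------------------------------------
# phylogeny and traits
# ---------------------------------------------------------------------------

def simulate_phylogeny(n_species: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) tree with `n_species` tips labelled ``sp001``...

    Branch lengths are exponential waiting times (birth rate 1); the same
    seed always yields the same Newick string.
    """
    if n_species < 2:
        raise InvalidArgumentError(f"n_species must be >= 2, got {n_species}")
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species,
        rng=random.Random(int(seed)))
    # Relabel tips deterministically in leaf-traversal order.
    width = max(3, len(str(n_species)))
    tree.taxon_namespace = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        taxon = dendropy.Taxon(label=f"sp{i:0{width}d}")
        tree.taxon_namespace.add_taxon(taxon)
        leaf.taxon = taxon
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.length <= 0:
            edge.length = 1e-8 if edge.head_node.parent_node is not None else None
    return Phylogeny([tree])


def _brownian_covariance(phylo: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Shared-path-length covariance of Brownian motion on the first tree."""
    tree = phylo.trees[0]
    tree.calc_node_root_distances()
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    labels = [nd.taxon.label for nd in leaves]
    depths = np.array([nd.root_distance for nd in leaves])
    D = phylo.distance_matrix().loc[labels, labels].to_numpy()
    C = (depths[:, None] + depths[None, :] - D) / 2.0
    return labels, C


def simulate_traits(phylogeny: Phylogeny, n_numeric: int = 3, n_nominal: int = 2,
                    pol_weight: float = 0.7, seed: int = 0) -> TraitTable:
    """Traits with a planted pace-of-life axis evolving on the phylogeny.

    Each numeric trait is ``pol_weight * L + (1 - pol_weight) * E_k`` where
    L is one shared Brownian latent axis on the tree and the E_k are
    independent Brownian deviates: `pol_weight` = 1 collapses all numeric
    traits onto a single axis, 0 makes them independent.  Nominal traits
    are drawn uniformly from small level sets.  The first numeric trait is
    named ``generation_length`` and serves as the natural slow-life-history
    anchor downstream.
    """
    if not (0.0 <= pol_weight <= 1.0):
        raise InvalidArgumentError(f"pol_weight must lie in [0, 1], got {pol_weight}")
    if n_numeric < 1:
        raise InvalidArgumentError("need at least one numeric trait")
    labels, C = _brownian_covariance(phylogeny)
    if len(labels) < 2:
        raise InvalidArgumentError("phylogeny needs >= 2 tips")
    rng = np.random.default_rng(int(seed))
    jitter = 1e-10 * np.trace(C) / len(labels)
    L_chol = np.linalg.cholesky(C + jitter * np.eye(len(labels)))

    latent = L_chol @ rng.standard_normal(len(labels))
    numeric_names = ["generation_length", "body_size"][:n_numeric]
    numeric_names += [f"trait_num{k}" for k in range(len(numeric_names) + 1,
                                                     n_numeric + 1)]
    cols: dict[str, np.ndarray | list] = {}
    schema: dict[str, TraitType] = {}
    for name in numeric_names:
        noise = L_chol @ rng.standard_normal(len(labels))
        cols[name] = pol_weight * latent + (1.0 - pol_weight) * noise
        schema[name] = TraitType("numeric")

    nominal_levels = [("egg", "larva", "pupa", "adult"), ("sessile", "motile"),
                      ("low", "mid", "high")]
    for k in range(n_nominal):
        levels = nominal_levels[k % len(nominal_levels)]
        name = ["overwintering_stage", "motility"][k] if k < 2 else f"trait_nom{k + 1}"
        cols[name] = list(rng.choice(levels, size=len(labels)))
        schema[name] = TraitType("nominal")

    return TraitTable(pd.DataFrame(cols, index=pd.Index(labels, name="species_id")),
                      schema)


# ---------------------------------------------------------------------------
# community abundance series
# ---------------------------------------------------------------------------

def _equicorrelated_factor(s: int, rho: float) -> np.ndarray:
    """Matrix A with A @ A.T equal to the equicorrelation matrix."""
    if s > 1 and not (-1.0 / (s - 1) - 1e-12 <= rho <= 1.0 + 1e-12):
        raise InvalidArgumentError(
            f"synchrony_rho={rho} gives a non-positive-semi-definite correlation "
            f"matrix for S={s} species (needs -1/(S-1) <= rho <= 1)")
    R = np.full((s, s), rho)
    np.fill_diagonal(R, 1.0)
    eigvals, eigvecs = np.linalg.eigh(R)
    eigvals = np.clip(eigvals, 0.0, None)
    return eigvecs * np.sqrt(eigvals)


def simulate_abundances(config: SimulationConfig) -> pd.DataFrame:
    """Long-format community series: ``site_id, year, species_id, abundance``.

    Per site, a fixed species subset of the pool is drawn to match the
    richness gradient; log-abundances are equicorrelated Gaussian with
    pairwise correlation `synchrony_rho` and per-species log-scale SDs
    chosen so the abundance coefficients of variation fall in `cv_range`
    (sigma_log = sqrt(ln(1 + CV^2)), exact for the log-normal); years are
    retained independently with `sampling_prob`.  Abundances are strictly
    positive for present species.
    """
    rng = np.random.default_rng(int(config.seed))
    richness = config.site_richness()
    width = max(3, len(str(config.n_species_pool)))
    pool = [f"sp{i + 1:0{width}d}" for i in range(config.n_species_pool)]
    years = np.arange(config.start_year, config.start_year + config.n_years)

    records = []
    for i in range(config.n_sites):
        site = f"site{i + 1:03d}"
        members = sorted(rng.choice(pool, size=richness[i], replace=False))
        s = len(members)
        cvs = rng.uniform(config.cv_range[0], config.cv_range[1], size=s)
        sigma_log = np.sqrt(np.log1p(cvs ** 2))
        mu_log = (config.mean_log_abundance
                  + config.mean_log_sd * rng.standard_normal(s)
                  - 0.5 * sigma_log ** 2)
        A = _equicorrelated_factor(s, config.synchrony_rho)
        z = (A @ rng.standard_normal((s, config.n_years)))
        log_ab = mu_log[:, None] + sigma_log[:, None] * z
        sampled = rng.random(config.n_years) < config.sampling_prob
        if not sampled.any():
            sampled[rng.integers(config.n_years)] = True  # every site keeps >= 1 year
        for t, year in enumerate(years):
            if not sampled[t]:
                continue
            for j, sp in enumerate(members):
                records.append((site, int(year), sp, float(np.exp(log_ab[j, t]))))
    return pd.DataFrame(records, columns=["site_id", "year", "species_id", "abundance"])


# ---------------------------------------------------------------------------
# daily temperature
# ---------------------------------------------------------------------------

def simulate_daily_temperature(n_sites: int, n_years: int,
                               gradient_per_site: float = 0.5, seed: int = 0, *,
                               start_year: int = 2000, base_mean_c: float = 4.0,
                               amplitude_c: float = 12.0,
                               noise_sd_c: float = 2.0) -> pd.DataFrame:
    """Daily mean temperatures: annual sine cycle + site offset + day noise.

    Site 1 is the warmest; each later site is `gradient_per_site` degC
    colder on annual average, emulating a south-to-north gradient.  Every
    day of every simulated year is present (interpolated series have no
    gaps).  Columns: ``site_id, date, tmean_c`` with ISO dates.
    """
    if n_sites < 1 or n_years < 1:
        raise InvalidArgumentError("n_sites and n_years must be >= 1")
    rng = np.random.default_rng(int(seed))
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31",
                          freq="D")
    doy = dates.dayofyear.to_numpy()
    cycle = amplitude_c * np.sin(2.0 * np.pi * (doy - 110) / 365.25)
    frames = []
    for i in range(n_sites):
        temps = (base_mean_c - gradient_per_site * i + cycle
                 + noise_sd_c * rng.standard_normal(len(dates)))
        frames.append(pd.DataFrame({"site_id": f"site{i + 1:03d}",
                                    "date": dates.strftime("%Y-%m-%d"),
                                    "tmean_c": temps}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# linear-Gaussian SEM tables
# ---------------------------------------------------------------------------

def simulate_sem_dataset(cfg: PlantedSemConfig) -> pd.DataFrame:
    """Generate a table from a DAG with planted linear coefficients.

    Variables are built in topological order: exogenous vertices are
    standard normal; each endogenous vertex is the coefficient-weighted
    sum of its parents plus ``Normal(0, noise_sd)`` (default SD 1).
    """
    rng = np.random.default_rng(int(cfg.seed))
    data: dict[str, np.ndarray] = {}
    for v in cfg.dag.topological_order():
        parents = sorted(cfg.dag.parents(v))
        if not parents:
            data[v] = rng.standard_normal(cfg.n)
            continue
        val = np.zeros(cfg.n)
        for p in parents:
            val += cfg.coefficients.get((p, v), 0.0) * data[p]
        sd = float(cfg.noise_sd.get(v, 1.0))
        if sd > 0:
            val = val + sd * rng.standard_normal(cfg.n)
        data[v] = val
    return pd.DataFrame(data)[cfg.dag.vertices]


#: Planted standardized-scale coefficients used for the default
#: diversity-stability topology in calibration studies: every edge carries
#: a moderate effect and each endogenous vertex keeps unit noise.
_DEFAULT_COEFS = {
    ("SR", "FDis"): 0.5, ("SR", "MPD"): 0.4, ("SR", "CWPoL"): -0.3,
    ("mT", "FDis"): 0.3, ("mT", "MPD"): 0.2, ("mT", "CWPoL"): 0.2,
    ("sdT", "FDis"): -0.2, ("sdT", "MPD"): -0.2, ("sdT", "CWPoL"): 0.15,
    ("FDis", "logSpop"): 0.4, ("MPD", "logSpop"): 0.3, ("CWPoL", "logSpop"): -0.25,
    ("mT", "logSpop"): 0.2, ("sdT", "logSpop"): -0.15,
    ("FDis", "logPhi"): 0.3, ("MPD", "logPhi"): 0.25, ("CWPoL", "logPhi"): 0.2,
    ("mT", "logPhi"): 0.15, ("sdT", "logPhi"): -0.1,
    ("logSpop", "logScom"): 0.6, ("logPhi", "logScom"): 0.5,
}


def default_sem_config(n: int = 200, seed: int = 0,
                       noise_sd: float = 1.0) -> PlantedSemConfig:
    """Planted linear system on the default diversity-stability DAG.

    Used for type-I-error calibration and recovery studies: the data obey
    the default topology exactly (independent errors everywhere), so every
    basis-set independence claim is true by construction.
    """
    from .psem import DEFAULT_MODEL_SPEC
    dag = parse_dag(DEFAULT_MODEL_SPEC)
    noise = {v: noise_sd for v in dag.endogenous}
    return PlantedSemConfig(dag=dag, coefficients=dict(_DEFAULT_COEFS),
                            noise_sd=noise, n=n, seed=seed)
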