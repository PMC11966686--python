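"""Functional and phylogenetic community metrics.

Four per-community quantities feed the diversity-stability models:

* **SR** — species richness, the count of species with positive abundance;
* **FDis** — functional dispersion: the abundance-weighted mean distance of
  species from the community's weighted centroid in a mixed-type trait
  space (Gower dissimilarities embedded by principal coordinates, with the
  standard correction for negative-eigenvalue axes);
* **MPD** — mean pairwise patristic distance among the species present,
  averaged across trees when the phylogeny is a posterior sample;
* **CWPoL** — community-weighted mean position on a pace-of-life axis, the
  first principal component of the standardized species traits, with its
  sign anchored so that high scores mean a slow life history.

Metrics are computed per site-year and then averaged over each site's
sampled window years, which is the unit of analysis downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .errors import (DegenerateTraitsError, InvalidArgumentError,
                     MissingDataError)

__all__ = [
    "TraitType", "TraitTable", "Phylogeny", "PaceOfLifeAxis", "TraitSpace",
    "gower_matrix", "pace_of_life_axis", "community_weighted_mean",
    "functional_dispersion", "mean_pairwise_distance", "site_year_metrics",
    "temporal_average",
]

_EIG_RTOL = 1e-9  # relative threshold below which PCoA eigenvalues are noise


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitType:
    """Declared type of one trait column."""

    kind: str                         # "numeric" | "ordinal" | "nominal"
    levels: tuple[str, ...] | None = None   # ordered levels, ordinal only

    def __post_init__(self):
        if self.kind not in ("numeric", "ordinal", "nominal"):
            raise InvalidArgumentError(f"unknown trait kind {self.kind!r}")
        if self.kind == "ordinal" and not self.levels:
            raise InvalidArgumentError("ordinal trait needs declared levels")


@dataclass
class TraitTable:
    """Species x trait table with a declared type schema.

    `data` is indexed by species id; every column must appear in `schema`.
    Ordinal levels are mapped to their rank in the declared order wherever
    a numeric representation is needed.
    """

    data: pd.DataFrame
    schema: dict[str, TraitType]

    def __post_init__(self):
        undeclared = [c for c in self.data.columns if c not in self.schema]
        if undeclared:
            raise InvalidArgumentError(f"traits missing from schema: {undeclared}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise InvalidArgumentError(f"duplicate species rows: {dupes}")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def numeric_frame(self, include_nominal: bool = False) -> pd.DataFrame:
        """Numeric view: ordinal traits as level ranks, nominal one-hot if asked."""
        cols = {}
        for name in self.data.columns:
            t = self.schema[name]
            col = self.data[name]
            if t.kind == "numeric":
                cols[name] = pd.to_numeric(col)
            elif t.kind == "ordinal":
                mapping = {lev: i for i, lev in enumerate(t.levels)}
                unknown = set(col.dropna()) - set(t.levels)
                if unknown:
                    raise InvalidArgumentError(
                        f"trait {name!r}: undeclared ordinal level(s) {sorted(unknown)}")
                cols[name] = col.map(mapping).astype(float)
            elif include_nominal:
                for lev in sorted(col.dropna().unique()):
                    cols[f"{name}={lev}"] = (col == lev).astype(float)
        return pd.DataFrame(cols, index=self.data.index)

    def subset(self, species: Iterable[str]) -> "TraitTable":
        species = list(species)
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise MissingDataError(f"species lacking trait rows: {missing}")
        return TraitTable(self.data.loc[species], self.schema)

    @classmethod
    def from_csv(cls, traits_path, schema_path) -> "TraitTable":
        """Load a traits CSV (first column = species id) and its YAML schema."""
        df = pd.read_csv(traits_path, index_col=0)
        df.index = df.index.astype(str)
        with open(schema_path) as fh:
            raw = yaml.safe_load(fh)
        schema = {}
        for name, decl in raw.items():
            if isinstance(decl, str):
                schema[name] = TraitType(kind=decl)
            else:
                schema[name] = TraitType(kind=decl["kind"],
                                         levels=tuple(decl.get("levels") or ()) or None)
        return cls(df, schema)

    def schema_to_yaml(self, path) -> None:
        out = {}
        for name, t in self.schema.items():
            out[name] = t.kind if t.levels is None else {"kind": t.kind,
                                                         "levels": list(t.levels)}
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

class Phylogeny:
    """One or more rooted trees with branch lengths over the same tip set.

    With several trees (e.g. a posterior sample from a published
    megaphylogeny) distance-based metrics average across trees.  Patristic
    distances are cached as a tip x tip matrix on first use.
    """

    def __init__(self, trees: Sequence[dendropy.Tree]):
        if not trees:
            raise InvalidArgumentError("need at least one tree")
        self.trees = list(trees)
        self._dist: pd.DataFrame | None = None

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        """Read tree(s) from a Newick file path or a Newick string."""
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        trees = dendropy.TreeList.get(data=text, schema="newick")
        return cls(list(trees))

    @property
    def tip_labels(self) -> list[str]:
        return sorted(t.label for t in self.trees[0].taxon_namespace)

    def distance_matrix(self) -> pd.DataFrame:
        """Mean patristic distance matrix across trees (tip x tip)."""
        if self._dist is None:
            mats = []
            for tree in self.trees:
                pdm = tree.phylogenetic_distance_matrix()
                taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
                labels = [t.label for t in taxa]
                m = np.zeros((len(taxa), len(taxa)))
                for i, a in enumerate(taxa):
                    for j in range(i + 1, len(taxa)):
                        d = pdm.patristic_distance(a, taxa[j])
                        m[i, j] = m[j, i] = d
                mats.append(pd.DataFrame(m, index=labels, columns=labels))
            base = mats[0]
            for other in mats[1:]:
                base = base + other.loc[base.index, base.columns]
            self._dist = base / len(mats)
        return self._dist

    def to_newick(self) -> str:
        return "".join(t.as_string(schema="newick") for t in self.trees)


# ---------------------------------------------------------------------------
# pace-of-life axis and community-weighted means
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PaceOfLifeAxis:
    """PC1 of the standardized species-pool traits, sign-anchored."""

    loadings: dict[str, float]
    scores: pd.Series                    # per species; zero mean over the pool
    explained_variance_fraction: float
    sign_flipped: bool


def pace_of_life_axis(traits: TraitTable, anchor_trait: str,
                      include_nominal: bool = False) -> PaceOfLifeAxis:
    """First principal component of the standardized trait matrix.

    Ordinal traits enter as integer level ranks; nominal traits are
    excluded by default (one-hot columns distort a life-history axis) but
    can be included.  Every column is z-scored, PC1 comes from the eigen-
    decomposition of the covariance matrix, and the axis is multiplied by
    -1 if the anchor trait (a slow-life-history trait such as generation
    length) loads negatively — so a high score always means slow pace of
    life.
    """
    X = traits.numeric_frame(include_nominal=include_nominal)
    if len(X) < 2:
        raise InvalidArgumentError("need >= 2 species for a principal axis")
    sds = X.std(ddof=1)
    usable = sds.index[sds > 0]
    if len(usable) < 2:
        raise DegenerateTraitsError(
            "fewer than 2 trait columns with variance after encoding")
    X = X[usable]
    if anchor_trait not in X.columns:
        raise InvalidArgumentError(
            f"anchor trait {anchor_trait!r} not among usable columns {list(X.columns)}")
    Z = (X - X.mean()) / X.std(ddof=1)
    if Z.isna().any().any():
        bad = Z.columns[Z.isna().any()].tolist()
        raise MissingDataError(f"missing trait values in column(s) {bad}")

    cov = np.cov(Z.to_numpy(), rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    pc1 = eigvecs[:, -1]
    flipped = pc1[list(Z.columns).index(anchor_trait)] < 0
    if flipped:
        pc1 = -pc1
    scores = pd.Series(Z.to_numpy() @ pc1, index=Z.index, name="pol_score")
    evf = float(eigvals[-1] / eigvals.sum()) if eigvals.sum() > 0 else 1.0
    return PaceOfLifeAxis(loadings=dict(zip(Z.columns, pc1.astype(float))),
                          scores=scores, explained_variance_fraction=evf,
                          sign_flipped=bool(flipped))


def community_weighted_mean(scores: Mapping[str, float],
                            abundances: Mapping[str, float]) -> float:
    """Abundance-weighted mean score: sum_j p_j * score_j over present species."""
    present = [(s, a) for s, a in abundances.items() if a > 0]
    total = sum(a for _, a in present)
    if total <= 0:
        raise InvalidArgumentError("total abundance is zero")
    missing = [s for s, _ in present if s not in scores]
    if missing:
        raise MissingDataError(f"species without scores: {missing}")
    return float(sum(a / total * scores[s] for s, a in present))


# ---------------------------------------------------------------------------
# Gower dissimilarity, PCoA embedding and functional dispersion
# ---------------------------------------------------------------------------

def gower_matrix(traits: TraitTable, max_missing: float = 0.5) -> pd.DataFrame:
    """Pairwise Gower dissimilarities over mixed-type traits.

    Numeric and ordinal (rank-coded) traits contribute range-scaled
    absolute differences; nominal traits contribute simple matching (0/1).
    Missing values drop out of a pair's average; a species missing more
    than `max_missing` of its traits is a data error.
    """
    numeric = traits.numeric_frame(include_nominal=False)
    nominal = [c for c in traits.data.columns if traits.schema[c].kind == "nominal"]
    n = len(traits.data)
    n_traits = numeric.shape[1] + len(nominal)
    if n_traits == 0:
        raise InvalidArgumentError("no traits to compare")

    miss_frac = (numeric.isna().sum(axis=1)
                 + traits.data[nominal].isna().sum(axis=1)) / n_traits
    bad = miss_frac.index[miss_frac > max_missing].tolist()
    if bad:
        raise MissingDataError(
            f"species exceeding missing-trait fraction {max_missing}: {bad}")

    num = numeric.to_numpy(dtype=float)
    ranges = np.nanmax(num, axis=0) - np.nanmin(num, axis=0) if num.size else np.array([])
    dsum = np.zeros((n, n))
    dcount = np.zeros((n, n))
    for k in range(num.shape[1]):
        col = num[:, k]
        valid = np.isfinite(col)
        both = np.outer(valid, valid)
        if ranges[k] > 0:
            diff = np.abs(col[:, None] - col[None, :]) / ranges[k]
        else:
            diff = np.zeros((n, n))  # constant trait: no dissimilarity signal
        dsum += np.where(both, diff, 0.0)
        dcount += both
    for name in nominal:
        col = traits.data[name].to_numpy()
        valid = pd.notna(col)
        both = np.outer(valid, valid)
        diff = (col[:, None] != col[None, :]).astype(float)
        dsum += np.where(both, diff, 0.0)
        dcount += both
    if np.any(dcount == 0):
        raise MissingDataError("some species pairs share no observed trait")
    D = dsum / dcount
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=traits.data.index, columns=traits.data.index)


@dataclass
class TraitSpace:
    """Principal-coordinates embedding of a Gower dissimilarity matrix.

    Negative-eigenvalue axes (generic for non-Euclidean Gower matrices)
    are kept as an *imaginary* coordinate block; squared distances in the
    embedding are ``d_real^2 - d_imag^2`` and reproduce the input
    dissimilarities exactly.
    """

    species: list[str]
    real: np.ndarray       # (n, r) real-axis coordinates
    imag: np.ndarray       # (n, s) imaginary-axis coordinates
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.index = {s: i for i, s in enumerate(self.species)}

    @classmethod
    def from_gower(cls, D: pd.DataFrame) -> "TraitSpace":
        d2 = D.to_numpy(dtype=float) ** 2
        n = d2.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ d2 @ J
        eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
        tol = _EIG_RTOL * max(np.abs(eigvals).max(), 1e-30)
        pos = eigvals > tol
        neg = eigvals < -tol
        real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
        imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
        return cls(species=list(D.index), real=real, imag=imag)

    def fdis(self, abundances: Mapping[str, float]) -> float:
        """Abundance-weighted dispersion around the weighted centroid.

        Per-species distance to the centroid is corrected for the
        imaginary block as ``z_j = sqrt(|d_real^2 - d_imag^2|)``; FDis is
        the weighted mean of the z_j.  A single-species community has
        dispersion zero by definition.
        """
        present = [(s, a) for s, a in abundances.items() if a > 0]
        if not present:
            raise InvalidArgumentError("no species with positive abundance")
        missing = [s for s, _ in present if s not in self.index]
        if missing:
            raise MissingDataError(f"species not in trait space: {missing}")
        if len(present) == 1:
            return 0.0
        idx = [self.index[s] for s, _ in present]
        w = np.array([a for _, a in present], dtype=float)
        p = w / w.sum()
        xr, xi = self.real[idx], self.imag[idx]
        cr = p @ xr
        ci = p @ xi
        d2r = ((xr - cr) ** 2).sum(axis=1)
        d2i = ((xi - ci) ** 2).sum(axis=1)
        z = np.sqrt(np.abs(d2r - d2i))
        return float(p @ z)


def functional_dispersion(traits: TraitTable, abundances: Mapping[str, float],
                          max_missing: float = 0.5) -> float:
    """FDis of one community (convenience wrapper; see :class:`TraitSpace`).

    For repeated communities over the same species pool, build the
    :class:`TraitSpace` once and call its ``fdis`` method instead.
    """
    return TraitSpace.from_gower(gower_matrix(traits, max_missing)).fdis(abundances)


# ---------------------------------------------------------------------------
# phylogenetic mean pairwise distance
# ---------------------------------------------------------------------------

def mean_pairwise_distance(phylogeny: Phylogeny, present_species: Iterable[str],
                           abundances: Mapping[str, float] | None = None,
                           weighted: bool = False) -> float:
    """Mean pairwise patristic distance among the species present.

    Unweighted (default): arithmetic mean over unordered pairs.  Weighted:
    ``sum_{i != j} p_i p_j d_ij / sum_{i != j} p_i p_j`` with relative
    abundances p.  Fewer than 2 species returns NaN (the value is
    undefined and is excluded from temporal averages downstream); species
    absent from the tree raise a mapping error listing them.
    """
    present = sorted(set(present_species))
    D = phylogeny.distance_matrix()
    missing = [s for s in present if s not in D.index]
    if missing:
        raise MissingDataError(f"species not on the phylogeny: {missing}")
    if len(present) < 2:
        return float("nan")
    sub = D.loc[present, present].to_numpy()
    if weighted:
        if abundances is None:
            raise InvalidArgumentError("weighted MPD needs abundances")
        w = np.array([abundances.get(s, 0.0) for s in present], dtype=float)
        W = np.outer(w, w)
        np.fill_diagonal(W, 0.0)
        if W.sum() <= 0:
            return float("nan")
        return float((W * sub).sum() / W.sum())
    iu = np.triu_indices(len(present), k=1)
    return float(sub[iu].mean())


# ---------------------------------------------------------------------------
# per-site-year metrics and temporal averaging
# ---------------------------------------------------------------------------

def site_year_metrics(abundance: pd.DataFrame, traits: TraitTable,
                      phylogeny: Phylogeny, axis: PaceOfLifeAxis,
                      mpd_weighted: bool = False) -> pd.DataFrame:
    """SR, FDis, MPD and CWPoL for every site-year in a long abundance table.

    Only species with positive abundance in a given year enter that year's
    metrics.  Returns a frame with columns ``site_id, year, SR, FDis, MPD,
    CWPoL``; MPD is NaN for single-species years.
    """
    space = TraitSpace.from_gower(gower_matrix(traits))
    scores = axis.scores.to_dict()
    rows = []
    for (site, year), grp in abundance.groupby(["site_id", "year"], sort=True):
        ab = grp.groupby("species_id")["abundance"].sum()
        ab = ab[ab > 0]
        if ab.empty:
            continue
        ab_map = {str(k): float(v) for k, v in ab.items()}
        rows.append({
            "site_id": str(site), "year": int(year), "SR": int(len(ab_map)),
            "FDis": space.fdis(ab_map),
            "MPD": mean_pairwise_distance(phylogeny, ab_map, ab_map,
                                          weighted=mpd_weighted),
            "CWPoL": community_weighted_mean(scores, ab_map),
        })
    return pd.DataFrame(rows, columns=["site_id", "year", "SR", "FDis", "MPD", "CWPoL"])


def temporal_average(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-site temporal means of SR, FDis, MPD and CWPoL.

    MPD averages over the years where it is defined; the count of
    contributing years is reported per metric.
    """
    out = []
    for site, grp in rows.groupby("site_id"):
        rec = {"site_id": str(site), "n_years": len(grp)}
        for col in ("SR", "FDis", "MPD", "CWPoL"):
            vals = grp[col].dropna()
            rec[col] = float(vals.mean()) if len(vals) else float("nan")
            rec[f"n_years_{col.lower()}"] = int(len(vals))
        out.append(rec)
    return pd.DataFrame(out)
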