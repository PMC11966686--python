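"""End-to-end orchestration: raw files in, ranked causal models out.

The pipeline chains the analysis stages in their natural order —
site selection -> climate summaries -> diversity metrics -> stability
decomposition -> Spearman screening -> piecewise SEMs (one per climate
variable, growing and freezing degree days) -> model comparison — writing
every intermediate table to the output directory so each stage can be
audited, plus a JSON run log recording the seed, row counts and every
excluded site.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import correlation_matrix, correlations_to_frame
from .climate import climate_table, read_daily_climate
from .diversity import (Phylogeny, TraitTable, pace_of_life_axis,
                        site_year_metrics, temporal_average)
from .errors import InvalidArgumentError
from .psem import DEFAULT_MODEL_SPEC, compare_models, fit_sem, indirect_effects, parse_dag
from .sites import select_sites, windows_to_frame
from .stability import stability_table
from .synthetic import (SimulationConfig, simulate_abundances,
                        simulate_daily_temperature, simulate_phylogeny,
                        simulate_traits)

__all__ = ["PipelineConfig", "run_pipeline", "generate_example_dataset", "PRESETS"]

logger = logging.getLogger(__name__)

STAGES = ("select", "climate", "metrics", "stability", "correlate", "sem")


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run (serialisable to YAML)."""

    abundance: str
    traits: str
    trait_schema: str
    trees: str
    climate: str
    dag_spec: str = ""            # empty -> built-in default topology
    out_dir: str = "divstab_out"
    window_len: int = 20
    min_sampled: int = 5
    min_span: int = 15
    gdd_base: float = 5.0
    fdd_threshold: float = 0.0
    mpd_weighted: bool = False
    anchor_trait: str = "generation_length"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def validate(self) -> None:
        for name in ("abundance", "traits", "trait_schema", "trees", "climate"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise InvalidArgumentError(f"{name} file not found: {p}")
        if self.dag_spec and not Path(self.dag_spec).exists():
            raise InvalidArgumentError(f"dag_spec file not found: {self.dag_spec}")
        for name in ("window_len", "min_sampled", "min_span"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")


def _write(df: pd.DataFrame, out: Path, name: str, log: dict) -> None:
    path = out / name
    df.to_csv(path, index=False)
    log.setdefault("outputs", {})[name] = len(df)


def run_pipeline(config: PipelineConfig, upto: str = "sem") -> dict:
    """Run the pipeline through stage `upto` (default: everything).

    Returns a dict of the computed objects (windows, tables, fitted
    models); all tables are also written under ``config.out_dir`` together
    with ``run_log.json``.
    """
    if upto not in STAGES:
        raise InvalidArgumentError(f"unknown stage {upto!r}; stages: {STAGES}")
    last = STAGES.index(upto)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "seed": config.seed, "exclusions": {}}
    results: dict = {}

    abundance = pd.read_csv(config.abundance, dtype={"site_id": str, "species_id": str})
    log["input_rows"] = {"abundance": len(abundance)}

    # --- stage: site selection -------------------------------------------
    retained, excluded = select_sites(abundance, window_len=config.window_len,
                                      min_sampled=config.min_sampled,
                                      min_span=config.min_span)
    results["windows"], results["excluded_windows"] = retained, excluded
    _write(windows_to_frame(retained + excluded), out, "site_selection.csv", log)
    log["exclusions"]["site_selection"] = [
        {"site_id": w.site_id, "rule": w.exclusion_rule} for w in excluded]

    if last >= STAGES.index("climate"):
        daily = read_daily_climate(config.climate)
        clim = climate_table(daily, retained, base_c=config.gdd_base,
                             threshold_c=config.fdd_threshold)
        results["climate"] = clim
        _write(clim, out, "climate_summary.csv", log)

    if last >= STAGES.index("metrics"):
        traits = TraitTable.from_csv(config.traits, config.trait_schema)
        phylo = Phylogeny.from_newick(config.trees)
        axis = pace_of_life_axis(traits, anchor_trait=config.anchor_trait)
        results["axis"] = axis
        # restrict to sampled years inside each retained window
        keep = pd.concat([abundance[(abundance["site_id"] == w.site_id)
                                    & abundance["year"].isin(w.sampled_years)]
                          for w in retained]) if retained else abundance.iloc[:0]
        per_year = site_year_metrics(keep, traits, phylo, axis,
                                     mpd_weighted=config.mpd_weighted)
        per_site = temporal_average(per_year)
        results["metrics_site_year"], results["metrics_site"] = per_year, per_site
        _write(per_year, out, "metrics_site_year.csv", log)
        _write(per_site, out, "metrics_site.csv", log)

    if last >= STAGES.index("stability"):
        stab, stab_excl = stability_table(abundance, retained)
        results["stability"] = stab
        log["exclusions"]["stability"] = stab_excl
        _write(stab, out, "stability.csv", log)

    if last >= STAGES.index("correlate"):
        site_tables = {}
        for var in ("GDD", "FDD"):
            cvar = results["climate"]
            cw = cvar[cvar["variable"] == var][["site_id", "mT", "sdT"]]
            tbl = (results["metrics_site"][["site_id", "SR", "FDis", "MPD", "CWPoL"]]
                   .merge(cw, on="site_id")
                   .merge(results["stability"][["site_id", "log_S_com", "log_S_pop",
                                                "log_phi"]], on="site_id")
                   .rename(columns={"log_S_com": "logScom", "log_S_pop": "logSpop",
                                    "log_phi": "logPhi"}))
            site_tables[var] = tbl
        results["site_tables"] = site_tables
        for var, tbl in site_tables.items():
            _write(tbl, out, f"site_metrics_{var.lower()}.csv", log)
        corr = correlation_matrix(site_tables["GDD"],
                                  ["SR", "FDis", "MPD", "CWPoL", "mT", "sdT",
                                   "logScom", "logSpop", "logPhi"])
        results["correlations"] = corr
        _write(correlations_to_frame(corr), out, "correlations.csv", log)

    if last >= STAGES.index("sem"):
        spec_text = (Path(config.dag_spec).read_text() if config.dag_spec
                     else DEFAULT_MODEL_SPEC)
        dag = parse_dag(spec_text)
        fits, coef_rows, dsep_rows, eff_rows, gof = [], [], [], [], {}
        for var in ("GDD", "FDD"):
            fitted = fit_sem(dag, results["site_tables"][var], name=var)
            fits.append(fitted)
            gof[var] = asdict(fitted.gof)
            for v, sub in fitted.submodels.items():
                for p, raw in sub.coef.items():
                    i = sub.fit.predictors.index(p)
                    coef_rows.append({"model": var, "submodel": v, "term": p,
                                      "raw": raw, "standardized": sub.std_coef[p],
                                      "se": sub.fit.se[i], "p": sub.fit.p_values[i]})
            for c in fitted.claims:
                dsep_rows.append({"model": var, "response": c.response,
                                  "other": c.other,
                                  "conditioning": "+".join(c.conditioning_set),
                                  "coefficient": c.coefficient, "p": c.p_value})
            for source in dag.vertices:
                if source == "logScom":
                    continue
                eff = indirect_effects(fitted, source, "logScom")
                eff_rows.append({"model": var, "source": source, "target": "logScom",
                                 "direct": eff.direct,
                                 "total_indirect": eff.total_indirect,
                                 "total": eff.total, "n_paths": len(eff.paths)})
        results["fits"] = fits
        results["comparison"] = compare_models(fits)
        _write(pd.DataFrame(coef_rows), out, "sem_coefficients.csv", log)
        _write(pd.DataFrame(dsep_rows), out, "dsep_tests.csv", log)
        _write(pd.DataFrame(eff_rows), out, "indirect_effects.csv", log)
        _write(results["comparison"], out, "comparison.csv", log)
        (out / "gof.json").write_text(json.dumps(gof, indent=2))

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    results["log"] = log
    return results


# ---------------------------------------------------------------------------
# example datasets
# ---------------------------------------------------------------------------

#: Ready-made synthetic presets; the larger ones mirror the scale of the
#: long-term Finnish monitoring schemes (sites x species pool x years with
#: their typical sampling frequency), the small one is for quick runs.
PRESETS: dict[str, dict] = {
    "small": dict(n_sites=10, n_species_pool=15, n_years=20, sampling_prob=1.0,
                  richness_gradient=(12.0, 6.0)),
    "bird-like": dict(n_sites=40, n_species_pool=159, n_years=20, sampling_prob=1.0,
                      richness_gradient=(60.0, 25.0)),
    "moth-like": dict(n_sites=52, n_species_pool=480, n_years=20, sampling_prob=0.9,
                      richness_gradient=(120.0, 40.0)),
    "smallmammal-like": dict(n_sites=50, n_species_pool=20, n_years=20,
                             sampling_prob=0.95, richness_gradient=(10.0, 4.0)),
}


def generate_example_dataset(out_dir, preset: str = "small",
                             seed: int = 0) -> PipelineConfig:
    """Write a ready-to-run synthetic dataset and its pipeline config.

    Produces abundance, traits (+ YAML schema), a Newick tree, daily
    climate, the default model-DSL file and ``config.yaml`` under
    `out_dir`.  The same seed reproduces identical files.
    """
    if preset not in PRESETS:
        raise InvalidArgumentError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    p = PRESETS[preset]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=seed, **p)
    abundance = simulate_abundances(cfg)
    phylo = simulate_phylogeny(cfg.n_species_pool, seed=seed + 1)
    traits = simulate_traits(phylo, n_numeric=3, n_nominal=2, pol_weight=0.7,
                             seed=seed + 2)
    daily = simulate_daily_temperature(cfg.n_sites, cfg.n_years,
                                       gradient_per_site=0.25, seed=seed + 3,
                                       start_year=cfg.start_year)

    abundance.to_csv(out / "abundance.csv", index=False)
    traits.data.to_csv(out / "traits.csv")
    traits.schema_to_yaml(out / "trait_schema.yaml")
    (out / "tree.nwk").write_text(phylo.to_newick())
    daily.to_csv(out / "climate_daily.csv", index=False)
    (out / "model_spec.txt").write_text(DEFAULT_MODEL_SPEC)

    pc = PipelineConfig(
        abundance=str(out / "abundance.csv"), traits=str(out / "traits.csv"),
        trait_schema=str(out / "trait_schema.yaml"), trees=str(out / "tree.nwk"),
        climate=str(out / "climate_daily.csv"), dag_spec=str(out / "model_spec.txt"),
        out_dir=str(out / "results"), seed=seed)
    pc.to_yaml(out / "config.yaml")
    return pc
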