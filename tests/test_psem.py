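import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divstab.errors import (CollinearityError, CycleError, InvalidArgumentError,
                            ModelSpecError, UndefinedStatisticError)
from divstab.linmod import OlsFit
from divstab.psem import (DEFAULT_MODEL_SPEC, DagModel, FittedSem, GofStats,
                          Submodel, basis_set, chisq_vs_saturated,
                          compare_models, correlated_errors, dsep_tests,
                          fishers_c, fit_sem, fit_submodels, indirect_effects,
                          model_aicc, parse_dag, suggest_modifications)
from divstab.synthetic import PlantedSemConfig, simulate_sem_dataset


# ---------------------------------------------------------------------------
# model DSL
# ---------------------------------------------------------------------------

class TestParseDag:
    def test_simple_chain(self):
        dag = parse_dag("Y ~ X\nZ ~ Y")
        assert len(dag.vertices) == 3
        assert len(dag.edges) == 2
        assert not dag.correlated

    def test_cycle_named(self):
        with pytest.raises(CycleError, match="X.*Y|Y.*X"):
            parse_dag("Y ~ X\nX ~ Y")

    def test_default_spec_shape(self):
        dag = parse_dag(DEFAULT_MODEL_SPEC)
        assert len(dag.vertices) == 9
        assert nx.is_directed_acyclic_graph(dag.graph)
        assert len(dag.correlated) == 3
        assert dag.exogenous == {"SR", "mT", "sdT"}

    def test_correlation_between_adjacent_rejected(self):
        with pytest.raises(ModelSpecError):
            parse_dag("Y ~ X\nX ~~ Y")

    def test_self_correlation_rejected(self):
        with pytest.raises(ModelSpecError):
            parse_dag("Y ~ X\nZ ~ X\nZ ~~ Z")

    def test_bad_line_rejected(self):
        with pytest.raises(ModelSpecError):
            parse_dag("Y = X")


# ---------------------------------------------------------------------------
# basis set
# ---------------------------------------------------------------------------

def brute_force_basis(dag):
    """Independent enumeration over all vertex pairs by the stated rules."""
    order = {v: i for i, v in enumerate(dag.topological_order())}
    exo = dag.exogenous
    out = set()
    for a, b in itertools.combinations(sorted(dag.graph.nodes), 2):
        adjacent = dag.graph.has_edge(a, b) or dag.graph.has_edge(b, a)
        if adjacent or frozenset((a, b)) in dag.correlated:
            continue
        if a in exo and b in exo:
            continue
        cond = frozenset((dag.parents(a) | dag.parents(b)) - {a, b})
        out.add((frozenset((a, b)), cond))
    return out


def random_dag(rng, n_vertices):
    names = [f"v{i}" for i in range(n_vertices)]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for i, j in itertools.combinations(range(n_vertices), 2):
        if rng.random() < 0.3:
            g.add_edge(names[i], names[j])
    dag = DagModel(graph=g)
    nonadj = [(a, b) for a, b in itertools.combinations(names, 2)
              if not dag.adjacent(a, b)]
    corr = set()
    for a, b in nonadj:
        if rng.random() < 0.1:
            corr.add(frozenset((a, b)))
    return DagModel(graph=g, correlated=frozenset(corr))


class TestBasisSet:
    def test_chain_textbook_claim(self):
        claims = basis_set(parse_dag("Y ~ X\nZ ~ Y"))
        assert len(claims) == 1
        c = claims[0]
        assert {c.response, c.other} == {"X", "Z"}
        assert c.conditioning_set == ("Y",)

    def test_fork_single_claim(self):
        claims = basis_set(parse_dag("Y ~ X\nZ ~ X"))
        assert len(claims) == 1
        assert claims[0].conditioning_set == ("X",)
        assert {claims[0].response, claims[0].other} == {"Y", "Z"}

    def test_default_spec_claim_count_matches_brute_force(self):
        dag = parse_dag(DEFAULT_MODEL_SPEC)
        claims = basis_set(dag)
        oracle = brute_force_basis(dag)
        assert len(claims) == len(oracle) == 9
        got = {(frozenset((c.response, c.other)), frozenset(c.conditioning_set))
               for c in claims}
        assert got == oracle

    def test_matches_brute_force_on_random_dags(self, rng):
        for _ in range(100):
            dag = random_dag(rng, int(rng.integers(3, 11)))
            got = {(frozenset((c.response, c.other)), frozenset(c.conditioning_set))
                   for c in basis_set(dag)}
            assert got == brute_force_basis(dag)

    def test_response_is_never_exogenous_when_avoidable(self, rng):
        for _ in range(50):
            dag = random_dag(rng, 8)
            for c in basis_set(dag):
                if c.response in dag.exogenous:
                    assert c.other in dag.exogenous  # never happens: such pairs skipped
                    raise AssertionError("exogenous response with endogenous partner")


# ---------------------------------------------------------------------------
# fitting and d-separation
# ---------------------------------------------------------------------------

class TestFitSubmodels:
    def test_noiseless_chain_exact(self):
        dag = parse_dag("Y ~ X")
        df = simulate_sem_dataset(PlantedSemConfig(
            dag=dag, coefficients={("X", "Y"): 0.5}, noise_sd={"Y": 0.0},
            n=30, seed=0))
        fitted = fit_submodels(dag, df)
        assert fitted.submodels["Y"].coef["X"] == pytest.approx(0.5, abs=1e-12)

    def test_standardized_slope_is_pearson_r_for_single_parent(self, rng):
        dag = parse_dag("Y ~ X")
        df = pd.DataFrame({"X": rng.normal(size=100)})
        df["Y"] = 0.4 * df.X + rng.normal(size=100)
        fitted = fit_submodels(dag, df)
        assert fitted.submodels["Y"].std_coef["X"] == pytest.approx(
            np.corrcoef(df.X, df.Y)[0, 1], rel=1e-10)

    def test_collinear_parents_named(self, rng):
        dag = parse_dag("Y ~ A + B")
        a = rng.normal(size=50)
        df = pd.DataFrame({"A": a, "B": 2 * a, "Y": rng.normal(size=50)})
        with pytest.raises(CollinearityError, match="B"):
            fit_submodels(dag, df)

    def test_missing_rows_dropped(self, rng):
        dag = parse_dag("Y ~ X")
        df = pd.DataFrame({"X": rng.normal(size=20), "Y": rng.normal(size=20)})
        df.loc[3, "Y"] = np.nan
        fitted = fit_submodels(dag, df)
        assert fitted.n == 19


class TestDsep:
    def test_p_matches_direct_regression_oracle(self, rng):
        import statsmodels.api as sm

        dag = parse_dag("Y ~ X\nZ ~ Y")
        df = simulate_sem_dataset(PlantedSemConfig(
            dag=dag, coefficients={("X", "Y"): 0.6, ("Y", "Z"): 0.5},
            n=150, seed=4))
        fitted = fit_submodels(dag, df)
        claim = dsep_tests(fitted)[0]  # Z _||_ X | {Y}
        design = sm.add_constant(df[["Y", "X"]])
        ref = sm.OLS(df["Z"], design).fit()
        assert claim.p_value == pytest.approx(ref.pvalues["X"], rel=1e-8)
        assert claim.coefficient == pytest.approx(ref.params["X"], rel=1e-8)

    def test_omitted_edge_detected_with_growing_n(self):
        # True system has X -> Z, the tested model omits it.
        true = parse_dag("Y ~ X\nZ ~ Y + X")
        model = parse_dag("Y ~ X\nZ ~ Y")
        ps = []
        for n in (50, 200, 800):
            df = simulate_sem_dataset(PlantedSemConfig(
                dag=true, coefficients={("X", "Y"): 0.5, ("Y", "Z"): 0.5,
                                        ("X", "Z"): 0.4}, n=n, seed=7))
            fitted = fit_submodels(model, df)
            ps.append(dsep_tests(fitted)[0].p_value)
        assert ps[-1] < 1e-6
        assert ps[-1] <= ps[0]

    def test_exact_identity_response_yields_p_one(self, rng):
        # logScom-style deterministic submodel: the extra predictor's
        # coefficient is exactly zero with zero residual -> p = 1.
        dag = parse_dag("S ~ A + B\nA ~ X\nB ~ X")
        x = rng.normal(size=60)
        a = 0.5 * x + rng.normal(size=60)
        b = -0.3 * x + rng.normal(size=60)
        df = pd.DataFrame({"X": x, "A": a, "B": b, "S": a + b})
        fitted = fit_submodels(dag, df)
        claims = {(c.response, c.other): c for c in dsep_tests(fitted)}
        assert claims[("S", "X")].p_value == pytest.approx(1.0)


class TestFishersC:
    def test_all_ones(self):
        assert fishers_c([1.0, 1.0, 1.0]) == (0.0, 6, 1.0)

    def test_empty_is_saturated_convention(self):
        assert fishers_c([]) == (0.0, 0, 1.0)

    def test_two_marginal_p_values(self):
        c, df, p = fishers_c([0.05, 0.05])
        assert c == pytest.approx(-4 * np.log(0.05), rel=1e-12)
        assert c == pytest.approx(11.983, abs=5e-4)
        assert df == 4
        assert p == pytest.approx(stats.chi2.sf(c, 4), rel=1e-12)

    @pytest.mark.parametrize("k", [5, 10, 20])
    def test_mean_case_sits_mid_distribution(self, k):
        c, df, p = fishers_c([np.exp(-1.0)] * k)
        assert c == pytest.approx(2 * k)
        assert 0.40 < p < 0.60

    def test_zero_p_clamped_finite(self):
        c, df, p = fishers_c([0.0, 0.5])
        assert np.isfinite(c) and p >= 0.0


class TestChisqAndAicc:
    def test_saturated_topology_gives_zero(self, rng):
        dag = parse_dag("Y ~ X")  # no non-adjacent pairs -> no constraints
        df = pd.DataFrame({"X": rng.normal(size=40)})
        df["Y"] = df.X + rng.normal(size=40)
        fitted = fit_submodels(dag, df)
        assert chisq_vs_saturated(fitted) == (0.0, 0, 1.0)

    def test_chisq_nonnegative_with_df_equal_claims(self, rng):
        dag = parse_dag(DEFAULT_MODEL_SPEC)
        from divstab.synthetic import default_sem_config
        for seed in range(10):
            df = simulate_sem_dataset(default_sem_config(n=120, seed=seed))
            fitted = fit_submodels(dag, df)
            chisq, df_, p = chisq_vs_saturated(fitted)
            assert chisq >= 0.0
            assert df_ == len(basis_set(dag))

    def test_aicc_decreasing_in_likelihood(self, rng):
        dag = parse_dag("Y ~ X")
        x = rng.normal(size=60)
        tight = pd.DataFrame({"X": x, "Y": 0.5 * x + 0.1 * rng.normal(size=60)})
        loose = pd.DataFrame({"X": x, "Y": 0.5 * x + 2.0 * rng.normal(size=60)})
        f_tight, f_loose = fit_submodels(dag, tight), fit_submodels(dag, loose)
        assert f_tight.loglik() > f_loose.loglik()
        assert model_aicc(f_tight) < model_aicc(f_loose)
        assert f_tight.k_params() == f_loose.k_params()

    def test_aicc_undefined_at_tiny_n(self, rng):
        dag = parse_dag("Y ~ A + B")
        df = pd.DataFrame({"A": rng.normal(size=5), "B": rng.normal(size=5),
                           "Y": rng.normal(size=5)})
        fitted = fit_submodels(dag, df)
        with pytest.raises(UndefinedStatisticError):
            model_aicc(fitted)


class TestCorrelatedErrors:
    def make_data(self, rng, shared_sd, n=500):
        x = rng.normal(size=n)
        shared = shared_sd * rng.normal(size=n)
        a = 0.5 * x + shared + rng.normal(size=n)
        b = -0.4 * x + shared + rng.normal(size=n)
        return pd.DataFrame({"X": x, "A": a, "B": b})

    def test_independent_residuals_near_zero(self, rng):
        dag = parse_dag("A ~ X\nB ~ X\nA ~~ B")
        df = self.make_data(rng, shared_sd=0.0)
        out = correlated_errors(fit_submodels(dag, df))
        assert len(out) == 1
        assert abs(out[0]["r"]) < 3 / np.sqrt(500)

    def test_shared_latent_detected(self, rng):
        dag = parse_dag("A ~ X\nB ~ X\nA ~~ B")
        df = self.make_data(rng, shared_sd=1.0)
        out = correlated_errors(fit_submodels(dag, df))
        assert out[0]["r"] > 0.2 and out[0]["p"] < 0.05

    def test_exogenous_member_uses_centered_values(self, rng):
        # Z is exogenous (parent of A only); the B ~~ Z term correlates B's
        # residuals with Z's centered raw values.
        dag = parse_dag("A ~ X + Z\nB ~ X\nB ~~ Z")
        df = self.make_data(rng, shared_sd=0.0)
        df["Z"] = rng.normal(size=len(df))
        out = correlated_errors(fit_submodels(dag, df))
        assert [(o["var_a"], o["var_b"]) for o in out] == [("B", "Z")]
        assert abs(out[0]["r"]) < 3 / np.sqrt(len(df))


# ---------------------------------------------------------------------------
# effects, suggestions, comparison
# ---------------------------------------------------------------------------

def manual_fit(dag_text, std_coefs, n=100):
    """A FittedSem with hand-set standardized coefficients."""
    dag = parse_dag(dag_text)
    submodels = {}
    for v in dag.endogenous:
        parents = sorted(dag.parents(v))
        fit = OlsFit(response=v, predictors=parents,
                     coef=np.zeros(len(parents)), intercept=0.0,
                     se=np.zeros(len(parents)), t_values=np.zeros(len(parents)),
                     p_values=np.ones(len(parents)), residuals=np.zeros(n),
                     sigma2_ml=1.0, loglik=0.0, r_squared=0.0, n=n,
                     n_params=len(parents) + 2)
        submodels[v] = Submodel(fit=fit, std_coef={p: std_coefs[(p, v)]
                                                   for p in parents})
    return FittedSem(dag=dag, data=pd.DataFrame(index=range(n)),
                     submodels=submodels)


class TestIndirectEffects:
    def test_chain_product(self):
        fitted = manual_fit("M ~ X\nY ~ M",
                            {("X", "M"): 0.5, ("M", "Y"): 0.4})
        eff = indirect_effects(fitted, "X", "Y")
        assert eff.total_indirect == pytest.approx(0.2)
        assert eff.direct == 0.0
        assert len(eff.paths) == 1

    def test_parallel_paths_sum(self):
        fitted = manual_fit(
            "M1 ~ X\nM2 ~ X\nY ~ M1 + M2",
            {("X", "M1"): 0.5, ("X", "M2"): 0.6,
             ("M1", "Y"): 0.4, ("M2", "Y"): 0.5})
        eff = indirect_effects(fitted, "X", "Y")
        assert eff.total_indirect == pytest.approx(0.5 * 0.4 + 0.6 * 0.5)

    def test_direct_edge_reported_separately(self):
        fitted = manual_fit("M ~ X\nY ~ M + X",
                            {("X", "M"): 0.5, ("M", "Y"): 0.4, ("X", "Y"): -0.3})
        eff = indirect_effects(fitted, "X", "Y")
        assert eff.direct == pytest.approx(-0.3)
        assert eff.total_indirect == pytest.approx(0.2)
        assert eff.total == pytest.approx(-0.1)

    def test_no_path_is_empty_zero(self):
        fitted = manual_fit("M ~ X\nY ~ M", {("X", "M"): 0.5, ("M", "Y"): 0.4})
        eff = indirect_effects(fitted, "Y", "X")
        assert eff.paths == () and eff.total == 0.0


class TestSuggestions:
    def test_quiet_claims_give_no_suggestions(self):
        from divstab.psem import IndependenceClaim
        claims = [IndependenceClaim("A", "B", (), p_value=0.5, coefficient=0.1)]
        assert suggest_modifications(claims) == []

    def test_planted_missing_edge_ranked_first(self):
        true = parse_dag("Y ~ X\nZ ~ Y + X")
        model = parse_dag("Y ~ X\nZ ~ Y")
        hits = 0
        for seed in range(40):
            df = simulate_sem_dataset(PlantedSemConfig(
                dag=true, coefficients={("X", "Y"): 0.5, ("Y", "Z"): 0.5,
                                        ("X", "Z"): 0.4}, n=500, seed=seed))
            fitted = fit_submodels(model, df)
            sugg = suggest_modifications(dsep_tests(fitted))
            if sugg and {sugg[0]["response"], sugg[0]["other"]} == {"X", "Z"}:
                hits += 1
        assert hits / 40 >= 0.95

    def test_suggestions_subset_of_basis_pairs(self, rng):
        dag = parse_dag(DEFAULT_MODEL_SPEC)
        from divstab.synthetic import default_sem_config
        df = simulate_sem_dataset(default_sem_config(n=100, seed=5))
        fitted = fit_submodels(dag, df)
        claims = dsep_tests(fitted)
        pairs = {frozenset((c.response, c.other)) for c in claims}
        for s in suggest_modifications(claims, alpha=0.5):
            assert frozenset((s["response"], s["other"])) in pairs


class TestCompareModels:
    def test_single_model_delta_zero(self):
        fitted = manual_fit("Y ~ X", {("X", "Y"): 0.5})
        fitted.gof = GofStats(1.0, 2, 0.6, 0.5, 1, 0.5, 100.0, 3)
        table = compare_models([fitted])
        assert table["delta_aicc"].iloc[0] == 0.0

    def test_ordering_and_support_rule(self):
        a = manual_fit("Y ~ X", {("X", "Y"): 0.5})
        a.name = "good"
        a.gof = GofStats(1.0, 2, 0.6, 0.5, 1, 0.5, 100.0, 3)
        b = manual_fit("Y ~ X", {("X", "Y"): 0.5})
        b.name = "fisher_fails"
        b.gof = GofStats(9.0, 2, 0.04, 0.5, 1, 0.2, 103.0, 3)
        table = compare_models([b, a])
        assert list(table["model"]) == ["good", "fisher_fails"]
        assert table["delta_aicc"].iloc[1] == pytest.approx(3.0)
        assert bool(table["supported"].iloc[0]) is True
        # one p-value below 0.05 is enough to lose support
        assert bool(table["supported"].iloc[1]) is False
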