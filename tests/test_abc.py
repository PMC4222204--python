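import warnings

import numpy as np
import pandas as pd
import pytest

from microsatpop import abc as A
from microsatpop.abc import (
    PARAM_COLUMNS,
    STAT_NAMES,
    ParameterDraw,
    PriorSpec,
    ReferenceTable,
    SampleConfig,
    ScenarioSpec,
    build_reference_table,
    confidence_evaluation,
    direct_posterior,
    logistic_posterior,
    posterior_parameters,
    sample_prior,
    simulate_dataset,
    summary_stats,
)
from microsatpop.genotypes import GenotypeDataset


class TestPriors:
    def test_t1_moments_and_supports(self):
        rng = np.random.default_rng(0)
        priors = PriorSpec()
        draws = [sample_prior(priors, rng) for _ in range(20_000)]
        t1 = np.array([d.t1_years for d in draws])
        assert abs(t1.mean() - 25_000) / 25_000 < 0.01
        assert abs(t1.std() - 5_000) / 5_000 < 0.05
        nb = np.array([d.Nb1 for d in draws] + [d.Nb2 for d in draws])
        assert nb.min() >= 10 and nb.max() <= 100
        assert all(d.t1_years > d.db_years for d in draws)

    def test_db_maps_to_one_to_three_generations(self):
        rng = np.random.default_rng(1)
        gens = {sample_prior(PriorSpec(), rng).db_gen for _ in range(3000)}
        assert gens == {1, 2, 3}

    def test_t1_generations_exceed_bottleneck(self):
        d = ParameterDraw(N1=1e4, N2=1e4, N_anc=1e4, Nb1=50, Nb2=50,
                          t1_years=300, db_years=290, mu=1e-4, gsm_p=0.2, sni=0.0)
        assert d.t1_gen > d.db_gen


class TestScenarios:
    def test_exactly_three_unique(self):
        specs = ScenarioSpec.all()
        assert [s.id for s in specs] == [1, 2, 3]
        assert {s.ancestral for s in specs} == {"pop1", "pop2", "unsampled"}
        with pytest.raises(ValueError):
            ScenarioSpec(4, "pop1")


def _draw(**kw):
    base = dict(N1=20_000, N2=20_000, N_anc=20_000, Nb1=50, Nb2=50,
                t1_years=25_000, db_years=500, mu=3e-4, gsm_p=0.2, sni=1e-7)
    base.update(kw)
    return ParameterDraw(**base)


class TestSimulation:
    def test_zero_mutation_gives_monomorphic(self):
        ds = simulate_dataset(ScenarioSpec.by_id(1), _draw(mu=0.0, sni=0.0),
                              SampleConfig(10, 10, 5), seed=3)
        for l in range(ds.n_loci):
            assert np.unique(ds.calls[:, l, :]).size == 1

    def test_deterministic_given_seed(self):
        cfg = SampleConfig(8, 8, 4)
        a = simulate_dataset(ScenarioSpec.by_id(2), _draw(), cfg, seed=7)
        b = simulate_dataset(ScenarioSpec.by_id(2), _draw(), cfg, seed=7)
        assert a.equals(b)

    def test_single_deme_smm_variance_matches_theory(self):
        """Strict stepwise model in one deme: E[sample allele-size variance]
        = theta / 2 with theta = 4 N mu."""
        from microsatpop import _coalescent

        N, mu = 2_500.0, 1e-4  # theta = 1
        seeds = np.arange(1, 2_501, dtype=np.int64)
        variances = []
        for s in seeds:
            alleles = _coalescent.divergence_locus(
                int(s), 30, 0, 0, N, N, N, N, N, 0.0, 0.0, mu, 0.0, 0.0)
            variances.append(np.var(alleles / 2.0, ddof=1))
        assert np.mean(variances) == pytest.approx(0.5, rel=0.15)

    def test_deep_divergence_differentiates(self):
        # low theta keeps homoplasy on the bounded ladder from masking the
        # split; differentiation then approaches its ceiling at deep t1
        cfg = SampleConfig(20, 20, 8)
        low_div = dict(N1=500.0, N2=500.0, N_anc=500.0, mu=1e-4, sni=0.0)
        shallow = simulate_dataset(
            ScenarioSpec.by_id(3), _draw(t1_years=500, db_years=260, **low_div),
            cfg, seed=5)
        deep = simulate_dataset(
            ScenarioSpec.by_id(3), _draw(t1_years=5e6, **low_div), cfg, seed=5)
        fst_idx = STAT_NAMES.index("fst")
        assert summary_stats(deep)[fst_idx] > 0.3
        assert summary_stats(shallow)[fst_idx] < 0.1


class TestSummaryStats:
    def test_schema(self):
        ds = simulate_dataset(ScenarioSpec.by_id(1), _draw(), SampleConfig(6, 6, 3), 1)
        vec = summary_stats(ds)
        assert vec.shape == (len(STAT_NAMES),)

    def test_hand_computed_fixture(self):
        # pop1: (100,100), (100,102); pop2: (102,102), (102,104)
        calls = np.array([
            [[100, 100]], [[100, 102]], [[102, 102]], [[102, 104]]], dtype=np.int32)
        ds = GenotypeDataset(["a", "b", "c", "d"], ["p1", "p1", "p2", "p2"],
                             ["l"], calls)
        vec = dict(zip(STAT_NAMES, summary_stats(ds)))
        assert vec["A_pop1"] == 2 and vec["A_pop2"] == 2
        # unbiased He: (4/3) * (1 - (3/4)^2 - (1/4)^2) = 0.5
        assert vec["He_pop1"] == pytest.approx(0.5)
        assert vec["He_pop2"] == pytest.approx(0.5)
        # sizes in ladder-step units (step 2): pop1 {50,50,50,51}
        assert vec["size_var_pop1"] == pytest.approx(np.var([50, 50, 50, 51], ddof=1))
        assert vec["gw_m_pop1"] == pytest.approx(2 / (1 + 1))
        # shared-allele distance: sum min(p1, p2) over {100: .75/0, 102: .25/.75, 104: 0/.25}
        assert vec["shared_allele_dist"] == pytest.approx(1 - 0.25)
        assert vec["delta_mu_sq"] == pytest.approx((50.25 - 51.25) ** 2)

    def test_duplicated_population_near_zero_fst(self):
        rng = np.random.default_rng(2)
        half = rng.choice([100, 102, 104, 106], size=(25, 6, 2)).astype(np.int32)
        calls = np.concatenate([half, half])
        ds = GenotypeDataset([f"i{j}" for j in range(50)],
                             ["p1"] * 25 + ["p2"] * 25,
                             [f"l{j}" for j in range(6)], calls)
        vec = dict(zip(STAT_NAMES, summary_stats(ds)))
        assert abs(vec["fst"]) < 0.02
        assert vec["delta_mu_sq"] == pytest.approx(0.0)


def _toy_table(n=300, seed=0, separated=False):
    """Reference table with synthetic statistics (no simulation)."""
    rng = np.random.default_rng(seed)
    scen = np.repeat([1, 2, 3], n)
    stats = rng.normal(size=(3 * n, len(STAT_NAMES)))
    if separated:
        stats[:, 0] += scen * 10.0  # one statistic separates scenarios sharply
    params = pd.DataFrame({"scenario": scen})
    for c in PARAM_COLUMNS:
        params[c] = rng.uniform(10, 100, size=3 * n)
    return ReferenceTable(params=params, stats=stats, stat_names=list(STAT_NAMES),
                          settings={"scenario_ids": [1, 2, 3]})


class TestPosteriors:
    def test_direct_zero_distance_single_neighbour(self):
        table = _toy_table()
        obs = table.stats[5].copy()
        probs = direct_posterior(obs, table, n_closest=1)
        assert probs.loc[1] == 1.0
        assert probs.sum() == pytest.approx(1.0)

    def test_direct_single_scenario_table(self):
        table = _toy_table()
        mask = table.scenarios == 2
        sub = ReferenceTable(table.params[mask].reset_index(drop=True),
                             table.stats[mask], table.stat_names,
                             {"scenario_ids": [2]})
        probs = direct_posterior(np.zeros(len(STAT_NAMES)), sub, n_closest=10)
        assert probs.loc[2] == 1.0

    def test_logistic_null_neighbourhood_uniform(self):
        table = _toy_table(seed=3)
        probs = logistic_posterior(np.zeros(len(STAT_NAMES)), table, n_closest=600)
        assert probs.sum() == pytest.approx(1.0)
        assert (probs > 0.2).all() and (probs < 0.5).all()

    def test_logistic_sharper_than_direct_when_separable(self):
        table = _toy_table(seed=4, separated=True)
        obs = np.zeros(len(STAT_NAMES))
        obs[0] = 2 * 10.0  # nearest scenario-2 territory
        direct = direct_posterior(obs, table, n_closest=450)
        logistic = logistic_posterior(obs, table, n_closest=450)
        assert logistic.idxmax() == 2
        assert logistic.max() >= direct.max() - 1e-9

    def test_logistic_single_scenario_falls_back(self):
        table = _toy_table(seed=5, separated=True)
        obs = np.zeros(len(STAT_NAMES))
        obs[0] = 1000.0  # far beyond scenario 3's territory: one-class hood
        with pytest.warns(UserWarning, match="single-scenario"):
            probs = logistic_posterior(obs, table, n_closest=5)
        assert probs.sum() == pytest.approx(1.0)

    def test_exchangeable_under_record_permutation(self):
        table = _toy_table(seed=6)
        rng = np.random.default_rng(0)
        order = rng.permutation(table.n_records)
        shuffled = ReferenceTable(table.params.iloc[order].reset_index(drop=True),
                                  table.stats[order], table.stat_names,
                                  table.settings)
        obs = np.full(len(STAT_NAMES), 0.3)
        assert direct_posterior(obs, table, 50).equals(
            direct_posterior(obs, shuffled, 50))
        a = logistic_posterior(obs, table, 300)
        b = logistic_posterior(obs, shuffled, 300)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-6)


class TestPosteriorParameters:
    def test_full_table_uniform_kernel_recovers_prior(self):
        table = _toy_table(seed=7)
        mask = table.scenarios == 1
        n = int(mask.sum())
        obs = np.zeros(len(STAT_NAMES))
        pq = posterior_parameters(obs, table, scenario=1, n_closest=n,
                                  kernel="uniform")
        prior_vals = table.params.loc[mask, "t1_years"].to_numpy()
        expected = np.quantile(prior_vals, [0.05, 0.5, 0.95])
        got = pq.loc["t1_years", ["q5", "q50", "q95"]].to_numpy(dtype=float)
        assert np.allclose(got, expected, rtol=0.05)

    def test_quantiles_ordered(self):
        table = _toy_table(seed=8)
        pq = posterior_parameters(np.zeros(len(STAT_NAMES)), table, 2, n_closest=100)
        assert (pq["q5"] <= pq["q50"]).all()
        assert (pq["q50"] <= pq["q95"]).all()

    def test_loclinear_adjustment_runs(self):
        table = _toy_table(seed=9)
        pq = posterior_parameters(np.zeros(len(STAT_NAMES)), table, 3,
                                  n_closest=150, adjust="loclinear")
        assert (pq["q5"] <= pq["q95"]).all()


class TestReferenceTable:
    def test_minimal_build_schema(self):
        table = build_reference_table(1, seed=0, config=SampleConfig(4, 4, 2))
        assert table.n_records == 3
        assert sorted(table.params["scenario"]) == [1, 2, 3]
        assert table.stats.shape == (3, len(STAT_NAMES))

    def test_build_deterministic(self):
        cfg = SampleConfig(5, 5, 3)
        a = build_reference_table(4, seed=42, config=cfg)
        b = build_reference_table(4, seed=42, config=cfg)
        assert a.params.equals(b.params)
        assert np.array_equal(a.stats, b.stats)

    def test_roundtrip_persistence(self, tmp_path):
        table = build_reference_table(2, seed=1, config=SampleConfig(4, 4, 2))
        path = tmp_path / "table.tsv"
        table.write(path)
        back = ReferenceTable.read(path)
        assert np.allclose(back.stats, table.stats)
        assert back.params["scenario"].tolist() == table.params["scenario"].tolist()


def test_confidence_evaluation_separable_toy(monkeypatch):
    """With a perfectly separating statistic the confidence approaches 1."""
    table = _toy_table(n=200, seed=10, separated=True)

    calls = {"i": 0}

    def fake_stats(ds):
        # place each POD exactly in its scenario's territory
        scen = 1 + (calls["i"] // 5) % 3
        calls["i"] += 1
        v = np.zeros(len(STAT_NAMES))
        v[0] = scen * 10.0
        return v

    def fake_simulate(scenario, draw, config, seed):
        calls["i"] = (scenario.id - 1) * 5
        from conftest import make_dataset
        return make_dataset({"pop1": 3, "pop2": 3}, 2, seed=1)

    monkeypatch.setattr(A, "summary_stats", fake_stats)
    monkeypatch.setattr(A, "simulate_dataset", fake_simulate)
    out = confidence_evaluation(table, n_pods=5, seed=0, method="direct",
                                n_closest=50)
    assert out["accuracy"] > 0.9
    for i in (1, 2, 3):
        assert out["type_1"][i] < 0.2
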