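import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from parvapop.diversity import harmonic_number
from parvapop.errors import ParameterError, ScenarioError
from parvapop.popio import table_from_records
from parvapop.scenarios import (
    ReferenceTable,
    abc_model_choice,
    abc_parameter_estimate,
    build_reference_table,
    default_scenarios,
    extended_stat_names,
    scenario_1,
    scenario_2,
    scenario_3,
    simulate_scenario,
    summary_stat_names,
    summary_stats,
    summary_stats_extended,
)

SIZES = {"pop1": 15, "pop2": 15, "pop3": 15, "pop4": 15}


def single_deme_spec(theta_locus, L=700, N=1000.0):
    """One constant-size deme: the scenario machine must reduce to the plain
    Kingman simulator (theta = 2 N mu L)."""
    from parvapop.scenarios import PriorSet, ScenarioSpec

    mu = theta_locus / (2 * N * L)
    return (
        ScenarioSpec(
            name="single",
            demes={"pop1": "N1"},
            sampled=("pop1",),
            events=(),
            root_deme="pop1",
            priors=PriorSet({"N1": ("uniform", N, N + 1e-9), "mu": ("uniform", mu, mu * (1 + 1e-12))}),
        ),
        {"N1": N, "mu": mu},
    )


class TestSimulateScenario:
    def test_single_deme_reduces_to_equilibrium(self, rng):
        # E[pi per site] = theta/L over replicates
        theta = 4.0
        spec, params = single_deme_spec(theta)
        pis = np.empty(3000)
        for r in range(3000):
            hap = simulate_scenario(spec, params, {"pop1": 2}, L=700, rng=rng)
            reps = hap.representatives
            counts = hap.counts.to_numpy().ravel()
            seqs = [r_ for r_, c in zip(reps, counts) for _ in range(c)]
            pis[r] = sum(a != b for a, b in zip(seqs[0], seqs[1])) / 700
        se = pis.std(ddof=1) / np.sqrt(len(pis))
        assert abs(pis.mean() - theta / 700) <= 3 * se

    def test_zero_admixture_matches_single_source(self, rng):
        # r = 1 sends every lineage to the major source: summary-statistic
        # distributions indistinguishable from an explicit split (KS test)
        from parvapop.scenarios import AdmixtureEvent, PriorSet, ScenarioSpec, SplitEvent

        priors = PriorSet({"N1": ("uniform", 500.0, 500.1), "t1": ("uniform", 50.0, 50.1),
                           "mu": ("uniform", 1e-8, 1.0001e-8)})
        params = {"N1": 500.0, "t1": 50.0, "mu": 1e-8}
        base = dict(demes={"pop1": "N1", "pop3": "N1", "GH": "N1"}, sampled=("pop1", "pop3"),
                    root_deme="pop1", priors=priors)
        adm = ScenarioSpec(name="a", events=(
            AdmixtureEvent("t1", "pop3", "pop1", "GH", "r"),), **base)
        spl = ScenarioSpec(name="s", events=(SplitEvent("t1", "pop3", "pop1"),), **base)
        params_adm = dict(params, r=1.0)
        stat = lambda hap: summary_stats(hap)[6]  # pi of pop3
        xs = [stat(simulate_scenario(adm, params_adm, {"pop1": 8, "pop3": 8}, rng=rng)) for _ in range(400)]
        ys = [stat(simulate_scenario(spl, params, {"pop1": 8, "pop3": 8}, rng=rng)) for _ in range(400)]
        assert ss.ks_2samp(xs, ys).pvalue > 0.01

    def test_founder_bottleneck_lowers_haplotype_diversity(self, rng):
        spec = scenario_1()
        p = spec.priors.midpoint()
        harsh = dict(p, NF=10.0, DB=20.0, t1=30.0)
        mild = dict(p, NF=1e9, DB=1e-9, t1=30.0)
        lower = 0
        n = 300
        for r in range(n):
            h_h = summary_stats(simulate_scenario(spec, harsh, SIZES, rng=rng))[9]  # H pop3
            h_m = summary_stats(simulate_scenario(spec, mild, SIZES, rng=rng))[9]
            lower += h_h < h_m
        assert lower / n >= 0.80

    def test_lineage_conservation_single_root(self, rng):
        for spec in default_scenarios():
            hap = simulate_scenario(spec, spec.priors.midpoint(), SIZES, rng=rng)
            assert int(hap.counts.to_numpy().sum()) == sum(SIZES.values())

    def test_contradictory_founder_rejected(self):
        spec = scenario_1()
        p = spec.priors.midpoint()
        p["DB"] = p["t1"] + 1
        with pytest.raises(ScenarioError):
            simulate_scenario(spec, p, SIZES, rng=np.random.default_rng(0))

    def test_scenario3_ordering_constraint(self):
        spec = scenario_3()
        p = spec.priors.midpoint()
        p["ta"] = p["t2"] / 2  # violates "GH2 admixture pre-dates GH1 admixture"
        with pytest.raises(ScenarioError):
            simulate_scenario(spec, p, SIZES, rng=np.random.default_rng(0))


class TestSummaryStats:
    def test_monomorphic_dataset_zero_diversity(self):
        t = table_from_records([f"s{i}" for i in range(8)], ["AAAA"] * 8,
                               ["p1"] * 4 + ["p2"] * 4)
        s = summary_stats(t)
        names = summary_stat_names(["p1", "p2"])
        d = dict(zip(names, s))
        assert d["H_p1"] == 0 and d["pi_p2"] == 0 and d["S_p1"] == 0
        assert d["FST_p1_p2"] == 0 and d["DXY_p1_p2"] == 0

    def test_vector_length_contract(self):
        for P in (2, 3, 4):
            pops = [f"p{i}" for i in range(P)]
            assert len(summary_stat_names(pops)) == 4 * P + 2 * P * (P - 1) // 2

    def test_agrees_with_diversity_module(self, two_pop_table):
        from parvapop.diversity import haplotype_diversity, pairwise_matrices

        s = dict(zip(summary_stat_names(["A", "B"]), summary_stats(two_pop_table)))
        m = pairwise_matrices(two_pop_table)
        assert s["FST_A_B"] == pytest.approx(float(m.fst.loc["A", "B"]))
        assert s["DXY_A_B"] == pytest.approx(float(m.dxy.loc["A", "B"]))
        assert s["H_A"] == pytest.approx(haplotype_diversity([3, 1]))

    def test_extended_stats_sharing_values(self, two_pop_table):
        s = dict(zip(extended_stat_names(["A", "B"]), summary_stats_extended(two_pop_table)))
        # both haplotypes present in both pops: nothing private, 2 shared
        assert s["private_A"] == 0 and s["private_B"] == 0
        assert s["shared_count_A_B"] == 2
        # min(3/4, 1/4) + min(1/4, 3/4) = 1/2
        assert s["shared_mass_A_B"] == pytest.approx(0.5)


@pytest.fixture(scope="module")
def small_refs():
    return [
        build_reference_table(spec, SIZES, 600, seed=50 + i)
        for i, spec in enumerate(default_scenarios())
    ]


class TestModelChoice:

    def test_direct_rows_sum_to_one(self, small_refs, rng):
        spec = default_scenarios()[0]
        obs = summary_stats_extended(simulate_scenario(spec, spec.priors.midpoint(), SIZES, rng=rng))
        res = abc_model_choice(obs, small_refs, seed=1, n_boot=5)
        sums = res.direct[[r.scenario for r in small_refs]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_logistic_probabilities_normalised(self, small_refs, rng):
        spec = default_scenarios()[2]
        obs = summary_stats_extended(simulate_scenario(spec, spec.priors.midpoint(), SIZES, rng=rng))
        res = abc_model_choice(obs, small_refs, seed=2, n_boot=5)
        assert res.logistic["prob"].sum() == pytest.approx(1.0, abs=1e-6)
        assert ((0 <= res.logistic["lo"]) & (res.logistic["lo"] <= res.logistic["hi"])
                & (res.logistic["hi"] <= 1)).all()

    def test_prior_predictive_centre_near_uniform(self, small_refs):
        # observation at the pooled reference median: no scenario favoured
        pooled = np.vstack([r.stats for r in small_refs])
        obs = np.nanmedian(pooled, axis=0)
        res = abc_model_choice(obs, small_refs, seed=3, n_boot=20)
        lo = res.logistic["lo"].to_numpy()
        hi = res.logistic["hi"].to_numpy()
        assert ((lo <= 1 / 3) & (1 / 3 <= hi)).sum() >= 2

    def test_duplicated_statistic_invariance(self, small_refs, rng):
        spec = default_scenarios()[0]
        obs = summary_stats_extended(simulate_scenario(spec, spec.priors.midpoint(), SIZES, rng=rng))
        refs_dup = [
            ReferenceTable(r.scenario, r.params, np.hstack([r.stats, r.stats[:, :1]]))
            for r in small_refs
        ]
        res1 = abc_model_choice(obs, small_refs, seed=4, n_boot=5)
        res2 = abc_model_choice(np.append(obs, obs[0]), refs_dup, seed=4, n_boot=5)
        # duplicating one statistic perturbs distances only marginally: the
        # ranking of scenarios is preserved
        assert res1.best_direct == res2.best_direct


class TestParameterEstimate:
    def test_no_signal_adjustment_is_null(self, rng):
        theta = rng.uniform(0, 1, 4000)
        stats = rng.normal(size=(4000, 3))
        ref = ReferenceTable("x", pd.DataFrame({"p": theta}), stats)
        post = abc_parameter_estimate(ref, np.zeros(3), tolerance=0.05, min_accepted=200)
        # posterior ~ prior: wide and centred
        assert 0.35 < post.loc["p", "median"] < 0.65
        assert post.loc["p", "q975"] - post.loc["p", "q025"] > 0.7

    def test_deterministic_relation_collapses_posterior(self, rng):
        theta = rng.uniform(0, 1, 4000)
        stats = np.column_stack([theta + 0.01 * rng.normal(size=4000), rng.normal(size=4000)])
        ref = ReferenceTable("x", pd.DataFrame({"p": theta}), stats)
        post = abc_parameter_estimate(ref, np.array([0.5, 0.0]), tolerance=0.05, min_accepted=200)
        prior_sd = 1 / np.sqrt(12)
        post_sd = (post.loc["p", "q975"] - post.loc["p", "q025"]) / 4
        assert post_sd < prior_sd / 5
        assert abs(post.loc["p", "median"] - 0.5) < 0.05

    def test_insufficient_acceptances_rejected(self, rng):
        ref = ReferenceTable("x", pd.DataFrame({"p": rng.uniform(0, 1, 50)}),
                             rng.normal(size=(50, 2)))
        with pytest.raises(ParameterError):
            abc_parameter_estimate(ref, np.zeros(2), tolerance=0.01, min_accepted=200)
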