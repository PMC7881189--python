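"""Coalescent SNP simulation: ascertainment, neutral expectations, and
agreement between the msprime engine and the built-in lineage simulator."""

import numpy as np
import pytest
from scipy import stats

from bridgehead import (
    DemographicScenario,
    SimulationRequest,
    generate_reference_table,
    pairwise_fst,
    simulate_dataset,
)
from bridgehead.ladder import _step1
from bridgehead.popgen import folded_sfs, heterozygosity
from bridgehead.scenarios import Admixture, Bottleneck, Split


def _one_pop(ne=1000.0):
    return DemographicScenario("one", {"p": ne}, [], sampled=["p"])


def _split_scenario(t=500.0, ne=1000.0, nb=None, d=0.0, admix_r=None):
    pops = {"a": ne, "b": ne, "c": ne, "root": ne}
    events = []
    if admix_r is not None:
        events.append(Admixture(t, "c", "a", "b", admix_r))
    else:
        events.append(Split(t, "c", "a"))
    if nb is not None:
        events.append(Bottleneck(t, "c", nb, d))
    events += [Split(20_000.0, "a", "root"), Split(20_000.0, "b", "root")]
    return DemographicScenario("split", pops, events, sampled=["a", "b", "c"])


def _request(scenario, sizes, n_loci, seed, engine="msprime", G=5.0):
    return SimulationRequest(scenario, {}, sizes, n_loci, seed,
                             generation_time=G, engine=engine)


class TestSimulateDataset:
    @pytest.mark.parametrize("engine", ["msprime", "naive"])
    def test_every_locus_polymorphic_in_pooled_sample(self, engine):
        g = simulate_dataset(_request(_one_pop(), {"p": 5}, 100, 3, engine))
        alt = g.codes.sum(axis=0)
        assert g.n_loci == 100
        assert ((alt > 0) & (alt < 2 * g.n_individuals)).all()

    @pytest.mark.parametrize("engine", ["msprime", "naive"])
    def test_deterministic_per_seed(self, engine):
        req = _request(_split_scenario(), {"a": 3, "b": 3, "c": 3}, 30, 17, engine)
        assert np.array_equal(simulate_dataset(req).codes,
                              simulate_dataset(req).codes)

    def test_disconnected_scenario_rejected(self):
        s = DemographicScenario("bad", {"a": 100.0, "b": 100.0}, [],
                                sampled=["a", "b"])
        with pytest.raises(ValueError, match="root"):
            simulate_dataset(_request(s, {"a": 2, "b": 2}, 5, 1))

    def test_neutral_folded_sfs_shape(self):
        # single constant-size population, n = 6 haploids: folded class
        # proportions follow (1/i + 1/(n-i)) / (1 + [i == n-i])
        g = simulate_dataset(_request(_one_pop(), {"p": 3}, 50_000, 5))
        sfs = folded_sfs(g, "p")
        expected = np.array([1 + 1 / 5, 1 / 2 + 1 / 4, (1 / 3 + 1 / 3) / 2])
        expected /= expected.sum()
        observed = sfs.counts / sfs.total
        se = np.sqrt(expected * (1 - expected) / sfs.total)
        assert (np.abs(observed - expected) < 3 * se).all()

    def test_deep_divergence_fixes_differences(self):
        # split 20 * N_e generations ago -> F_ST near fixation
        s = _split_scenario(t=20 * 100.0, ne=100.0)
        g = simulate_dataset(_request(s, {"a": 5, "c": 5, "b": 1}, 500, 9, G=1.0))
        assert pairwise_fst(g, "a", "c") > 0.9

    def test_exchangeable_under_population_reordering(self):
        s = _split_scenario()
        het_first, het_second = [], []
        for k in range(60):
            g1 = simulate_dataset(_request(s, {"a": 4, "b": 4, "c": 4}, 80, 100 + k))
            g2 = simulate_dataset(_request(s, {"c": 4, "b": 4, "a": 4}, 80, 500 + k))
            het_first.append(heterozygosity(g1, "a")[1])
            het_second.append(heterozygosity(g2, "a")[1])
        assert stats.ks_2samp(het_first, het_second).pvalue > 0.01


class TestEngineAgreement:
    """The built-in lineage simulator is the distributional oracle for the
    msprime engine (same event semantics, independent implementation)."""

    def test_single_population_sfs_agrees(self):
        n_loci = 3000
        g_ms = simulate_dataset(_request(_one_pop(), {"p": 3}, n_loci, 21))
        g_nv = simulate_dataset(_request(_one_pop(), {"p": 3}, n_loci, 22,
                                         engine="naive"))
        a = folded_sfs(g_ms, "p").counts
        b = folded_sfs(g_nv, "p").counts
        table = np.vstack([a, b])
        assert stats.chi2_contingency(table).pvalue > 0.01

    def test_structured_scenario_fst_agrees(self):
        s = _split_scenario(t=1000.0, ne=500.0, nb=20.0, d=40.0)
        sizes = {"a": 4, "b": 4, "c": 4}
        f_ms = np.mean([
            pairwise_fst(simulate_dataset(_request(s, sizes, 400, 31 + k)), "a", "c")
            for k in range(5)
        ])
        f_nv = np.mean([
            pairwise_fst(
                simulate_dataset(_request(s, sizes, 400, 61 + k, engine="naive")),
                "a", "c")
            for k in range(5)
        ])
        assert f_ms == pytest.approx(f_nv, abs=0.04)


class TestModelReductions:
    def test_null_bottleneck_indistinguishable(self):
        # N_b equal to the stable size with zero duration must match the
        # no-bottleneck model in the distribution of mean heterozygosity
        with_b = _split_scenario(nb=1000.0, d=0.0)
        without = _split_scenario(nb=None)
        sizes = {"a": 4, "b": 4, "c": 4}
        h1 = [heterozygosity(simulate_dataset(_request(with_b, sizes, 100, 1000 + k)),
                             "c")[1] for k in range(200)]
        h2 = [heterozygosity(simulate_dataset(_request(without, sizes, 100, 3000 + k)),
                             "c")[1] for k in range(200)]
        assert stats.ks_2samp(h1, h2).pvalue > 0.01

    def test_total_admixture_reduces_to_split(self):
        # r -> 1 pulls every founding lineage from source a: equivalent to
        # a pure split, measured on F_ST between the target and source b
        admixed = _split_scenario(admix_r=1 - 1e-12)
        split = _split_scenario()
        sizes = {"a": 4, "b": 4, "c": 4}
        f1 = [pairwise_fst(simulate_dataset(_request(admixed, sizes, 100, 5000 + k)),
                           "b", "c") for k in range(200)]
        f2 = [pairwise_fst(simulate_dataset(_request(split, sizes, 100, 7000 + k)),
                           "b", "c") for k in range(200)]
        assert stats.ks_2samp(f1, f2).pvalue > 0.01


class TestReferenceTable:
    def test_cardinality_and_column_partition(self):
        step = _step1()
        tbl = generate_reference_table(step, n_sims_per_scenario=10, n_loci=40,
                                       sample_sizes={p: 4 for p in
                                                     step.candidates[0].sampled},
                                       seed=2)
        assert len(tbl) == 30
        assert sorted(tbl.labels) == ["S1a", "S1b", "S1c"]
        assert len(tbl.stat_names) == 21  # P = 3 roster
        assert "t_us" in tbl.param_names

    def test_bit_identical_per_seed(self):
        step = _step1()
        kw = dict(n_sims_per_scenario=8, n_loci=30,
                  sample_sizes={p: 3 for p in step.candidates[0].sampled}, seed=4)
        assert generate_reference_table(step, **kw).data.equals(
            generate_reference_table(step, **kw).data
        )

    def test_parameter_columns_within_prior_bounds(self):
        step = _step1()
        tbl = generate_reference_table(step, n_sims_per_scenario=15, n_loci=30,
                                       sample_sizes={p: 3 for p in
                                                     step.candidates[0].sampled},
                                       seed=6)
        for cand in step.candidates:
            sub = tbl.restrict(cand.label)
            for name in cand.priors.names():
                lo, hi = cand.priors.uniforms[name]
                col = sub.parameter(name)
                assert np.nanmin(col) >= lo and np.nanmax(col) <= hi

    def test_restrict_unknown_label_raises(self):
        step = _step1()
        tbl = generate_reference_table(step, n_sims_per_scenario=5, n_loci=20,
                                       sample_sizes={p: 3 for p in
                                                     step.candidates[0].sampled},
                                       seed=8)
        with pytest.raises(KeyError):
            tbl.restrict("S9x")

    def test_csv_round_trip(self, tmp_path):
        from bridgehead import ReferenceTable

        step = _step1()
        tbl = generate_reference_table(step, n_sims_per_scenario=5, n_loci=20,
                                       sample_sizes={p: 3 for p in
                                                     step.candidates[0].sampled},
                                       seed=9)
        tbl.to_csv(tmp_path / "t.csv")
        back = ReferenceTable.from_csv(tmp_path / "t.csv")
        assert back.stat_names == tbl.stat_names
        assert back.param_names == tbl.param_names
        assert np.allclose(back.stats_matrix(), tbl.stats_matrix())
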