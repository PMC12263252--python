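import numpy as np
import pytest

from pteroevo import (DataError, SimulationConfig, bm_covariance,
                      simulate_island_communities, simulate_specimens,
                      simulate_trait, simulate_yule, write_newick)
from pteroevo.synthdata import simulate_yule_duration

from conftest import simulate_bm


class TestYule:
    def test_study_conditions(self):
        t = simulate_yule(56, crown_age=8.7, seed=0)
        assert t.n_tips == 56
        d = t.depths()[t.tip_indices]
        assert np.all(np.abs(d - 8.7) < 1e-9)

    def test_determinism(self):
        a = write_newick(simulate_yule(20, crown_age=8.7, seed=42))
        b = write_newick(simulate_yule(20, crown_age=8.7, seed=42))
        assert a == b
        c = write_newick(simulate_yule(20, crown_age=8.7, seed=43))
        assert a != c

    def test_expected_lineage_growth(self):
        # crown-conditioned pure birth: E[N(T)] = 2 e^{bT}
        b, T = 0.35, 4.0
        counts = np.array([simulate_yule_duration(b, T, seed=s).n_tips
                           for s in range(500)], dtype=float)
        expect = 2.0 * np.exp(b * T)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - expect) < 3.0 * se

    def test_invalid_inputs(self):
        with pytest.raises(DataError):
            simulate_yule(2, crown_age=8.7)
        with pytest.raises(DataError):
            simulate_yule(10, birth_rate=-1.0)


class TestTraitSimulation:
    def test_ou_alpha_zero_is_bm(self, small_tree):
        cfg_ou = SimulationConfig(seed=5, model="OU", sigma2=4.0, alpha=0.0,
                                  theta={"M": 60.0}, z0=55.0)
        cfg_bm = SimulationConfig(seed=5, model="BM", sigma2=4.0, alpha=0.0,
                                  theta={"M": 60.0}, z0=55.0)
        a = simulate_trait(small_tree, cfg_ou).tip_values
        b = simulate_trait(small_tree, cfg_bm).tip_values
        assert a == b  # identical draws: the limit is handled analytically

    def test_strong_pull_reaches_optimum(self, yule56, scheme4_56):
        # stationary sd = sqrt(sigma2/(2 alpha)); alpha=1e5 makes it ~0.016,
        # so a 0.1 window around each optimum is a >6 sigma bound
        cfg = SimulationConfig(seed=3, model="OU", sigma2=52.0, alpha=1e5,
                               theta={"L": 93.4, "M": 65.1, "S": 47.5,
                                      "I": 54.4})
        sim = simulate_trait(yule56, cfg, regimes=scheme4_56)
        for taxon, value in sim.tip_values.items():
            theta = cfg.theta[scheme4_56.category_of(taxon)]
            assert abs(value - theta) < 0.1

    def test_bm_tip_covariance_matches_tree(self, small_tree):
        # many replicates against the analytic covariance [[2,1,0],...]
        n_rep = 8000
        vals = np.empty((n_rep, 3))
        for r in range(n_rep):
            sim = simulate_bm(small_tree, seed=r, sigma2=1.0, z0=55.6)
            vals[r] = [sim.tip_values[l] for l in small_tree.tip_labels]
        emp = np.cov(vals.T)
        expect = bm_covariance(small_tree)
        # Monte-Carlo s.e. of a covariance entry is ~ sqrt(2/n)*scale
        se = 3.0 * np.sqrt(2.0 / n_rep) * 2.0
        assert np.max(np.abs(emp - expect)) < 3.0 * se

    def test_multi_optimum_needs_regimes(self, small_tree):
        cfg = SimulationConfig(seed=1, model="OU", sigma2=1.0, alpha=1.0,
                               theta={"S": 40.0, "L": 90.0})
        with pytest.raises(DataError):
            simulate_trait(small_tree, cfg)

    def test_determinism_and_node_states(self, yule56, scheme4_56):
        cfg = SimulationConfig(seed=9)
        s1 = simulate_trait(yule56, cfg, regimes=scheme4_56)
        s2 = simulate_trait(yule56, cfg, regimes=scheme4_56)
        assert s1.tip_values == s2.tip_values
        assert s1.node_states == s2.node_states
        assert len(s1.node_states) == yule56.n_nodes


class TestCommunities:
    SIZES = {f"t{i:02d}": 38.0 + 1.55 * i for i in range(30)}

    def test_displaced_gap_holds(self):
        comm = simulate_island_communities(self.SIZES, n_areas=6,
                                           species_per_area=3,
                                           structure="displaced",
                                           min_gap=8.0, seed=1)
        for area in comm.occupancy.areas:
            taxa = comm.occupancy.taxa_in(area)
            for i, a in enumerate(taxa):
                for b in taxa[i + 1:]:
                    assert abs(self.SIZES[a] - self.SIZES[b]) >= 8.0

    def test_random_close_pair_rate_matches_enumeration(self):
        # chance that a 3-species sample from the pool has a pair closer
        # than 8 mm, by brute-force enumeration over all triples
        from itertools import combinations
        sizes = list(self.SIZES.values())
        trips = list(combinations(sizes, 3))
        p_true = np.mean([any(abs(a - b) < 8.0 for a, b in
                              combinations(tr, 2)) for tr in trips])
        hits = []
        for s in range(1000):
            comm = simulate_island_communities(self.SIZES, n_areas=1,
                                               species_per_area=3,
                                               structure="random", seed=s)
            taxa = comm.occupancy.taxa_in(comm.occupancy.areas[0])
            close = any(abs(self.SIZES[a] - self.SIZES[b]) < 8.0
                        for a, b in combinations(taxa, 2))
            hits.append(close)
        p_emp = np.mean(hits)
        se = np.sqrt(p_true * (1 - p_true) / 1000)
        assert abs(p_emp - p_true) < 3.0 * se

    def test_single_isolated_taxon(self):
        comm = simulate_island_communities({"a": 50.0, "b": 60.0}, n_areas=1,
                                           species_per_area=1,
                                           structure="displaced", seed=0)
        assert len(comm.occupancy.taxa) == 1
        assert list(comm.planted_tiers.values()) == ["I"]

    def test_infeasible_gap_raises(self):
        with pytest.raises(DataError):
            simulate_island_communities({"a": 50.0, "b": 51.0, "c": 52.0},
                                        n_areas=1, species_per_area=3,
                                        structure="displaced", min_gap=8.0,
                                        seed=0)


class TestSpecimens:
    def test_summary_recomputed_from_specimens(self):
        tt = simulate_specimens({"a": 60.0, "b": 70.0}, n_per_taxon=5,
                                sd=1.5, seed=2)
        for taxon in tt.taxa:
            sub = tt.specimens[tt.specimens["taxon"] == taxon]["cbl_mm"]
            assert tt.mean_of(taxon) == pytest.approx(sub.mean(), abs=1e-9)
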