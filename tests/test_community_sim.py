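import numpy as np
import pandas as pd
import pytest

from campart.community_sim import (ENVIRONMENT, ISLAND, PLOTS,
                                   SimulationConfig, assign_species_types,
                                   blomberg_k, competition_ranking,
                                   generate_benchmark,
                                   mzsm_metacommunity, selection_abundances,
                                   simulate_dataset, simulate_trait,
                                   simulate_tree, situation_mixes)
from campart.phylo_binning import bin_by_tree, cophenetic_distances

N_POOL = 300  # desk-size regional pool for unit tests


@pytest.fixture(scope="module")
def pool_tree():
    return simulate_tree(N_POOL, seed=8)


@pytest.fixture(scope="module")
def pool_dist(pool_tree):
    return cophenetic_distances(pool_tree)


@pytest.fixture(scope="module")
def pool_bins(pool_tree, pool_dist):
    return bin_by_tree(pool_tree, 0.2, 12, dist=pool_dist)


@pytest.fixture(scope="module")
def meta(pool_tree):
    return mzsm_metacommunity(pool_tree, J=50_000, theta=200.0, seed=4)


@pytest.fixture(scope="module")
def test_config():
    return SimulationConfig(n_tips=N_POOL, J=50_000, theta=200.0,
                            local_size=500, richness=50)


class TestSimulateTree:
    def test_tip_count_and_names(self):
        tree = simulate_tree(40, seed=1)
        tips = list(tree.tips())
        assert len(tips) == 40
        assert tips[0].name.startswith("sp")

    def test_ultrametric_unit_depth(self):
        tree = simulate_tree(30, seed=2)
        depths = [t.accumulate_to_ancestor(tree) for t in tree.tips()]
        np.testing.assert_allclose(depths, 1.0, atol=1e-9)

    def test_reproducible(self):
        a = simulate_tree(25, seed=3)
        b = simulate_tree(25, seed=3)
        assert str(a) == str(b)

    def test_birth_death_option(self):
        tree = simulate_tree(25, seed=3, shape="birth_death")
        assert len(list(tree.tips())) == 25
        depths = [t.accumulate_to_ancestor(tree) for t in tree.tips()]
        np.testing.assert_allclose(depths, 1.0, atol=1e-9)


class TestBlombergK:
    def test_brownian_trait_near_one(self):
        tree = simulate_tree(80, seed=5)
        from campart.community_sim import (_evolve_bm, _tree_arrays,
                                           phylo_covariance)
        arrays = _tree_arrays(tree)
        _, parent, length, depth, tip_rows, tip_names = arrays
        cov = phylo_covariance(tree)
        ks = []
        for s in range(60):
            z = np.random.default_rng(s).standard_normal(len(parent))
            # unbounded Brownian motion (no reflection): use tiny variance
            x = 0.5 + np.zeros(len(parent))
            for i in range(len(parent)):
                if parent[i] >= 0:
                    x[i] = x[parent[i]] + z[i] * np.sqrt(0.001 * length[i])
            trait = pd.Series(x[tip_rows], index=tip_names)
            ks.append(blomberg_k(tree, trait, cov=cov))
        assert 0.8 < np.mean(ks) < 1.2

    def test_white_noise_low_k(self):
        tree = simulate_tree(80, seed=6)
        rng = np.random.default_rng(0)
        names = [t.name for t in tree.tips()]
        ks = [blomberg_k(tree, pd.Series(rng.normal(size=80), index=names))
              for _ in range(10)]
        assert np.mean(ks) < 0.5

    def test_affine_invariance(self):
        tree = simulate_tree(40, seed=7)
        rng = np.random.default_rng(1)
        names = [t.name for t in tree.tips()]
        x = pd.Series(rng.normal(size=40), index=names)
        k1 = blomberg_k(tree, x)
        k2 = blomberg_k(tree, 3.5 * x + 11.0)
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_constant_trait_rejected(self):
        tree = simulate_tree(10, seed=8)
        names = [t.name for t in tree.tips()]
        with pytest.raises(ValueError, match="constant"):
            blomberg_k(tree, pd.Series(np.ones(10), index=names))


class TestSimulateTrait:
    def test_scenario_k_ordering_and_bounds(self, pool_tree):
        lps, k_l = simulate_trait(pool_tree, "LPS", seed=1, max_attempts=60)
        hps, k_h = simulate_trait(pool_tree, "HPS", seed=1, max_attempts=60)
        assert k_h > k_l
        for tr in (lps, hps):
            assert tr.min() >= 0 and tr.max() <= 1

    def test_mps_k_within_band(self, pool_tree):
        _, k = simulate_trait(pool_tree, "MPS", seed=2, max_attempts=60)
        assert 0.45 <= k <= 1.35

    def test_lps_hits_target(self, pool_tree):
        _, k = simulate_trait(pool_tree, "LPS", seed=3, max_attempts=60)
        assert k == pytest.approx(0.15, abs=0.075)

    def test_reproducible(self, pool_tree):
        a, _ = simulate_trait(pool_tree, "MPS", seed=4, max_attempts=60)
        b, _ = simulate_trait(pool_tree, "MPS", seed=4, max_attempts=60)
        pd.testing.assert_series_equal(a, b)


class TestMzsm:
    def test_sums_to_one_and_reproducible(self, pool_tree):
        a = mzsm_metacommunity(pool_tree, J=50_000, theta=100.0, seed=9)
        b = mzsm_metacommunity(pool_tree, J=50_000, theta=100.0, seed=9)
        assert a.sum() == pytest.approx(1.0)
        pd.testing.assert_series_equal(a, b)

    def test_larger_theta_more_even(self, pool_tree):
        def shannon_evenness(p):
            p = p[p > 0]
            return float(-(p * np.log(p)).sum() / np.log(len(p)))

        means = []
        for theta in (50.0, 500.0, 5000.0):
            vals = [shannon_evenness(
                mzsm_metacommunity(pool_tree, J=200_000, theta=theta,
                                   seed=s).to_numpy())
                for s in range(20)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestAssignSpeciesTypes:
    def test_pure_selection(self, meta, pool_dist, pool_bins):
        types = assign_species_types(meta, pool_dist,
                                     {"selection": 1.0, "dispersal": 0,
                                      "drift": 0}, bins=pool_bins)
        assert (types == "selection").all()

    def test_realized_fractions_within_tolerance(self, meta, pool_dist,
                                                 pool_bins):
        mix = {"selection": 0.25, "dispersal": 0.25, "drift": 0.5}
        types = assign_species_types(meta, pool_dist, mix, bins=pool_bins,
                                     seed=3)
        ab = meta / meta.sum()
        for t, target in mix.items():
            assert abs(ab[types == t].sum() - target) <= 0.02 + 1e-12

    def test_types_constant_within_bins(self, meta, pool_dist, pool_bins):
        types = assign_species_types(
            meta, pool_dist, {"selection": 0.5, "dispersal": 0.25,
                              "drift": 0.25}, bins=pool_bins, seed=1)
        arr = types.to_numpy()
        for k in range(pool_bins.n_bins):
            mem = pool_bins.members(k)
            assert len(set(arr[mem])) == 1

    def test_species_level_propagation(self, meta, pool_dist):
        types = assign_species_types(
            meta, pool_dist, {"selection": 0.3, "dispersal": 0,
                              "drift": 0.7}, unit="species", seed=2,
            ds=0.1)
        assert set(types) <= {"selection", "drift"}
        ab = meta / meta.sum()
        assert abs(ab[types == "selection"].sum() - 0.3) <= 0.02 + 1e-12


class TestSelectionPrimitives:
    def test_gaussian_weight_ratios(self):
        sigma = 0.015
        w = selection_abundances(0.5, [0.5, 0.5 + sigma, 0.5 + 3 * sigma],
                                 sigma)
        assert w[1] / w[0] == pytest.approx(np.exp(-0.5))
        assert w[2] / w[0] == pytest.approx(np.exp(-4.5))

    def test_optimum_is_max(self):
        w = selection_abundances(0.3, np.linspace(0, 1, 21), 0.05)
        assert np.argmax(w) == 6  # trait 0.30

    def test_competition_niche_difference_and_geometric_series(self):
        # nd for a third competitor after priors at 0.2 and 0.8:
        # sqrt(0.5*(0.3)^2 + 0.25*(0.3)^2) = 0.2598
        nd = np.sqrt(0.5 * 0.09 + 0.25 * 0.09)
        assert nd == pytest.approx(0.2598, abs=1e-4)
        trait = {"a": 0.2, "b": 0.8, "c": 0.5}
        ranked, w = competition_ranking(0.21, trait, ["a", "b", "c"],
                                        seed=0)
        # abundances follow the halving series regardless of order
        np.testing.assert_allclose(w, np.array([0.5, 0.25, 0.125]) / 0.875)

    def test_competition_first_pick_is_among_fittest(self):
        # 14 candidates: the random first pick must come from the 10
        # with the smallest distance to the environment
        trait = {f"good{i}": 0.5 + 0.001 * i for i in range(10)}
        trait.update({f"bad{i}": 0.9 + 0.01 * i for i in range(4)})
        for seed in range(10):
            ranked, _ = competition_ranking(0.5, trait, list(trait),
                                            seed=seed)
            assert ranked[0].startswith("good")

    def test_competition_farther_trait_wins_next_rank(self):
        trait = {"a": 0.5, "near": 0.52, "far": 0.05}
        for seed in range(10):
            ranked, _ = competition_ranking(0.5, trait, list(trait),
                                            seed=seed)
            if ranked[0] in ("a", "near"):
                assert ranked[1] == "far"


@pytest.fixture(scope="module")
def datasets(pool_tree, pool_dist, pool_bins, meta, test_config):
    trait, _ = simulate_trait(pool_tree, "MPS", seed=5, max_attempts=60)
    out = {}
    for name, mix in {
        "drift": {"selection": 0, "dispersal": 0, "drift": 1.0},
        "dispersal": {"selection": 0, "dispersal": 1.0, "drift": 0},
        "mixed": {"selection": 0.5, "dispersal": 0.25, "drift": 0.25},
    }.items():
        out[name] = simulate_dataset(pool_tree, trait, meta, mix,
                                     test_config, seed=11,
                                     dist=pool_dist, bins=pool_bins)
    return out


class TestSimulatedDatasets:
    def test_exact_sizes_and_richness(self, datasets, test_config):
        for ds in datasets.values():
            counts = ds.table.abundance
            np.testing.assert_allclose(counts.sum(axis=0),
                                       test_config.local_size)
            np.testing.assert_array_equal((counts > 0).sum(axis=0),
                                          test_config.richness)

    def test_24_samples_in_4_plots(self, datasets):
        ds = datasets["drift"]
        assert ds.table.n_samples == 24
        assert sorted(set(ds.plot_map.values())) == sorted(PLOTS)

    def test_island_pools_disjoint(self, datasets):
        # the abundant (pool) species of the two islands do not overlap;
        # only rare metacommunity leakage is shared
        ds = datasets["dispersal"]
        counts = ds.table.abundance
        idx_a = [j for j, s in enumerate(ds.table.sample_ids)
                 if ISLAND[ds.plot_map[s]] == "A"]
        idx_b = [j for j, s in enumerate(ds.table.sample_ids)
                 if ISLAND[ds.plot_map[s]] == "B"]
        ab_a = counts[:, idx_a].sum(axis=1)
        ab_b = counts[:, idx_b].sum(axis=1)
        pool_a = ab_a / ab_a.sum() > 0.005
        pool_b = ab_b / ab_b.sum() > 0.005
        assert not np.any(pool_a & pool_b)
        # an island holds only trace (leaked) abundance of the other
        # island's pool species
        assert ab_b[pool_a].sum() / ab_b.sum() < 0.15
        assert ab_a[pool_b].sum() / ab_a.sum() < 0.15

    def test_within_island_more_similar(self, datasets):
        ds = datasets["dispersal"]
        counts = ds.table.abundance > 0

        def jaccard(i, j):
            a, b = counts[:, i], counts[:, j]
            return (a & b).sum() / (a | b).sum()

        ids = ds.table.sample_ids
        within, between = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                same = ISLAND[ds.plot_map[ids[i]]] == \
                    ISLAND[ds.plot_map[ids[j]]]
                (within if same else between).append(jaccard(i, j))
        assert np.mean(within) > np.mean(between)

    def test_drift_tracks_metacommunity(self, pool_tree, pool_dist,
                                        pool_bins, meta, test_config):
        trait, _ = simulate_trait(pool_tree, "MPS", seed=5,
                                  max_attempts=60)
        mix = {"selection": 0, "dispersal": 0, "drift": 1.0}
        rels = []
        for seed in range(15):
            ds = simulate_dataset(pool_tree, trait, meta, mix, test_config,
                                  seed=seed, dist=pool_dist,
                                  bins=pool_bins)
            rel = ds.table.abundance / ds.table.abundance.sum(axis=0)
            rels.append(rel.mean(axis=1))
        mean_rel = np.mean(rels, axis=0)
        r = np.corrcoef(mean_rel, meta.to_numpy())[0, 1]
        assert r > 0.9

    def test_expected_importance_rows_sum_to_one(self, datasets):
        for ds in datasets.values():
            from campart.process_partition import PROCESSES
            sums = ds.expected[list(PROCESSES)].sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_expected_importance_pure_drift(self, datasets):
        np.testing.assert_allclose(datasets["drift"].expected["DR"], 1.0,
                                   atol=1e-9)

    def test_expected_importance_geometry(self, datasets):
        ds = datasets["dispersal"]
        for pair, row in ds.expected.iterrows():
            u, v = pair.split("|")
            same_island = ISLAND[ds.plot_map[u]] == ISLAND[ds.plot_map[v]]
            if same_island:
                assert row["HD"] == pytest.approx(1.0)
            else:
                assert row["DL"] == pytest.approx(1.0)

    def test_expected_importance_mixture(self, datasets):
        ds = datasets["mixed"]
        # within one environment: selection contributes HoS, never HeS
        for pair, row in ds.expected.iterrows():
            u, v = pair.split("|")
            if ENVIRONMENT[ds.plot_map[u]] == ENVIRONMENT[ds.plot_map[v]]:
                assert row["HeS"] == 0.0
                assert row["HoS"] > 0.1
            else:
                assert row["HoS"] == 0.0


class TestBenchmarkGrid:
    def test_fifteen_distinct_mixes(self):
        mixes = situation_mixes()
        assert len(mixes) == 15
        seen = {tuple(m.values()) for m in mixes}
        assert len(seen) == 15
        for m in mixes:
            assert sum(m.values()) == pytest.approx(1.0)
        pure = [m for m in mixes if 1.0 in m.values()]
        assert len(pure) == 3

    def test_generate_benchmark_small(self, test_config):
        datasets = generate_benchmark("MPS", seed=2, config=test_config)
        assert len(datasets) == 15
        names = {d.situation for d in datasets}
        assert len(names) == 15
        assert all(d.table.n_samples == 24 for d in datasets)


class TestComplexBinMode:
    def test_analysis_bins_can_mix_processes(self, pool_tree, pool_dist,
                                             pool_bins, meta):
        cfg = SimulationConfig(n_tips=N_POOL, J=50_000, theta=200.0,
                               local_size=500, richness=50,
                               complex_bins=True)
        mixed_any = False
        for seed in range(4):
            ds = simulate_dataset(
                pool_tree, simulate_trait(pool_tree, "MPS", seed=5,
                                          max_attempts=60)[0],
                meta, {"selection": 0.5, "dispersal": 0.25, "drift": 0.25},
                cfg, seed=seed, dist=pool_dist, bins=pool_bins)
            arr = ds.types.to_numpy()
            for k in range(pool_bins.n_bins):
                if len(set(arr[pool_bins.members(k)])) > 1:
                    mixed_any = True
            counts = ds.table.abundance
            np.testing.assert_allclose(counts.sum(axis=0), 500)
        assert mixed_any
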