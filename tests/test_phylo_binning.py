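import numpy as np
import pandas as pd
import pytest

from campart.data_io import CommunityTable, EnvTable
from campart.phylo_binning import (BinSet, PhyloDistMatrix, bin_by_centroid,
                                   bin_by_pairwise, bin_by_tree,
                                   bin_phylo_signal, cophenetic_distances,
                                   merge_small_bins, niche_values,
                                   optimize_nmin)
from tests.conftest import random_tree


class TestCopheneticDistances:
    def test_path_sums(self, tiny_tree):
        d = cophenetic_distances(tiny_tree)
        df = pd.DataFrame(d.data, index=d.taxa_ids, columns=d.taxa_ids)
        assert df.loc["A", "B"] == pytest.approx(2.0)
        assert df.loc["A", "C"] == pytest.approx(4.0)
        assert df.loc["B", "C"] == pytest.approx(4.0)

    def test_zero_diagonal_and_symmetry(self, two_clade_tree):
        d = cophenetic_distances(two_clade_tree)
        assert np.all(np.diag(d.data) == 0)
        np.testing.assert_allclose(d.data, d.data.T)


def _strict_bins_ok(bins, dist, ds, criterion):
    """Brute-force check of each strict bin's defining criterion."""
    for k in range(bins.n_bins):
        if not bins.summary["strict"].iloc[k]:
            continue
        idx = bins.members(k)
        sub = dist.data[np.ix_(idx, idx)]
        if criterion == "pairwise":
            assert sub.max() < ds
        elif criterion == "radius":
            # at least one member (the centroid) within ds of all others
            assert (sub < ds).all(axis=1).any()


class TestBinningAlgorithms:
    @pytest.mark.parametrize("algorithm", [bin_by_centroid, bin_by_pairwise])
    def test_two_clades_recovered(self, two_clade_tree, algorithm):
        dist = cophenetic_distances(two_clade_tree)
        mean_ra = np.linspace(1, 2, 20) / 30.0
        bins = algorithm(dist, mean_ra, ds=0.2, nmin=3)
        assert bins.n_bins == 2
        for k in range(2):
            clades = {dist.taxa_ids[i][0] for i in bins.members(k)}
            assert len(clades) == 1  # all L or all R

    def test_tree_binning_two_clades(self, two_clade_tree):
        bins = bin_by_tree(two_clade_tree, ds=0.2, nmin=3)
        assert bins.n_bins == 2
        assert sorted(bins.sizes()) == [10, 10]

    def test_tree_binning_huge_ds_single_bin(self, two_clade_tree):
        bins = bin_by_tree(two_clade_tree, ds=10.0, nmin=1)
        assert bins.n_bins == 1

    def test_star_single_bin_by_centroid(self):
        names = [f"t{i}" for i in range(6)]
        d = np.full((6, 6), 0.1)
        np.fill_diagonal(d, 0.0)
        dist = PhyloDistMatrix(names, d)
        bins = bin_by_centroid(dist, np.ones(6) / 6, ds=0.2, nmin=2)
        assert bins.n_bins == 1

    def test_pairwise_greedy_chain(self):
        d = np.array([[0.0, 0.15, 0.30],
                      [0.15, 0.0, 0.15],
                      [0.30, 0.15, 0.0]])
        dist = PhyloDistMatrix(["A", "B", "C"], d)
        bins = bin_by_pairwise(dist, [0.5, 0.3, 0.2], ds=0.2, nmin=1)
        bs = bins.to_series()
        assert bs["A"] == bs["B"]
        assert bs["C"] != bs["A"]

    def test_single_taxon(self):
        dist = PhyloDistMatrix(["A"], np.zeros((1, 1)))
        bins = bin_by_pairwise(dist, [1.0], ds=0.2, nmin=1)
        assert bins.n_bins == 1

    @pytest.mark.parametrize("seed", [0, 1])
    def test_strict_bins_meet_their_criterion(self, seed):
        tree = random_tree(60, seed)
        dist = cophenetic_distances(tree)
        mean_ra = np.random.default_rng(seed).dirichlet(np.ones(60))
        b1 = bin_by_pairwise(dist, mean_ra, ds=0.25, nmin=1)
        _strict_bins_ok(b1, dist, 0.25, "pairwise")
        b2 = bin_by_centroid(dist, mean_ra, ds=0.25, nmin=1)
        _strict_bins_ok(b2, dist, 0.25, "radius")
        b3 = bin_by_tree(tree, ds=0.25, nmin=1, dist=dist)
        _strict_bins_ok(b3, dist, 0.25, "pairwise")

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_partition_property(self, seed):
        tree = random_tree(50, seed)
        dist = cophenetic_distances(tree)
        bins = bin_by_tree(tree, ds=0.2, nmin=5, dist=dist)
        assert bins.sizes().sum() == 50
        assert np.all(bins.sizes() >= 5)

    def test_deterministic(self, two_clade_tree):
        dist = cophenetic_distances(two_clade_tree)
        mean_ra = np.ones(20) / 20
        a = bin_by_centroid(dist, mean_ra, 0.2, 3).bin_ids
        b = bin_by_centroid(dist, mean_ra, 0.2, 3).bin_ids
        np.testing.assert_array_equal(a, b)


class TestMergeSmallBins:
    def _dist(self):
        # three groups at mutual distances: g0 close to g1, far from g2
        names = [f"t{i}" for i in range(12)]
        d = np.full((12, 12), 5.0)
        groups = [range(0, 2), range(2, 7), range(7, 12)]
        for g in groups:
            for i in g:
                for j in g:
                    d[i, j] = 0.1 if i != j else 0.0
        for i in groups[0]:
            for j in groups[1]:
                d[i, j] = d[j, i] = 1.0
        return PhyloDistMatrix(names, d), groups

    def test_small_bin_merges_into_nearest(self):
        dist, groups = self._dist()
        ids = np.zeros(12, dtype=int)
        ids[2:7] = 1
        ids[7:] = 2
        strict = BinSet(dist.taxa_ids, ids)
        merged = merge_small_bins(strict, dist, nmin=3)
        assert sorted(merged.sizes()) == [5, 7]
        bs = merged.to_series()
        assert bs["t0"] == bs["t2"]  # joined the nearer group

    def test_no_small_bins_identity(self):
        dist, _ = self._dist()
        ids = np.array([0] * 7 + [1] * 5)
        merged = merge_small_bins(BinSet(dist.taxa_ids, ids), dist, nmin=3)
        np.testing.assert_array_equal(np.sort(merged.sizes()), [5, 7])

    def test_fallback_single_bin(self):
        dist = PhyloDistMatrix(["A", "B"], np.array([[0, 1.], [1., 0]]))
        strict = BinSet(["A", "B"], np.array([0, 1]))
        with pytest.warns(UserWarning, match="single bin"):
            merged = merge_small_bins(strict, dist, nmin=5)
        assert merged.n_bins == 1

    def test_merged_bins_lose_strict_flag(self):
        dist, _ = self._dist()
        ids = np.zeros(12, dtype=int)
        ids[2:7] = 1
        ids[7:] = 2
        merged = merge_small_bins(BinSet(dist.taxa_ids, ids), dist, nmin=3)
        assert not merged.summary["strict"].all()


class TestNicheValues:
    def test_worked_temperature_example(self):
        # relative abundances 10%, 20%, 10% at 10, 20, 30 degrees -> 20
        table = CommunityTable(
            ["OTU1", "other"], ["s1", "s2", "s3"],
            np.array([[0.10, 0.20, 0.10], [0.90, 0.80, 0.90]]))
        table.is_relative = True
        env = EnvTable(values=pd.DataFrame(
            {"temperature": [10.0, 20.0, 30.0]},
            index=["s1", "s2", "s3"]))
        nv = niche_values(table, env)
        assert nv.loc["OTU1", "temperature"] == pytest.approx(20.0)

    def test_single_occurrence(self):
        table = CommunityTable(["A", "B"], ["s1", "s2"],
                               np.array([[1.0, 0.0], [1.0, 5.0]]))
        env = EnvTable(values=pd.DataFrame({"f": [3.0, 7.0]},
                                           index=["s1", "s2"]))
        nv = niche_values(table, env)
        assert nv.loc["A", "f"] == pytest.approx(3.0)

    def test_constant_factor(self, small_table):
        env = EnvTable(values=pd.DataFrame({"f": [4.0, 4.0]},
                                           index=["s1", "s2"]))
        nv = niche_values(small_table, env)
        assert np.allclose(nv["f"], 4.0)

    def test_bounded_by_factor_range(self):
        rng = np.random.default_rng(0)
        table = CommunityTable([f"t{i}" for i in range(8)],
                               [f"s{j}" for j in range(5)],
                               rng.uniform(0, 1, (8, 5)) + 0.01)
        env = EnvTable(values=pd.DataFrame(
            {"f": rng.uniform(-3, 3, 5)}, index=table.sample_ids))
        nv = niche_values(table, env)["f"]
        assert nv.min() >= env.values["f"].min() - 1e-12
        assert nv.max() <= env.values["f"].max() + 1e-12


class TestBinPhyloSignal:
    def test_perfect_signal(self, two_clade_tree):
        dist = cophenetic_distances(two_clade_tree)
        bins = BinSet(dist.taxa_ids, np.zeros(20, dtype=int))
        # niche values whose differences mirror the distances: clade-coded
        niche = pd.Series([0.0 if t.startswith("L") else 1.0
                           for t in dist.taxa_ids], index=dist.taxa_ids)
        rep = bin_phylo_signal(bins, dist, niche.to_frame("f"),
                               permutations=199, seed=0)
        assert rep.loc[0, "r"] > 0.9
        assert rep.loc[0, "p"] <= 1.0 / 200 + 1e-12
        assert bool(rep.loc[0, "significant"])

    def test_null_false_positive_rate(self):
        # shuffled niche values: significance rate stays near alpha
        from tests.conftest import random_dist
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 150
        for i in range(n_rep):
            d = random_dist(10, i)
            names = [f"t{j}" for j in range(10)]
            dist = PhyloDistMatrix(names, d)
            bins = BinSet(names, np.zeros(10, dtype=int))
            niche = pd.Series(rng.normal(size=10), index=names)
            rep = bin_phylo_signal(bins, dist, niche.to_frame("f"),
                                   permutations=99,
                                   seed=int(rng.integers(2**31 - 1)))
            hits += int(rep["significant"].iloc[0])
        assert hits / n_rep < 0.12

    def test_threshold_logic(self):
        # R below 0.1 or p above 0.05 must not flag
        names = ["a", "b", "c"]
        d = np.array([[0, 1.0, 2.0], [1.0, 0, 1.0], [2.0, 1.0, 0]])
        dist = PhyloDistMatrix(names, d)
        bins = BinSet(names, np.zeros(3, dtype=int))
        niche = pd.Series([0.0, 0.0, 0.0], index=names)
        rep = bin_phylo_signal(bins, dist, niche.to_frame("f"),
                               permutations=99, seed=0)
        assert not rep["significant"].iloc[0]


class TestOptimizeNmin:
    def test_single_candidate(self, two_clade_tree):
        dist = cophenetic_distances(two_clade_tree)
        niche = pd.Series(np.linspace(0, 1, 20),
                          index=dist.taxa_ids).to_frame("f")
        best, table = optimize_nmin([3], dist, niche, ds=0.2,
                                    tree=two_clade_tree, permutations=49)
        assert best == 3
        assert list(table.index) == [3]

    def test_tie_rules(self, monkeypatch, two_clade_tree):
        import campart.phylo_binning as pb

        dist = cophenetic_distances(two_clade_tree)
        niche = pd.Series(np.linspace(0, 1, 20),
                          index=dist.taxa_ids).to_frame("f")
        fake = {3: (5, 0.4), 5: (5, 0.3), 7: (7, 0.2)}

        def fake_signal(bins, dist, niche, permutations=999, seed=0,
                        **kw):
            nmin = fake_signal.current
            n_sig, mean_r = fake[nmin]
            return pd.DataFrame({
                "bin": range(10), "size": 3, "factor": "f",
                "r": [mean_r] * 10, "p": [0.01] * n_sig + [0.5] * (10 - n_sig),
                "significant": [True] * n_sig + [False] * (10 - n_sig),
            }).set_index("bin")

        real_bin_by_tree = pb.bin_by_tree

        def wrapped(tree, ds, nmin, dist=None):
            fake_signal.current = nmin
            return real_bin_by_tree(tree, ds, max(1, min(nmin, 3)),
                                    dist=dist)

        monkeypatch.setattr(pb, "bin_phylo_signal", fake_signal)
        monkeypatch.setattr(pb, "bin_by_tree", wrapped)
        # candidate 7 has most significant bins
        best, _ = optimize_nmin([3, 5, 7], dist, niche, ds=0.2,
                                tree=two_clade_tree)
        assert best == 7
        # equal counts: higher mean R wins (3 over 5)
        best, _ = optimize_nmin([3, 5], dist, niche, ds=0.2,
                                tree=two_clade_tree)
        assert best == 3
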