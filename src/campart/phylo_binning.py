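"""Partition taxa into phylogenetic bins with adequate within-bin signal.

A bin is a group of phylogenetically close taxa within which niche
preference is assumed conserved, so that a within-bin null model can read
selection off phylogenetic turnover.  Three binning algorithms are provided
(distance-to-centroid, complete-linkage-style pairwise, and tree truncation)
plus small-bin merging, taxon niche values, the within-bin Mantel test of
phylogenetic signal, and the n_min optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from campart._matrixstats import mantel_permutation_test
from campart.data_io import CommunityTable, EnvTable, to_relative

__all__ = [
    "PhyloDistMatrix",
    "BinSet",
    "cophenetic_distances",
    "bin_by_centroid",
    "bin_by_pairwise",
    "bin_by_tree",
    "merge_small_bins",
    "niche_values",
    "bin_phylo_signal",
    "optimize_nmin",
]


@dataclass
class PhyloDistMatrix:
    """Symmetric matrix of cophenetic (tip-to-tip path) distances."""

    taxa_ids: list
    data: np.ndarray

    def __post_init__(self):
        self.taxa_ids = list(self.taxa_ids)
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.taxa_ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if np.any(self.data < 0):
            raise ValueError("negative distances")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("nonzero diagonal")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("matrix not symmetric")

    def subset(self, taxa) -> "PhyloDistMatrix":
        idx = {t: i for i, t in enumerate(self.taxa_ids)}
        rows = np.array([idx[t] for t in taxa], dtype=np.intp)
        return PhyloDistMatrix(list(taxa), self.data[np.ix_(rows, rows)])


@dataclass
class BinSet:
    """A partition of taxa into bins.

    ``bin_ids`` holds the (0-based) bin index of every taxon, aligned with
    ``taxa_ids``.  ``summary`` has one row per bin: size, centroid taxon,
    strict flag (True until the bin was altered by merging) and mean
    relative abundance when known.
    """

    taxa_ids: list
    bin_ids: np.ndarray
    summary: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.taxa_ids = list(self.taxa_ids)
        self.bin_ids = np.asarray(self.bin_ids, dtype=int)
        if len(self.bin_ids) != len(self.taxa_ids):
            raise ValueError("bin assignment length mismatch")
        if self.summary is None:
            self.summary = _summarize(self.taxa_ids, self.bin_ids)

    @property
    def n_bins(self) -> int:
        return int(self.bin_ids.max()) + 1

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.bin_ids == k)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.bin_ids, minlength=self.n_bins)

    def to_series(self) -> pd.Series:
        return pd.Series(self.bin_ids, index=self.taxa_ids, name="bin")


def _summarize(taxa_ids, bin_ids, strict=None, centroids=None, mean_ra=None):
    n_bins = int(np.max(bin_ids)) + 1
    sizes = np.bincount(bin_ids, minlength=n_bins)
    rows = []
    for k in range(n_bins):
        rows.append({
            "bin": k,
            "size": int(sizes[k]),
            "centroid": None if centroids is None else centroids[k],
            "strict": True if strict is None else bool(strict[k]),
            "mean_ra": np.nan if mean_ra is None else float(
                np.sum(np.asarray(mean_ra)[np.asarray(bin_ids) == k])),
        })
    return pd.DataFrame(rows).set_index("bin")


def cophenetic_distances(tree: TreeNode) -> PhyloDistMatrix:
    """Tip-to-tip path-length distances of a tree."""
    dm = tree.tip_tip_distances()
    return PhyloDistMatrix(list(dm.ids), np.asarray(dm.data, dtype=float))


def _abundance_order(mean_ra, taxa_ids):
    """Indices sorted by descending abundance, ties lexicographic by ID."""
    return sorted(range(len(taxa_ids)),
                  key=lambda i: (-mean_ra[i], taxa_ids[i]))


def _check_params(ds, nmin):
    if ds <= 0:
        raise ValueError("ds must be positive")
    if nmin < 1:
        raise ValueError("nmin must be at least 1")


def bin_by_centroid(dist: PhyloDistMatrix, mean_ra, ds: float,
                    nmin: int) -> BinSet:
    """Radius binning: the most abundant unassigned taxon seeds a bin that
    absorbs every unassigned taxon within ``ds`` of it; repeat, then merge
    small bins up to ``nmin``."""
    _check_params(ds, nmin)
    mean_ra = np.asarray(mean_ra, dtype=float)
    n = len(dist.taxa_ids)
    order = _abundance_order(mean_ra, dist.taxa_ids)
    bin_ids = np.full(n, -1, dtype=int)
    centroids = []
    k = 0
    for i in order:
        if bin_ids[i] >= 0:
            continue
        join = (bin_ids < 0) & (dist.data[i] < ds)
        join[i] = True
        bin_ids[join] = k
        centroids.append(dist.taxa_ids[i])
        k += 1
    strict = BinSet(dist.taxa_ids, bin_ids,
                    _summarize(dist.taxa_ids, bin_ids, centroids=centroids,
                               mean_ra=mean_ra))
    return merge_small_bins(strict, dist, nmin)


def bin_by_pairwise(dist: PhyloDistMatrix, mean_ra, ds: float,
                    nmin: int) -> BinSet:
    """Clique-style binning: a bin grows greedily (descending abundance)
    with taxa whose distance to *every* current member is below ``ds``."""
    _check_params(ds, nmin)
    mean_ra = np.asarray(mean_ra, dtype=float)
    n = len(dist.taxa_ids)
    order = _abundance_order(mean_ra, dist.taxa_ids)
    bin_ids = np.full(n, -1, dtype=int)
    centroids = []
    k = 0
    for seed in order:
        if bin_ids[seed] >= 0:
            continue
        members = [seed]
        bin_ids[seed] = k
        for i in order:
            if bin_ids[i] >= 0:
                continue
            if all(dist.data[i, m] < ds for m in members):
                members.append(i)
                bin_ids[i] = k
        centroids.append(dist.taxa_ids[seed])
        k += 1
    strict = BinSet(dist.taxa_ids, bin_ids,
                    _summarize(dist.taxa_ids, bin_ids, centroids=centroids,
                               mean_ra=mean_ra))
    return merge_small_bins(strict, dist, nmin)


def _clade_diameter(tree):
    """Max tip-tip distance within every clade (iterative post-order)."""
    diam, depth = {}, {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            depth[id(node)] = 0.0
            diam[id(node)] = 0.0
            continue
        child_depths = [depth[id(ch)] + (ch.length or 0.0)
                        for ch in node.children]
        d = max(diam[id(ch)] for ch in node.children)
        tops = sorted(child_depths, reverse=True)
        if len(tops) >= 2:
            d = max(d, tops[0] + tops[1])
        depth[id(node)] = tops[0]
        diam[id(node)] = d
    return diam


def bin_by_tree(tree: TreeNode, ds: float, nmin: int,
                dist: PhyloDistMatrix | None = None) -> BinSet:
    """Truncate the tree as shallowly as possible so that every resulting
    clade has tip-to-tip diameter < ``ds``; clades become strict bins, then
    small bins merge into the bin with the nearest relative."""
    _check_params(ds, nmin)
    if dist is None:
        dist = cophenetic_distances(tree)
    diam = _clade_diameter(tree)
    clades = []
    stack = [tree]
    while stack:
        node = stack.pop()
        if diam[id(node)] < ds:
            clades.append([node.name] if node.is_tip()
                          else [t.name for t in node.tips()])
        else:
            stack.extend(reversed(node.children))
    idx = {t: i for i, t in enumerate(dist.taxa_ids)}
    bin_ids = np.full(len(dist.taxa_ids), -1, dtype=int)
    for k, clade in enumerate(clades):
        for t in clade:
            bin_ids[idx[t]] = k
    if np.any(bin_ids < 0):
        raise ValueError("tree tips and distance matrix ids disagree")
    strict = BinSet(dist.taxa_ids, bin_ids)
    return merge_small_bins(strict, dist, nmin)


def merge_small_bins(strict: BinSet, dist: PhyloDistMatrix,
                     nmin: int, linkage: str = "single") -> BinSet:
    """Merge bins smaller than ``nmin`` into their nearest-neighbour bin.

    The smallest bin (ties: lowest index) merges into the bin minimising the
    between-bin distance (single linkage by default, i.e. the minimum
    cross-pair cophenetic distance; ``linkage='mean'`` available).  Merged
    bins lose the strict flag.  Surviving bins are renumbered contiguously
    in order of their lowest taxon index, which keeps output deterministic.
    """
    n = len(strict.taxa_ids)
    if n < nmin:
        warnings.warn("fewer taxa than nmin: falling back to a single bin")
        return BinSet(strict.taxa_ids, np.zeros(n, dtype=int),
                      _summarize(strict.taxa_ids, np.zeros(n, dtype=int),
                                 strict=[False]))
    groups = {k: list(strict.members(k)) for k in range(strict.n_bins)}
    strict_flag = {k: bool(strict.summary["strict"].get(k, True))
                   for k in groups}
    while True:
        sizes = {k: len(v) for k, v in groups.items()}
        small = [k for k, s in sizes.items() if s < nmin]
        if not small:
            break
        k_small = min(small, key=lambda k: (sizes[k], k))
        best, best_d = None, np.inf
        rows = np.array(groups[k_small], dtype=np.intp)
        for k_other in groups:
            if k_other == k_small:
                continue
            cols = np.array(groups[k_other], dtype=np.intp)
            cross = dist.data[np.ix_(rows, cols)]
            d = cross.min() if linkage == "single" else cross.mean()
            if d < best_d - 1e-15 or (np.isclose(d, best_d)
                                      and (best is None or k_other < best)):
                best, best_d = k_other, d
        groups[best].extend(groups.pop(k_small))
        strict_flag[best] = False
        strict_flag.pop(k_small)
    new_ids = np.empty(n, dtype=int)
    ordered = sorted(groups, key=lambda k: min(groups[k]))
    strict_list = []
    for new_k, old_k in enumerate(ordered):
        for i in groups[old_k]:
            new_ids[i] = new_k
        strict_list.append(strict_flag[old_k])
    return BinSet(strict.taxa_ids, new_ids,
                  _summarize(strict.taxa_ids, new_ids, strict=strict_list))


def niche_values(table: CommunityTable, env: EnvTable) -> pd.DataFrame:
    """Relative-abundance-weighted mean of each environmental factor per
    taxon, a proxy for the taxon's niche optimum.

    v_i = sum_j ra_ij * E_j / sum_j ra_ij over the samples shared between
    the table and the factor table.  Taxa absent everywhere get NaN.
    """
    if set(table.sample_ids) - set(env.sample_ids):
        raise ValueError("environmental table missing some table samples")
    rel = to_relative(table)
    ra = rel.to_dataframe()[table.sample_ids].to_numpy()
    env_vals = env.values.loc[table.sample_ids].to_numpy()  # samples x fac
    wsum = ra.sum(axis=1)
    out = np.full((table.n_taxa, env_vals.shape[1]), np.nan)
    present = wsum > 0
    out[present] = (ra[present] @ env_vals) / wsum[present, None]
    if np.any(~present):
        warnings.warn(f"{int((~present).sum())} taxa absent everywhere: "
                      "niche value undefined")
    return pd.DataFrame(out, index=table.taxa_ids,
                        columns=env.factor_names)


def bin_phylo_signal(bins: BinSet, dist: PhyloDistMatrix,
                     niche: pd.DataFrame, permutations: int = 999,
                     seed: int = 0, r_threshold: float = 0.1,
                     p_threshold: float = 0.05) -> pd.DataFrame:
    """Mantel test of within-bin phylogenetic signal, one bin at a time.

    For each bin of size >= 3, correlates within-bin phylogenetic distances
    with absolute niche-value differences (per factor; the factor with the
    highest R is reported).  A bin is significant when R > 0.1 and the
    one-tailed permutation p < 0.05.
    """
    if isinstance(niche, pd.Series):
        niche = niche.to_frame("trait")
    niche = niche.loc[bins.taxa_ids]
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(bins.n_bins):
        idx = bins.members(k)
        best = {"bin": k, "size": len(idx), "factor": None,
                "r": np.nan, "p": np.nan, "significant": False}
        if len(idx) >= 3:
            sub_d = dist.data[np.ix_(idx, idx)]
            for fac in niche.columns:
                v = niche[fac].to_numpy()[idx]
                if np.any(np.isnan(v)):
                    continue
                nd = np.abs(v[:, None] - v[None, :])
                r, p = mantel_permutation_test(
                    sub_d, nd, permutations,
                    seed=int(rng.integers(2**31 - 1)),
                    alternative="greater")
                if np.isnan(r):
                    continue
                if np.isnan(best["r"]) or r > best["r"]:
                    best.update(factor=fac, r=r, p=p)
        if not np.isnan(best["r"]):
            best["significant"] = bool(best["r"] > r_threshold
                                       and best["p"] < p_threshold)
        rows.append(best)
    return pd.DataFrame(rows).set_index("bin")


def optimize_nmin(candidates, dist: PhyloDistMatrix, niche: pd.DataFrame,
                  ds: float, tree: TreeNode = None, mean_ra=None,
                  algorithm: str = "tree", permutations: int = 999,
                  seed: int = 0):
    """Choose the n_min maximising the number of bins with significant
    phylogenetic signal; ties broken by higher mean within-bin Mantel R,
    then by smaller n_min.  Returns (best_nmin, per-candidate table)."""
    if not candidates:
        raise ValueError("no candidates")
    rows = []
    for nmin in candidates:
        if algorithm == "tree":
            bins = bin_by_tree(tree, ds, nmin, dist=dist)
        elif algorithm == "centroid":
            bins = bin_by_centroid(dist, mean_ra, ds, nmin)
        elif algorithm == "pairwise":
            bins = bin_by_pairwise(dist, mean_ra, ds, nmin)
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        report = bin_phylo_signal(bins, dist, niche,
                                  permutations=permutations, seed=seed)
        rows.append({"nmin": nmin,
                     "n_bins": bins.n_bins,
                     "n_significant": int(report["significant"].sum()),
                     "mean_r": float(report["r"].mean())})
    table = pd.DataFrame(rows).set_index("nmin")
    best = table.sort_values(["n_significant", "mean_r"],
                             ascending=[False, False], kind="stable")
    top = best.iloc[0]
    tied = best[(best["n_significant"] == top["n_significant"])
                & (np.isclose(best["mean_r"], top["mean_r"]))]
    return int(tied.index.min()), table
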