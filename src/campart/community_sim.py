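"""Benchmark community simulator with known per-pair process ground truth.

The simulated region holds a neutral metacommunity (zero-sum multinomial
species-abundance distribution) spread over two islands (A, B), each with a
low-environment (L) and a high-environment (H) plot; six local communities
are sampled per plot, for 24 samples named ``LA1..LA6, LB1.., HA1.., HB1..``.
Species in the regional pool are assigned to a governing process —
selection (Gaussian environmental filtering of a heritable trait), optional
competition (niche-difference geometric ranking), dispersal (disjoint
island pools with high within-island exchange), or drift (neutral sampling
at moderate immigration) — in configurable abundance fractions, and each
local community is assembled part by part so that every pairwise turnover
has a known expected process decomposition.

Three regional pools differ in the phylogenetic signal of the selection
trait: low (Blomberg's K ~ 0.15, mean-reverting trait evolution), medium
(K ~ 0.9, bounded Brownian motion) and high (K ~ 5.5, decelerating-rate
Brownian motion).
"""

from __future__ import annotations

import io
import math
import random
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from campart.data_io import CommunityTable
from campart.phylo_binning import PhyloDistMatrix, cophenetic_distances

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_trait",
    "blomberg_k",
    "phylo_covariance",
    "mzsm_metacommunity",
    "assign_species_types",
    "selection_abundances",
    "competition_ranking",
    "simulate_dataset",
    "expected_importance",
    "generate_benchmark",
    "situation_mixes",
    "SCENARIO_K_TARGETS",
]

PLOTS = ("LA", "LB", "HA", "HB")
ISLAND = {"LA": "A", "HA": "A", "LB": "B", "HB": "B"}
ENVIRONMENT = {"LA": "L", "LB": "L", "HA": "H", "HB": "H"}

#: target Blomberg K per phylogenetic-signal scenario
SCENARIO_K_TARGETS = {"LPS": 0.15, "MPS": 0.9, "HPS": 5.5}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the simulator.

    The defaults are a desk-scale preset (regional pool J = 2e5 individuals,
    fundamental biodiversity number theta = 500, local communities of 2000
    individuals); :meth:`full_scale` returns the original-scale settings
    (J = 2e7, theta = 5000, locals of 20000 individuals).
    """

    n_tips: int = 1140
    J: int = 200_000
    theta: float = 500.0
    sigma_e: float = 0.015        # selection width in trait units
    m1: float = 0.01              # metacommunity immigration (dispersal sims)
    m2: float = 0.99              # island-pool immigration
    m_drift: float = 0.5          # immigration rate for drift sims
    local_size: int = 2000        # individuals per local community
    richness: int = 100           # species per local community
    replicates: int = 6           # local communities per plot
    ev_by_env: dict = field(default_factory=lambda: {"L": 0.05, "H": 0.95})
    ds: float = 0.2               # type-propagation phylogenetic radius
    competition_fraction: float = 0.0  # fraction of selection under competition
    lps_model: str = "ou"         # or "bm_noise"
    type_tolerance: float = 0.02  # allowed deviation of realized mix
    #: complex-bin robustness mode: assign process pools on a bin grid
    #: drawn from (complex_nmin_grid x complex_ds_grid) instead of the
    #: analysis grid, so analysis bins can mix governing processes
    complex_bins: bool = False
    complex_nmin_grid: tuple = (3, 6, 12, 24, 48)
    complex_ds_grid: tuple = (0.1, 0.2, 0.4)
    #: sd of per-sample log-fitness noise in the selection filter: a
    #: demographic lottery that rotates dominance among species of similar
    #: fitness (|E - EV| within ~ lottery^0.5 * sigma_e), so replicate
    #: communities under identical selection differ taxonomically while
    #: staying trait- (and with signal, phylogeny-) matched
    selection_lottery: float = 0.0

    @classmethod
    def full_scale(cls, **overrides) -> "SimulationConfig":
        base = dict(J=20_000_000, theta=5000.0, local_size=20_000)
        base.update(overrides)
        return cls(**base)


@dataclass
class SimulatedDataset:
    """One simulated situation: communities, tree, trait, ground truth."""

    table: CommunityTable
    tree: TreeNode
    trait: pd.Series
    types: pd.Series               # species -> process pool
    metacommunity: pd.Series
    expected: pd.DataFrame         # per pair: EP per process
    plot_map: dict                 # sample -> plot
    mix: dict                      # process pool -> abundance fraction
    scenario: str
    situation: str
    achieved_k: float

    @property
    def expected_stochasticity(self) -> pd.Series:
        return self.expected[["HD", "DL", "DR"]].sum(axis=1)


def _relabel_and_scale(newick: str) -> TreeNode:
    tree = TreeNode.read(io.StringIO(newick))
    # scale to unit root-to-tip depth
    depth = max(t.accumulate_to_ancestor(tree) for t in tree.tips())
    for node in tree.traverse(include_self=False):
        node.length = (node.length or 0.0) / depth
    return tree


def simulate_tree(n_tips: int = 1140, seed: int = 0,
                  shape: str = "equilibrium",
                  birth_rate: float = 1.0,
                  death_rate: float = 0.0) -> TreeNode:
    """Simulate an ultrametric phylogeny with ``n_tips`` extant species.

    ``shape='equilibrium'`` (default) draws a coalescent genealogy — the
    limit of a birth-death process at speciation-extinction equilibrium —
    whose node depths concentrate near the tips, as in lineages that have
    turned over for a long time.  ``shape='birth_death'`` runs a forward
    birth-death simulation with the given rates (death 0 gives a Yule
    tree).  Branch lengths are rescaled to unit root-to-tip depth and tips
    are named ``sp0001..``.
    """
    if shape == "equilibrium":
        import msprime

        ts = msprime.sim_ancestry(samples=n_tips, ploidy=1,
                                  population_size=1.0,
                                  random_seed=int(seed) % (2**31 - 2) + 1)
        newick = ts.first().as_newick()
        tree = _relabel_and_scale(newick)
        for i, leaf in enumerate(tree.tips()):
            leaf.name = f"sp{i + 1:04d}"
        return tree
    if shape != "birth_death":
        raise ValueError(f"unknown tree shape {shape!r}")
    from dendropy.simulate import treesim

    pyrng = random.Random(int(seed))
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_tips, rng=pyrng)
    dtree.seed_node.edge.length = 0.0
    # the simulation stops at the n-th speciation, so the youngest sibling
    # pair has zero-length branches; extend every tip by the waiting time
    # to the next event to keep tip ages equal and branch lengths positive
    extra = pyrng.expovariate(n_tips * (birth_rate + death_rate))
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:04d}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    return _relabel_and_scale(newick)


def _tree_arrays(tree: TreeNode):
    """Preorder node list with parent pointers, branch lengths, depths and
    tip indices (tips ordered as ``tree.tips()``)."""
    nodes = list(tree.preorder(include_self=True))
    index = {id(n): i for i, n in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    length = np.zeros(len(nodes))
    depth = np.zeros(len(nodes))
    for i, n in enumerate(nodes):
        if n.parent is not None:
            parent[i] = index[id(n.parent)]
            length[i] = n.length or 0.0
            depth[i] = depth[parent[i]] + length[i]
    tip_rows = [index[id(t)] for t in tree.tips()]
    tip_names = [t.name for t in tree.tips()]
    return nodes, parent, length, depth, tip_rows, tip_names


def phylo_covariance(tree: TreeNode):
    """Brownian-motion covariance matrix among tips (shared root-to-MRCA
    path lengths).  Returns (C, tip_names)."""
    nodes = list(tree.postorder(include_self=True))
    tip_names = [t.name for t in tree.tips()]
    tip_index = {name: i for i, name in enumerate(tip_names)}
    below = {}
    n = len(tip_names)
    C = np.zeros((n, n))
    for node in nodes:
        if node.is_tip():
            below[id(node)] = [tip_index[node.name]]
        else:
            acc = []
            for ch in node.children:
                acc.extend(below.pop(id(ch)))
            below[id(node)] = acc
        if node.parent is not None and node.length:
            idx = np.array(below[id(node)], dtype=np.intp)
            C[np.ix_(idx, idx)] += node.length
    return C, tip_names


def blomberg_k(tree: TreeNode, trait, cov=None) -> float:
    """Blomberg's K statistic of phylogenetic signal.

    The ratio of the observed mean squared error of tip values around the
    phylogenetically corrected mean to the phylogenetically expected MSE,
    scaled by its Brownian-motion expectation; K = 1 under Brownian
    evolution, K -> 0 for signal-free traits, K > 1 when variation is
    concentrated among deep clades.  Invariant to affine transforms of the
    trait.
    """
    from scipy.linalg import cho_factor, cho_solve

    if cov is None:
        C, tip_names = phylo_covariance(tree)
    else:
        C, tip_names = cov
    if isinstance(trait, pd.Series):
        x = trait.loc[tip_names].to_numpy(dtype=float)
    else:
        x = np.asarray(trait, dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("constant trait: K undefined")
    n = len(x)
    try:
        factor = cho_factor(C)
    except np.linalg.LinAlgError:
        # zero-length branches can make C numerically semidefinite
        factor = cho_factor(C + 1e-10 * np.trace(C) / n * np.eye(n))
    ones = np.ones(n)
    Ci1 = cho_solve(factor, ones)
    a_hat = float(x @ Ci1 / (ones @ Ci1))
    resid = x - a_hat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ cho_solve(factor, resid)) / (n - 1)
    expected = (np.trace(C) - n / float(ones @ Ci1)) / (n - 1)
    return (mse0 / mse) / expected


def _reflect01(x: np.ndarray) -> np.ndarray:
    """Reflect values into [0, 1] (folding at both boundaries)."""
    y = np.mod(x, 2.0)
    return np.where(y > 1.0, 2.0 - y, y)


def _evolve_bm(parent, length, depth, z, sigma2, root, rate_fn=None):
    """Trait values at all nodes under (possibly time-rescaled) Brownian
    motion with reflection at 0 and 1; ``z`` holds one standard normal per
    node."""
    x = np.empty(len(parent))
    for i in range(len(parent)):
        if parent[i] < 0:
            x[i] = root
            continue
        if rate_fn is None:
            var = sigma2 * length[i]
        else:
            var = sigma2 * rate_fn(depth[parent[i]], depth[i])
        x[i] = x[parent[i]] + z[i] * math.sqrt(max(var, 0.0))
    return _reflect01(x)


def _evolve_ou(parent, length, z, alpha, stat_var, root):
    """Ornstein-Uhlenbeck trait: mean reversion to 0.5 at rate ``alpha``
    with stationary variance ``stat_var``."""
    x = np.empty(len(parent))
    for i in range(len(parent)):
        if parent[i] < 0:
            x[i] = root
            continue
        e = math.exp(-alpha * length[i])
        var = stat_var * (1.0 - e * e)
        x[i] = 0.5 + (x[parent[i]] - 0.5) * e + z[i] * math.sqrt(max(var, 0.0))
    return _reflect01(x)


# generator calibration: decelerating-rate strength for the high-signal
# pool and stationary spread of the mean-reverting low-signal pool
_HPS_RATE_LOG = math.log(2000.0)
_HPS_SIGMA2 = 40.0
_MPS_SIGMA2 = 0.15
_OU_STAT_VAR = 0.14


def _simulate_trait_once(tree_arrays, scenario: str,
                         rng: np.random.Generator,
                         lps_model: str = "ou", cov=None, tree=None):
    nodes, parent, length, depth, tip_rows, tip_names = tree_arrays
    z = rng.standard_normal(len(parent))

    def k_of(x_nodes):
        tip = pd.Series(np.asarray(x_nodes)[tip_rows], index=tip_names)
        return tip, blomberg_k(tree, tip, cov=cov)

    if scenario == "MPS":
        return k_of(_evolve_bm(parent, length, depth, z, _MPS_SIGMA2, 0.5))
    if scenario == "HPS":
        # early-burst: instantaneous rate decays as g^(-t) over unit depth
        r = _HPS_RATE_LOG

        def seg(t0, t1):
            return (math.exp(-r * t0) - math.exp(-r * t1)) / r

        return k_of(_evolve_bm(parent, length, depth, z, _HPS_SIGMA2, 0.5,
                               rate_fn=seg))
    if scenario == "LPS":
        target = SCENARIO_K_TARGETS["LPS"]
        if lps_model == "ou":
            lo, hi = 0.5, 400.0

            def k_at(alpha):
                return k_of(_evolve_ou(parent, length, z, alpha,
                                       _OU_STAT_VAR, 0.5))

            # K decreases with the reversion rate; bisect to the target
            for _ in range(40):
                mid = math.sqrt(lo * hi)
                tip, k = k_at(mid)
                if abs(k - target) < 0.005:
                    return tip, k
                if k > target:
                    lo = mid
                else:
                    hi = mid
            return tip, k
        if lps_model == "bm_noise":
            base = _evolve_bm(parent, length, depth, z, _MPS_SIGMA2, 0.5)
            noise = rng.standard_normal(len(tip_rows))
            x0 = np.asarray(base)[tip_rows]
            lo, hi = 0.0, 5.0
            for _ in range(40):
                mid = (lo + hi) / 2.0
                tip = pd.Series(_reflect01(x0 + mid * noise),
                                index=tip_names)
                k = blomberg_k(tree, tip, cov=cov)
                if abs(k - target) < 0.005:
                    return tip, k
                if k > target:
                    lo = mid
                else:
                    hi = mid
            return tip, k
        raise ValueError(f"unknown lps_model {lps_model!r}")
    raise ValueError(f"unknown scenario {scenario!r}")


def simulate_trait(tree: TreeNode, scenario: str, seed: int = 0,
                   lps_model: str = "ou", max_attempts: int = 20,
                   optima=(0.05, 0.95), min_adapted: int | None = None):
    """Simulate the niche-optimum trait E_i in [0, 1] for one scenario.

    Returns ``(trait, achieved_K)``.  Attempts are repeated (new seed
    stream) until the achieved Blomberg K lies within +/-50% of the
    scenario target and the pool holds at least ``min_adapted`` species
    within 0.05 trait units of every environmental optimum (otherwise
    selection situations would be unrealizable); raises after
    ``max_attempts`` failures.
    """
    target = SCENARIO_K_TARGETS[scenario]
    arrays = _tree_arrays(tree)
    if min_adapted is None:
        # ~2.6% of the pool per optimum (30 species of the default 1140)
        min_adapted = max(5, round(0.026 * len(arrays[4])))
    cov = phylo_covariance(tree)
    rng = np.random.default_rng(seed)
    last_k = None
    for _ in range(max_attempts):
        trait, k = _simulate_trait_once(arrays, scenario, rng,
                                        lps_model=lps_model, cov=cov,
                                        tree=tree)
        last_k = k
        vals = trait.to_numpy()
        adapted = all(np.sum(np.abs(vals - ev) < 0.05) >= min_adapted
                      for ev in optima)
        if 0.5 * target <= k <= 1.5 * target and adapted:
            return trait, k
    raise RuntimeError(
        f"failed to reach K within 50% of {target} with an adequate pool "
        f"after {max_attempts} attempts (last K = {last_k:.3f})")


def mzsm_metacommunity(taxa, J: int, theta: float, seed: int = 0) -> pd.Series:
    """Relative metacommunity abundances from the metacommunity zero-sum
    multinomial species-abundance distribution.

    Each species' abundance is an independent draw from the mZSM law
    ``phi(n) ~ (theta/n) (1 - n/J)^(theta - 1)`` for 1 <= n < J; the draws
    are normalized and assigned to the provided taxa in random order.
    """
    if isinstance(taxa, TreeNode):
        taxa = [t.name for t in taxa.tips()]
    taxa = list(taxa)
    rng = np.random.default_rng(seed)
    # truncate the tail where the survival factor underflows
    scale = J / max(theta - 1.0, 1.0)
    n_max = min(J - 1, int(np.ceil(700.0 * scale)))
    n = np.arange(1, n_max + 1, dtype=float)
    logp = np.log(theta) - np.log(n) + (theta - 1.0) * np.log1p(-n / J)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    counts = rng.choice(n, size=len(taxa), p=p)
    order = rng.permutation(len(taxa))
    rel = counts[order] / counts.sum()
    return pd.Series(rel, index=taxa, name="metacommunity")


def assign_species_types(pool: pd.Series, dist: PhyloDistMatrix, mix: dict,
                         ds: float = 0.2, seed: int = 0,
                         tolerance: float = 0.02,
                         max_attempts: int = 200,
                         bins=None, unit: str = "bin",
                         trait: pd.Series | None = None,
                         optima=(0.05, 0.95), adapted_radius: float = 0.05,
                         min_adapted: int = 5) -> pd.Series:
    """Assign species to selection / dispersal / drift pools.

    ``mix`` maps process pools to target relative-abundance fractions
    (summing to 1).  Assignment respects trait conservatism: with
    ``unit='bin'`` (default) whole phylogenetic bins are allocated to one
    pool each (so closely related species always share a pool); with
    ``unit='species'`` a species assigned to selection or dispersal drags
    its unassigned relatives within ``ds`` along.  Drift takes the
    remainder.

    When ``trait`` is given, the selection pool must contain at least
    ``min_adapted`` species within ``adapted_radius`` of every
    environmental optimum — otherwise a selection regime would act on
    lineages with no adapted members and be unrealizable; assignments are
    retried until both this and the abundance tolerance hold (the
    best-covering assignment is kept as a fallback).
    """
    taxa = list(pool.index)
    if list(dist.taxa_ids) != taxa:
        dist = dist.subset(taxa)
    ab = pool.to_numpy(dtype=float)
    ab = ab / ab.sum()
    n = len(taxa)
    targets = {t: float(mix.get(t, 0.0)) for t in
               ("selection", "dispersal", "drift")}
    if not np.isclose(sum(targets.values()), 1.0):
        raise ValueError("mix fractions must sum to 1")
    if unit == "bin":
        if bins is None:
            raise ValueError("unit='bin' needs a BinSet")
        groups_all = [bins.members(k) for k in range(bins.n_bins)]
    elif unit != "species":
        raise ValueError(f"unknown unit {unit!r}")
    trait_v = None
    if trait is not None:
        trait_v = trait.loc[taxa].to_numpy(dtype=float)

    def adapted_counts(mask):
        if trait_v is None:
            return None
        return [int(np.sum(np.abs(trait_v[mask] - ev) < adapted_radius))
                for ev in optima]

    rng = np.random.default_rng(seed)
    best = None
    best_cov = -1
    for _ in range(max_attempts):
        assigned = np.full(n, "", dtype=object)
        realized = {"selection": 0.0, "dispersal": 0.0}
        for ptype in ("selection", "dispersal"):
            target = targets[ptype]
            if target <= 0:
                continue
            if unit == "bin":
                order = list(rng.permutation(len(groups_all)))
                if ptype == "selection" and trait_v is not None:
                    # visit, per optimum in turn, the lineages richest in
                    # members adapted to it, so the selection pool can
                    # respond to every environment; remaining picks random
                    per_opt = [np.array([
                        np.sum(np.abs(trait_v[np.asarray(g)] - ev)
                               < adapted_radius) for g in groups_all])
                        for ev in optima]
                    g_ab_all = np.array([ab[np.asarray(g)].sum()
                                         for g in groups_all])
                    front = []
                    # cheapest adequate lineage per optimum, scarcest
                    # optimum first, so coverage fits the abundance budget
                    for j in np.argsort([c.max() for c in per_opt]):
                        adequate = [int(x) for x in np.argsort(g_ab_all)
                                    if per_opt[j][x] >= min_adapted
                                    and x not in front]
                        if adequate:
                            front.append(adequate[0])
                    order = front + [x for x in order if x not in front]
            else:
                order = list(rng.permutation(n))
            for gi in order:
                if realized[ptype] >= target - tolerance / 2:
                    break
                if unit == "bin":
                    group = np.asarray(groups_all[gi])
                    if assigned[group[0]]:
                        continue
                else:
                    if assigned[gi]:
                        continue
                    group = np.flatnonzero((assigned == "")
                                           & (dist.data[gi] < ds))
                g_ab = ab[group].sum()
                if realized[ptype] + g_ab <= target + tolerance:
                    assigned[group] = ptype
                    realized[ptype] += g_ab
        assigned[assigned == ""] = "drift"
        realized["drift"] = ab[assigned == "drift"].sum()
        frac_ok = all(abs(realized.get(t, 0.0) - targets[t]) <= tolerance
                      for t in targets)
        cover_ok = True
        cov_score = 0
        if trait_v is not None and targets["selection"] > 0:
            counts = adapted_counts(assigned == "selection")
            cov_score = min(counts)
            cover_ok = cov_score >= min_adapted
        if frac_ok and cover_ok:
            return pd.Series(assigned, index=taxa, name="type")
        if frac_ok and cov_score > best_cov:
            best, best_cov = assigned.copy(), cov_score
    if best is not None:
        warnings.warn("selection pool covers the environmental optima only "
                      f"partially (min adapted members = {best_cov})")
        return pd.Series(best, index=taxa, name="type")
    if unit == "bin" or ds > 1e-9:
        # the current grouping is too coarse for the requested fractions;
        # relax to species-level assignment, then shrink the trait-
        # conservatism radius until the mix becomes reachable
        next_ds = ds if unit == "bin" else (ds / 2 if ds > 0.01 else 0.0)
        warnings.warn("assignment granularity too coarse for the mix; "
                      f"retrying at species level (radius {next_ds:g})")
        return assign_species_types(pool, dist, mix, ds=next_ds, seed=seed,
                                    tolerance=tolerance,
                                    max_attempts=max_attempts,
                                    unit="species", trait=trait,
                                    optima=optima,
                                    adapted_radius=adapted_radius,
                                    min_adapted=min_adapted)
    raise RuntimeError("could not match the requested process mix within "
                       f"{tolerance:.0%}")


def selection_abundances(ev: float, trait, sigma_e: float) -> np.ndarray:
    """Gaussian environmental-filtering weights
    ``exp(-(EV - E_i)^2 / (2 sigma_E^2))`` normalized to sum to 1."""
    e = np.asarray(trait, dtype=float)
    w = np.exp(-((ev - e) ** 2) / (2.0 * sigma_e ** 2))
    tot = w.sum()
    if tot == 0:
        w = np.full_like(e, 1.0 / len(e))
    else:
        w = w / tot
    return w


def competition_ranking(ev: float, trait, candidates, seed: int = 0,
                        n_rank: int | None = None):
    """Rank competitors by iterated niche difference; geometric abundances.

    The strongest competitor is drawn at random from the 10 candidates with
    trait closest to the environment; each further rank h maximises
    ``nd_hi = sqrt(sum_j 0.5^j (E_i - E_j)^2)`` over prior competitors j.
    Returns (ranked candidate list, weights proportional to 0.5^h).
    """
    candidates = list(candidates)
    e = {c: float(trait[c]) for c in candidates}
    if n_rank is None:
        n_rank = len(candidates)
    n_rank = min(n_rank, len(candidates))
    rng = np.random.default_rng(seed)
    fit_order = sorted(candidates, key=lambda c: (abs(ev - e[c]), c))
    first = fit_order[int(rng.integers(min(10, len(fit_order))))]
    ranked = [first]
    remaining = [c for c in candidates if c != first]
    while len(ranked) < n_rank and remaining:
        def nd(c):
            return math.sqrt(sum(0.5 ** (j + 1) * (e[c] - e[r]) ** 2
                                 for j, r in enumerate(ranked)))
        best = max(remaining, key=lambda c: (nd(c), c))
        ranked.append(best)
        remaining.remove(best)
    weights = np.array([0.5 ** (h + 1) for h in range(len(ranked))])
    return ranked, weights / weights.sum()


def _draw_part(rng, species_idx, log_weights, n_species, n_individuals):
    """Draw ``n_species`` distinct species by weight and give them
    ``n_individuals`` in total (each at least one individual).

    Weighted sampling without replacement is done on log weights with the
    Gumbel top-k device, so that astronomically small weights (e.g. a
    Gaussian filter many standard deviations from the optimum) still rank
    species correctly instead of underflowing to a uniform draw.
    """
    lw = np.asarray(log_weights, dtype=float)
    lw = np.where(np.isfinite(lw), lw, -1e12)
    n_species = min(n_species, len(species_idx), n_individuals)
    keys = lw + rng.gumbel(size=len(lw))
    chosen = np.argpartition(-keys, n_species - 1)[:n_species]
    wc = np.exp(lw[chosen] - lw[chosen].max()) + 1e-300
    wc /= wc.sum()
    counts = 1 + rng.multinomial(n_individuals - n_species, wc)
    return np.asarray(species_idx)[chosen], counts


def _draw_selection(rng, idx_sel, lineages, trait_all, ev, sigma_e,
                    n_species, n_individuals, lottery: float = 0.0):
    """Lineage-structured environmental filtering.

    Selection acts within every phylogenetic lineage: the community's
    selection richness is spread over lineages in proportion to their share
    of the selection pool, the members occurring within a lineage are drawn
    by Gaussian fitness rank for the local environment (Gumbel top-k on log
    weights), and individuals are then allocated by the same Gaussian
    fitness across all drawn members — so the best-adapted lineages
    dominate abundance while every lineage remains represented by its
    best-adapted members.
    """
    if not lineages:
        lineages = [np.asarray(idx_sel)]
    tot = sum(len(m) for m in lineages)
    shares = {i: len(m) / tot for i, m in enumerate(lineages)}
    alloc = _split_counts(min(n_species, n_individuals), shares)

    def log_gauss(members):
        return -((ev - trait_all[members]) ** 2) / (2.0 * sigma_e ** 2)

    drawn_parts, logw_parts = [], []
    leftover = 0
    for i, m in enumerate(lineages):
        k_slots = min(alloc.get(i, 0), len(m))
        leftover += alloc.get(i, 0) - k_slots
        if k_slots == 0:
            continue
        lg = log_gauss(m)
        keys = lg + rng.gumbel(size=len(m)) * max(lottery, 1.0)
        part = m[np.argpartition(-keys, k_slots - 1)[:k_slots]]
        # lineage fitness (hence its abundance share) is deterministic;
        # the lottery only rotates which of its similarly fit members
        # carry that abundance, so rotation stays phylogenetically local
        lg_true = log_gauss(part)
        lin_logw = np.logaddexp.reduce(lg_true)
        within = lg_true + (rng.gumbel(size=len(part)) * lottery
                            if lottery > 0 else 0.0)
        within = within - np.logaddexp.reduce(within)
        drawn_parts.append(part)
        logw_parts.append(lin_logw + within)
    drawn = np.concatenate(drawn_parts)
    logw = np.concatenate(logw_parts)
    if leftover:
        rest = np.setdiff1d(np.asarray(idx_sel), drawn)
        if len(rest):
            lg = log_gauss(rest)
            keys = lg + rng.gumbel(size=len(rest)) * max(lottery, 1.0)
            k = min(leftover, len(rest))
            extra = rest[np.argpartition(-keys, k - 1)[:k]]
            drawn = np.concatenate([drawn, extra])
            logw = np.concatenate([logw, log_gauss(extra)])
    w = np.exp(logw - logw.max()) + 1e-300
    w /= w.sum()
    counts = 1 + rng.multinomial(n_individuals - len(drawn), w)
    return drawn, counts


def _split_counts(total: int, fractions: dict) -> dict:
    """Integer allocation of ``total`` proportional to fractions."""
    keys = [k for k, f in fractions.items() if f > 0]
    raw = {k: fractions[k] * total for k in keys}
    out = {k: int(np.floor(raw[k])) for k in keys}
    rem = total - sum(out.values())
    for k in sorted(keys, key=lambda k: raw[k] - out[k], reverse=True):
        if rem <= 0:
            break
        out[k] += 1
        rem -= 1
    return out


def simulate_dataset(tree: TreeNode, trait: pd.Series,
                     metacommunity: pd.Series, mix: dict,
                     config: SimulationConfig, seed: int = 0,
                     scenario: str = "", situation: str = "",
                     achieved_k: float = np.nan,
                     dist: PhyloDistMatrix | None = None,
                     types: pd.Series | None = None,
                     bins=None, type_nmin: int = 24) -> SimulatedDataset:
    """Assemble the 24 local communities of one situation.

    ``mix`` maps 'selection' / 'dispersal' / 'drift' to abundance
    fractions.  Each local community holds exactly ``config.local_size``
    individuals of ``config.richness`` species, split across the process
    pools in proportion to the mix.
    """
    rng = np.random.default_rng(seed)
    taxa = list(metacommunity.index)
    if dist is None:
        dist = cophenetic_distances(tree)
    if list(dist.taxa_ids) != taxa:
        dist = dist.subset(taxa)
    lineage_bins = bins
    if types is None:
        from campart.phylo_binning import bin_by_tree
        type_bins = bins
        type_ds = config.ds
        if config.complex_bins:
            # deliberately mismatched grid: the analysis still bins at its
            # own (ds, nmin), so estimated bins can hold members governed
            # by different processes
            type_ds = float(rng.choice(config.complex_ds_grid))
            grid_nmin = int(rng.choice(config.complex_nmin_grid))
            type_bins = bin_by_tree(tree, type_ds, grid_nmin, dist=dist)
        elif type_bins is None:
            type_bins = bin_by_tree(tree, config.ds, type_nmin, dist=dist)
        types = assign_species_types(
            metacommunity, dist, mix, ds=type_ds,
            seed=int(rng.integers(2**31 - 1)),
            tolerance=config.type_tolerance, bins=type_bins, unit="bin",
            trait=trait,
            optima=tuple(sorted(set(config.ev_by_env.values()))))
        lineage_bins = type_bins
    trait = trait.loc[taxa]
    type_arr = types.loc[taxa].to_numpy()
    meta = metacommunity.to_numpy(dtype=float)
    meta = meta / meta.sum()

    idx_sel = np.flatnonzero(type_arr == "selection")
    idx_comp = np.array([], dtype=int)
    if config.competition_fraction > 0 and len(idx_sel):
        k = int(round(len(idx_sel) * config.competition_fraction))
        pick = rng.choice(len(idx_sel), size=k, replace=False)
        idx_comp = idx_sel[pick]
        idx_sel = np.setdiff1d(idx_sel, idx_comp)
    idx_disp = np.flatnonzero(type_arr == "dispersal")
    idx_drift = np.flatnonzero(type_arr == "drift")

    # lineages over which the selection part is structured (the same
    # grouping the process pools were assigned on)
    sel_lineages = []
    if lineage_bins is not None and len(idx_sel):
        sel_set = set(idx_sel.tolist())
        for k in range(lineage_bins.n_bins):
            m = np.array([i for i in lineage_bins.members(k)
                          if i in sel_set], dtype=int)
            if len(m):
                sel_lineages.append(m)

    # island-unique dispersal pools (disjoint species sets)
    pool_rel = {}
    if len(idx_disp):
        p_d = meta[idx_disp] / meta[idx_disp].sum()
        r_disp = _split_counts(config.richness, mix).get("dispersal", 0)
        n_pool = min(len(idx_disp) // 2, max(2 * r_disp, r_disp))
        order = np.arange(len(idx_disp))
        chosen_a = rng.choice(order, size=n_pool, replace=False, p=p_d)
        rest = np.setdiff1d(order, chosen_a)
        p_rest = p_d[rest] / p_d[rest].sum()
        chosen_b = rest[rng.choice(len(rest), size=min(n_pool, len(rest)),
                                   replace=False, p=p_rest)]
        for name, chosen in (("A", chosen_a), ("B", chosen_b)):
            alpha = config.m1 * config.local_size * \
                (p_d[chosen] / p_d[chosen].sum())
            pool = rng.dirichlet(np.maximum(alpha, 1e-6))
            full = np.zeros(len(idx_disp))
            full[chosen] = pool
            # locals immigrate mostly from the island pool, a little from
            # the regional metacommunity
            pool_rel[name] = config.m2 * full + config.m1 * p_d

    frac_by_type = {t: f for t, f in mix.items() if f > 0}
    if config.competition_fraction > 0 and "selection" in frac_by_type:
        fsel = frac_by_type.pop("selection")
        frac_by_type["selection"] = fsel * (1 - config.competition_fraction)
        frac_by_type["competition"] = fsel * config.competition_fraction
        frac_by_type = {t: f for t, f in frac_by_type.items() if f > 0}

    sample_ids, plot_map = [], {}
    columns = {}
    for plot in PLOTS:
        ev = config.ev_by_env[ENVIRONMENT[plot]]
        island = ISLAND[plot]
        for rep in range(config.replicates):
            sid = f"{plot}{rep + 1}"
            sample_ids.append(sid)
            plot_map[sid] = plot
            rich = _split_counts(config.richness, frac_by_type)
            size = _split_counts(config.local_size, frac_by_type)
            col = np.zeros(len(taxa))
            if rich.get("selection"):
                sp, ct = _draw_selection(rng, idx_sel, sel_lineages,
                                         trait.to_numpy(), ev,
                                         config.sigma_e, rich["selection"],
                                         size["selection"],
                                         lottery=config.selection_lottery)
                col[sp] += ct
            if rich.get("competition"):
                cand = [taxa[i] for i in idx_comp]
                ranked, wgt = competition_ranking(
                    ev, trait, cand, seed=int(rng.integers(2**31 - 1)),
                    n_rank=rich["competition"])
                ridx = np.array([taxa.index(c) for c in ranked])
                sp, ct = _draw_part(rng, ridx, np.log(wgt), len(ridx),
                                    size["competition"])
                col[sp] += ct
            if rich.get("dispersal"):
                q = pool_rel[island]
                sp, ct = _draw_part(rng, idx_disp, np.log(q + 1e-300),
                                    rich["dispersal"], size["dispersal"])
                col[sp] += ct
            if rich.get("drift"):
                p_r = meta[idx_drift] / meta[idx_drift].sum()
                alpha = (config.local_size * config.m_drift
                         / (1.0 - config.m_drift)) * p_r
                q = rng.dirichlet(np.maximum(alpha, 1e-6))
                sp, ct = _draw_part(rng, idx_drift, np.log(q + 1e-300),
                                    rich["drift"], size["drift"])
                col[sp] += ct
            columns[sid] = col

    # keep every regional-pool species as a table row (zeros where never
    # sampled): the pool is the null-model reference for the analysis
    mat = np.column_stack([columns[s] for s in sample_ids])
    table = CommunityTable(list(taxa), sample_ids, mat)
    ds_obj = SimulatedDataset(
        table=table, tree=tree, trait=trait, types=types,
        metacommunity=metacommunity, expected=None, plot_map=plot_map,
        mix=dict(mix), scenario=scenario, situation=situation,
        achieved_k=achieved_k)
    ds_obj.expected = expected_importance(ds_obj)
    return ds_obj


def pair_geometry(plot_u: str, plot_v: str) -> str:
    """Geometry class of a sample pair, from its plots."""
    same_env = ENVIRONMENT[plot_u] == ENVIRONMENT[plot_v]
    same_isl = ISLAND[plot_u] == ISLAND[plot_v]
    if plot_u == plot_v:
        return "within_plot"
    if same_isl:
        return "same_island"
    if same_env:
        return "same_environment"
    return "different"


def expected_importance(dataset: SimulatedDataset) -> pd.DataFrame:
    """Expected relative importance of each process for every sample pair.

    Species governed by selection contribute to homogeneous selection
    within one environment and heterogeneous selection across environments;
    dispersal species to homogenizing dispersal within an island and
    dispersal limitation across islands; drift species to 'drift';
    competition species (when simulated) to a combined 'SEL' column.
    Weights are the pair-mean relative abundances, so rows sum to 1.
    """
    table = dataset.table
    rel = table.abundance / table.abundance.sum(axis=0)
    type_arr = dataset.types.loc[table.taxa_ids].to_numpy()
    n = table.n_samples
    cols = ["HeS", "HoS", "DL", "HD", "DR"]
    has_comp = bool((type_arr == "competition").any())
    if has_comp:
        cols = cols + ["SEL"]
    masks = {
        "selection": type_arr == "selection",
        "dispersal": type_arr == "dispersal",
        "drift": type_arr == "drift",
        "competition": type_arr == "competition",
    }
    rows = []
    index = []
    for u in range(n):
        for v in range(u + 1, n):
            su, sv = table.sample_ids[u], table.sample_ids[v]
            w = (rel[:, u] + rel[:, v]) / 2.0
            pu, pv = dataset.plot_map[su], dataset.plot_map[sv]
            same_env = ENVIRONMENT[pu] == ENVIRONMENT[pv]
            same_isl = ISLAND[pu] == ISLAND[pv]
            ep = dict.fromkeys(cols, 0.0)
            ep["HoS" if same_env else "HeS"] = w[masks["selection"]].sum()
            ep["HD" if same_isl else "DL"] = w[masks["dispersal"]].sum()
            ep["DR"] = w[masks["drift"]].sum()
            if has_comp:
                ep["SEL"] = w[masks["competition"]].sum()
            ep["geometry"] = pair_geometry(pu, pv)
            rows.append(ep)
            index.append(f"{su}|{sv}")
    out = pd.DataFrame(rows, index=index)
    out.index.name = "pair"
    return out


def situation_mixes(step: float = 0.25):
    """All (selection, dispersal, drift) compositions on the given grid."""
    levels = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    mixes = []
    for s in levels:
        for d in levels:
            r = round(1.0 - s - d, 10)
            if 0.0 <= r <= 1.0:
                mixes.append({"selection": float(s), "dispersal": float(d),
                              "drift": float(r)})
    return mixes


def _situation_name(mix: dict) -> str:
    return "s{:02.0f}_d{:02.0f}_r{:02.0f}".format(
        100 * mix["selection"], 100 * mix["dispersal"], 100 * mix["drift"])


def generate_benchmark(scenario: str, seed: int = 0,
                       config: SimulationConfig | None = None,
                       tree: TreeNode | None = None,
                       trait: pd.Series | None = None,
                       achieved_k: float = np.nan):
    """Generate the 15 benchmark situations of one phylogenetic-signal
    scenario (process mixes on a 25% grid).  Returns a list of
    :class:`SimulatedDataset`."""
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(20) % (2**31 - 1)
    if tree is None:
        tree = simulate_tree(config.n_tips, seed=int(seeds[0]))
    if trait is None:
        trait, achieved_k = simulate_trait(tree, scenario,
                                           seed=int(seeds[1]),
                                           lps_model=config.lps_model)
    meta = mzsm_metacommunity(tree, config.J, config.theta,
                              seed=int(seeds[2]))
    dist = cophenetic_distances(tree)
    from campart.phylo_binning import bin_by_tree
    bins = bin_by_tree(tree, config.ds, 24, dist=dist)
    datasets = []
    for i, mix in enumerate(situation_mixes()):
        datasets.append(simulate_dataset(
            tree, trait, meta, mix, config, seed=int(seeds[3 + i]),
            scenario=scenario, situation=_situation_name(mix),
            achieved_k=achieved_k, dist=dist, bins=bins))
    return datasets
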