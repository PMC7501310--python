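"""Beta-diversity metrics and their null distributions within bins.

Selection is read off the phylogenetic turnover of a bin: the observed
abundance-weighted beta mean pairwise distance (betaMPD) is standardised
against a 'taxa shuffle' null that permutes taxa across tree tips, giving
the beta net relatedness index (betaNRI).  Dispersal and drift are read off
taxonomic turnover: the observed Bray-Curtis dissimilarity is ranked within
a richness- and occupancy-constrained null, giving the modified Raup-Crick
metric (RC) in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from campart.data_io import CommunityTable
from campart.phylo_binning import BinSet, PhyloDistMatrix

__all__ = [
    "NullEnsemble",
    "beta_mpd",
    "bray_curtis",
    "taxa_shuffle",
    "taxonomic_null",
    "beta_nri",
    "rc_metric",
    "direct_significance",
    "pair_bin_metrics",
]

#: default number of null-model randomizations
DEFAULT_RANDOMIZATIONS = 1000


@dataclass
class NullEnsemble:
    """An observed metric value together with its null distribution."""

    metric: str
    observed: float
    nulls: np.ndarray

    def __post_init__(self):
        self.nulls = np.asarray(self.nulls, dtype=float)

    @property
    def n_rand(self) -> int:
        return len(self.nulls)

    @property
    def null_mean(self) -> float:
        return float(self.nulls.mean())

    @property
    def null_sd(self) -> float:
        return float(self.nulls.std(ddof=0))


def beta_mpd(f_u, f_v, d) -> float:
    """Abundance-weighted beta mean pairwise phylogenetic distance.

    ``sum_ij f_iu f_jv d_ij / sum_ij f_iu f_jv`` over the taxa of one bin;
    the ratio is invariant to uniform rescaling of either abundance vector.
    """
    f_u = np.asarray(f_u, dtype=float)
    f_v = np.asarray(f_v, dtype=float)
    d = np.asarray(d, dtype=float)
    denom = f_u.sum() * f_v.sum()
    if denom == 0:
        raise ValueError("bin absent from at least one community: "
                         "betaMPD undefined")
    return float(f_u @ d @ f_v / denom)


def bray_curtis(x_u, x_v) -> float:
    """Bray-Curtis dissimilarity ``sum|x_u - x_v| / sum(x_u + x_v)``."""
    x_u = np.asarray(x_u, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    tot = (x_u + x_v).sum()
    if tot == 0:
        raise ValueError("both abundance vectors are all-zero")
    return float(np.abs(x_u - x_v).sum() / tot)


def taxa_shuffle(dist: PhyloDistMatrix, bins: BinSet | None = None,
                 scope: str = "across_all", seed: int = 0,
                 rng: np.random.Generator | None = None) -> PhyloDistMatrix:
    """Randomize taxa across tree tips by permuting distance-matrix labels.

    ``scope='across_all'`` permutes all taxa; ``'within_bin'`` permutes taxa
    only among members of their own bin (requires ``bins``).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(dist.taxa_ids)
    if scope == "across_all":
        perm = rng.permutation(n)
    elif scope == "within_bin":
        if bins is None:
            raise ValueError("within_bin shuffle requires a BinSet")
        perm = np.arange(n)
        for k in range(bins.n_bins):
            idx = bins.members(k)
            perm[idx] = idx[rng.permutation(len(idx))]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return PhyloDistMatrix(dist.taxa_ids, dist.data[np.ix_(perm, perm)])


def _null_counts(counts: np.ndarray, occ_prob: np.ndarray,
                 fill_w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One taxonomic-null realization of a count matrix.

    Per sample: draw exactly the observed richness of taxa without
    replacement (selection probability proportional to occurrence
    frequency), then give each drawn taxon one individual and distribute
    the remaining total multinomially with the fill weights, so richness
    and totals are preserved exactly.
    """
    n_taxa, n_samp = counts.shape
    out = np.zeros_like(counts)
    for j in range(n_samp):
        richness = int((counts[:, j] > 0).sum())
        total = int(round(counts[:, j].sum()))
        chosen = rng.choice(n_taxa, size=richness, replace=False, p=occ_prob)
        w = fill_w[chosen]
        w = w / w.sum()
        out[chosen, j] = 1 + rng.multinomial(total - richness, w)
    return out


def taxonomic_null(table: CommunityTable, seed: int = 0,
                   weights: str = "mean_ra",
                   rng: np.random.Generator | None = None) -> CommunityTable:
    """Richness- and occupancy-constrained null community table.

    Taxon occurrence probability is proportional to its observed occurrence
    frequency across samples; abundances are filled multinomially with
    weights proportional to each taxon's mean relative abundance
    (``weights='equal'`` for uniform fill).  Requires integer counts.
    """
    counts = table.abundance
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("taxonomic null requires integer counts")
    counts = np.round(counts)
    if rng is None:
        rng = np.random.default_rng(seed)
    occ = (counts > 0).sum(axis=1).astype(float)
    occ_prob = occ / occ.sum()
    if weights == "mean_ra":
        fill = (counts / counts.sum(axis=0)).mean(axis=1)
    elif weights == "equal":
        fill = np.ones(table.n_taxa)
    else:
        raise ValueError(f"unknown weights {weights!r}")
    max_rich = int((counts > 0).any(axis=1).sum())
    if np.any((counts > 0).sum(axis=0) > max_rich):
        raise ValueError("sample richness exceeds taxa with nonzero "
                         "occurrence")
    out = _null_counts(counts, occ_prob, fill, rng)
    return CommunityTable(table.taxa_ids, table.sample_ids,
                          out.astype(float))


def beta_nri(ensemble: NullEnsemble) -> float:
    """Standard effect size (observed - null mean) / null sd; 0 when the
    null distribution is degenerate (with a warning)."""
    sd = ensemble.null_sd
    if sd == 0:
        warnings.warn("null standard deviation is zero: betaNRI set to 0 "
                      "(treated as non-significant)")
        return 0.0
    return (ensemble.observed - ensemble.null_mean) / sd


def rc_metric(ensemble: NullEnsemble, equal_tol: float = 1e-9) -> float:
    """Modified Raup-Crick metric in [-1, 1].

    ``2 * sum(delta) / N_r - 1`` where delta is 1 when a null value falls
    below the observed, 0.5 when equal (within ``equal_tol``), 0 otherwise.
    """
    if ensemble.n_rand == 0:
        raise ValueError("empty null ensemble")
    diff = ensemble.observed - ensemble.nulls
    delta = np.where(diff > equal_tol, 1.0,
                     np.where(diff < -equal_tol, 0.0, 0.5))
    return float(2.0 * delta.sum() / ensemble.n_rand - 1.0)


def direct_significance(ensemble: NullEnsemble,
                        alpha: float = 0.05) -> str:
    """Two-sided empirical-quantile test against the null distribution.

    Returns 'high' when the observed value exceeds the (1 - alpha/2)
    empirical quantile of the nulls, 'low' when it falls below the alpha/2
    quantile, otherwise 'ns'.  The default alpha of 0.05 mirrors the
    +/-1.96 standard-effect-size threshold for a Gaussian null.
    """
    if ensemble.n_rand < 2.0 / alpha:
        warnings.warn("few randomizations: empirical quantiles unstable")
    lo = np.quantile(ensemble.nulls, alpha / 2.0)
    hi = np.quantile(ensemble.nulls, 1.0 - alpha / 2.0)
    if ensemble.observed > hi:
        return "high"
    if ensemble.observed < lo:
        return "low"
    return "ns"


def _pair_index(n: int):
    iu = np.triu_indices(n, k=1)
    return iu


def _bin_beta_mpd_all_pairs(B: np.ndarray, d: np.ndarray,
                            present: np.ndarray) -> np.ndarray:
    """betaMPD for all sample pairs of one bin.

    ``B`` is the within-bin-normalised abundance matrix (taxa x samples,
    columns that have the bin sum to 1), ``present`` flags columns where the
    bin occurs.  Returns a condensed vector with NaN where the bin is absent
    from either sample.
    """
    M = B.T @ d @ B
    iu = _pair_index(B.shape[1])
    vals = M[iu]
    ok = present[iu[0]] & present[iu[1]]
    return np.where(ok, vals, np.nan)


def _bin_bray_curtis_all_pairs(X: np.ndarray,
                               present: np.ndarray) -> np.ndarray:
    """Bin-restricted Bray-Curtis for all sample pairs (condensed), NaN
    where the bin is absent from both samples (one-sided absence gives a
    well-defined dissimilarity of 1)."""
    with np.errstate(invalid="ignore"):
        bc = pdist(X.T, metric="braycurtis")
    iu = _pair_index(X.shape[1])
    ok = present[iu[0]] | present[iu[1]]
    return np.where(ok, np.nan_to_num(bc, nan=1.0), np.nan)


def pair_bin_metrics(table: CommunityTable, dist: PhyloDistMatrix,
                     bins: BinSet, n_rand: int = DEFAULT_RANDOMIZATIONS,
                     seed: int = 0, phylo_scope: str = "within_bin",
                     taxo_weights: str = "mean_ra",
                     equal_tol: float = 1e-9,
                     alpha: float = 0.05) -> pd.DataFrame:
    """betaMPD, betaNRI, Bray-Curtis and RC for every (sample pair, bin).

    The phylogenetic null shuffles taxa across tips (within each bin by
    default; ``phylo_scope='across_all'`` for a whole-tree shuffle) and the
    taxonomic null re-draws whole communities under the richness/occupancy
    constraints; metrics are always evaluated within bins.  Pair-bins where
    the bin is absent from either sample are flagged ``excluded`` and carry
    NaN metrics.

    Returns a long-format DataFrame with one row per (pair, bin).
    """
    if table.taxa_ids != dist.taxa_ids or table.taxa_ids != bins.taxa_ids:
        raise ValueError("table, distances and bins must share taxon order")
    counts = table.abundance
    rel = counts / counts.sum(axis=0)
    n_samp = table.n_samples
    iu = _pair_index(n_samp)
    n_pairs = len(iu[0])
    rng = np.random.default_rng(seed)
    rng_phylo = np.random.default_rng(rng.integers(2**31 - 1))
    rng_taxo = np.random.default_rng(rng.integers(2**31 - 1))

    K = bins.n_bins
    member_idx = [bins.members(k) for k in range(K)]
    # within-bin normalised observed abundances and presence masks
    B_obs, X_obs, present = [], [], []
    for k in range(K):
        X = rel[member_idx[k]]
        tot = X.sum(axis=0)
        pres = tot > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            B = np.where(pres, X / np.where(pres, tot, 1.0), 0.0)
        B_obs.append(B)
        X_obs.append(X)
        present.append(pres)

    obs_bmpd = np.empty((K, n_pairs))
    obs_bc = np.empty((K, n_pairs))
    for k in range(K):
        d_k = dist.data[np.ix_(member_idx[k], member_idx[k])]
        obs_bmpd[k] = _bin_beta_mpd_all_pairs(B_obs[k], d_k, present[k])
        obs_bc[k] = _bin_bray_curtis_all_pairs(X_obs[k], present[k])

    # phylogenetic null: accumulate the full null ensemble of betaMPD
    # (falls back to moments + a Gaussian tail when too large to store)
    store_nulls = n_rand * K * n_pairs <= 2e8
    if store_nulls:
        nulls = np.empty((n_rand, K, n_pairs))
    else:
        sum_null = np.zeros((K, n_pairs))
        sumsq_null = np.zeros((K, n_pairs))
    n_all = table.n_taxa
    for r in range(n_rand):
        if phylo_scope == "across_all":
            perm = rng_phylo.permutation(n_all)
        elif phylo_scope == "within_bin":
            perm = np.arange(n_all)
            for k in range(K):
                idx = member_idx[k]
                perm[idx] = idx[rng_phylo.permutation(len(idx))]
        else:
            raise ValueError(f"unknown phylo_scope {phylo_scope!r}")
        for k in range(K):
            pk = perm[member_idx[k]]
            d_k = dist.data[np.ix_(pk, pk)]
            v = _bin_beta_mpd_all_pairs(B_obs[k], d_k, present[k])
            if store_nulls:
                nulls[r, k] = v
            else:
                sum_null[k] += v
                sumsq_null[k] += v * v
    if store_nulls:
        null_mean = nulls.mean(axis=0)
        null_sd = nulls.std(axis=0)
    else:
        null_mean = sum_null / n_rand
        null_sd = np.sqrt(np.maximum(sumsq_null / n_rand - null_mean**2,
                                     0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        bnri = np.where(null_sd > 0,
                        (obs_bmpd - null_mean) / np.where(null_sd > 0,
                                                          null_sd, 1.0),
                        0.0)
    bnri = np.where(np.isnan(obs_bmpd), np.nan, bnri)
    # empirical two-sided quantile test of the observed betaMPD (the
    # 'direct' significance test, robust to non-normal null ensembles)
    if store_nulls:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            q_lo = np.nanquantile(nulls, alpha / 2.0, axis=0)
            q_hi = np.nanquantile(nulls, 1.0 - alpha / 2.0, axis=0)
    else:
        from scipy.stats import norm

        z = norm.ppf(1.0 - alpha / 2.0)
        q_lo, q_hi = null_mean - z * null_sd, null_mean + z * null_sd
    with np.errstate(invalid="ignore"):
        direct = np.where(obs_bmpd > q_hi, 1,
                          np.where(obs_bmpd < q_lo, -1, 0))

    # taxonomic null: rank observed Bray-Curtis within the null ensemble
    occ = (counts > 0).sum(axis=1).astype(float)
    occ_prob = occ / occ.sum()
    if taxo_weights == "mean_ra":
        fill = rel.mean(axis=1)
    else:
        fill = np.ones(n_all)
    delta_sum = np.zeros((K, n_pairs))
    counts_int = np.round(counts)
    for _ in range(n_rand):
        null_tab = _null_counts(counts_int, occ_prob, fill, rng_taxo)
        null_rel = null_tab / null_tab.sum(axis=0)
        for k in range(K):
            Xn = null_rel[member_idx[k]]
            with np.errstate(invalid="ignore"):
                bc_n = pdist(Xn.T, metric="braycurtis")
            diff = obs_bc[k] - np.nan_to_num(bc_n, nan=1.0)
            delta_sum[k] += np.where(diff > equal_tol, 1.0,
                                     np.where(diff < -equal_tol, 0.0, 0.5))
    rc = 2.0 * delta_sum / n_rand - 1.0
    rc = np.where(np.isnan(obs_bc), np.nan, rc)

    recs = []
    u_ids = [table.sample_ids[i] for i in iu[0]]
    v_ids = [table.sample_ids[j] for j in iu[1]]
    for k in range(K):
        # excluded only when the bin occurs in neither sample; one-sided
        # absence leaves RC defined (betaNRI stays NaN = no phylogenetic
        # evidence)
        excluded = np.isnan(obs_bc[k])
        for p in range(n_pairs):
            recs.append((u_ids[p], v_ids[p], k, obs_bmpd[k, p], bnri[k, p],
                         int(direct[k, p]), obs_bc[k, p], rc[k, p],
                         bool(excluded[p])))
    return pd.DataFrame(recs, columns=["sample_u", "sample_v", "bin",
                                       "bMPD", "bNRI", "direct", "BC",
                                       "RC", "excluded"])
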