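"""Entire-community null-model baseline (QPEN).

QPEN partitions the same five assembly processes as the bin-based pipeline
but from whole-community metrics: the beta nearest taxon index (betaNTI,
the standardised effect size of abundance-weighted beta mean nearest taxon
distance against a taxa shuffle) and the modified Raup-Crick metric on
community-wide Bray-Curtis.  Its per-group importances are the fractions of
pairwise turnovers assigned to each process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from campart.data_io import CommunityTable
from campart.null_models import (_null_counts, _pair_index,
                                 DEFAULT_RANDOMIZATIONS)
from campart.phylo_binning import PhyloDistMatrix, cophenetic_distances
from campart.process_partition import PROCESSES

__all__ = ["beta_mntd", "qpen_classify", "qpen_importance", "run_qpen",
           "QpenResult"]

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def beta_mntd(f_u, f_v, d) -> float:
    """Abundance-weighted beta mean nearest taxon distance.

    Mean of the two directed nearest-neighbour sums: for each taxon present
    in one community, the distance to its closest taxon present in the
    other, weighted by relative abundance.
    """
    f_u = np.asarray(f_u, float)
    f_v = np.asarray(f_v, float)
    d = np.asarray(d, float)
    pu = f_u > 0
    pv = f_v > 0
    if not pu.any() or not pv.any():
        raise ValueError("empty community")
    wu = f_u[pu] / f_u[pu].sum()
    wv = f_v[pv] / f_v[pv].sum()
    duv = d[np.ix_(pu, pv)]
    return float(0.5 * (wu @ duv.min(axis=1) + wv @ duv.min(axis=0)))


def qpen_classify(bnti: float, rc: float) -> str:
    """Whole-community process label; betaNTI threshold 2 by convention."""
    if np.isnan(bnti) or np.isnan(rc):
        raise ValueError("cannot classify NaN metrics")
    if bnti > BNTI_THRESHOLD:
        return "HeS"
    if bnti < -BNTI_THRESHOLD:
        return "HoS"
    if rc > RC_THRESHOLD:
        return "DL"
    if rc < -RC_THRESHOLD:
        return "HD"
    return "DR"


def qpen_importance(labels) -> pd.Series:
    """Fraction of pairwise turnovers per process within one grouping."""
    labels = list(labels)
    if not labels:
        raise ValueError("no pairs")
    out = pd.Series(0.0, index=list(PROCESSES))
    for lab in labels:
        out[lab] += 1.0 / len(labels)
    return out


@dataclass
class QpenResult:
    pairs: pd.DataFrame        # per pair: bNTI, RC, label
    group_fractions: pd.DataFrame  # per group: process fractions


def _all_pair_bmntd(rel: np.ndarray, d: np.ndarray) -> np.ndarray:
    """betaMNTD for every sample pair (condensed) in one pass.

    ``nd[i, v]`` is the distance from taxon i to the nearest taxon present
    in sample v; pair values are then abundance-weighted sums.
    """
    n_taxa, n_samp = rel.shape
    present = rel > 0
    nd = np.empty((n_taxa, n_samp))
    for v in range(n_samp):
        nd[:, v] = d[:, present[:, v]].min(axis=1)
    iu = _pair_index(n_samp)
    w = rel / rel.sum(axis=0)
    out = np.empty(len(iu[0]))
    for p, (u, v) in enumerate(zip(*iu)):
        out[p] = 0.5 * (w[:, u] @ nd[:, v] + w[:, v] @ nd[:, u])
    return out


def run_qpen(table: CommunityTable, tree=None,
             dist: PhyloDistMatrix | None = None,
             n_rand: int = DEFAULT_RANDOMIZATIONS, seed: int = 0,
             groups: dict | None = None,
             equal_tol: float = 1e-9) -> QpenResult:
    """QPEN over all sample pairs of a count table.

    ``groups`` optionally maps each sample to a group label; fractions are
    then reported per within-group and per between-group-pair class (plus
    'all').  Deterministic given ``seed``.
    """
    from scipy.spatial.distance import pdist

    if dist is None:
        if tree is None:
            raise ValueError("need a tree or a distance matrix")
        dist = cophenetic_distances(tree)
    if list(dist.taxa_ids) != list(table.taxa_ids):
        dist = dist.subset(table.taxa_ids)
    counts = np.round(table.abundance)
    rel = counts / counts.sum(axis=0)
    n_samp = table.n_samples
    iu = _pair_index(n_samp)
    rng = np.random.default_rng(seed)
    rng_phylo = np.random.default_rng(rng.integers(2**31 - 1))
    rng_taxo = np.random.default_rng(rng.integers(2**31 - 1))

    obs_bmntd = _all_pair_bmntd(rel, dist.data)
    obs_bc = pdist(rel.T, metric="braycurtis")

    n_taxa = table.n_taxa
    s1 = np.zeros_like(obs_bmntd)
    s2 = np.zeros_like(obs_bmntd)
    for _ in range(n_rand):
        perm = rng_phylo.permutation(n_taxa)
        v = _all_pair_bmntd(rel, dist.data[np.ix_(perm, perm)])
        s1 += v
        s2 += v * v
    mean = s1 / n_rand
    sd = np.sqrt(np.maximum(s2 / n_rand - mean**2, 0.0))
    bnti = np.where(sd > 0, (obs_bmntd - mean) / np.where(sd > 0, sd, 1.0),
                    0.0)

    occ = (counts > 0).sum(axis=1).astype(float)
    occ_prob = occ / occ.sum()
    fill = rel.mean(axis=1)
    delta = np.zeros_like(obs_bc)
    for _ in range(n_rand):
        null_tab = _null_counts(counts, occ_prob, fill, rng_taxo)
        null_rel = null_tab / null_tab.sum(axis=0)
        bc_n = pdist(null_rel.T, metric="braycurtis")
        diff = obs_bc - bc_n
        delta += np.where(diff > equal_tol, 1.0,
                          np.where(diff < -equal_tol, 0.0, 0.5))
    rc = 2.0 * delta / n_rand - 1.0

    labels = [qpen_classify(b, r) for b, r in zip(bnti, rc)]
    pairs = pd.DataFrame({
        "sample_u": [table.sample_ids[i] for i in iu[0]],
        "sample_v": [table.sample_ids[j] for j in iu[1]],
        "bNTI": bnti, "RC": rc, "label": labels,
    })
    frames = {"all": qpen_importance(labels)}
    if groups is not None:
        gu = pairs["sample_u"].map(groups)
        gv = pairs["sample_v"].map(groups)
        key = np.where(gu == gv, gu, np.minimum(gu, gv) + "|"
                       + np.maximum(gu, gv))
        for g in np.unique(key):
            frames[g] = qpen_importance(pairs.loc[key == g, "label"])
    group_fractions = pd.DataFrame(frames).T
    group_fractions.index.name = "group"
    return QpenResult(pairs=pairs, group_fractions=group_fractions)
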