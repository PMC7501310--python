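"""Classify pair-bin turnovers into assembly processes and integrate them.

Each (sample pair, bin) receives exactly one label: heterogeneous selection
when betaNRI > 1.96, homogeneous selection when betaNRI < -1.96, otherwise
dispersal limitation when RC > 0.95, homogenizing dispersal when
RC < -0.95, and 'drift' (drift, diversification, weak selection and/or
weak dispersal) for the rest.  Boundary values belong to the non-significant
side.  Labels are then abundance-weighted into per-pair, per-bin and group
level relative importances, and per-bin contributions to each process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from campart.data_io import CommunityTable, to_relative
from campart.null_models import pair_bin_metrics, DEFAULT_RANDOMIZATIONS
from campart.phylo_binning import (BinSet, PhyloDistMatrix, bin_by_tree,
                                   bin_by_centroid, bin_by_pairwise,
                                   cophenetic_distances)

__all__ = [
    "PROCESSES",
    "classify",
    "pair_importance",
    "bin_importance",
    "group_importance",
    "bin_contributions",
    "run_icamp",
    "IcampResult",
]

#: fixed process order: heterogeneous selection, homogeneous selection,
#: dispersal limitation, homogenizing dispersal, 'drift'
PROCESSES = ("HeS", "HoS", "DL", "HD", "DR")

BNRI_THRESHOLD = 1.96
RC_THRESHOLD = 0.95


def classify(bnri: float, rc: float) -> str:
    """Label one pair-bin turnover from its betaNRI and RC values."""
    if np.isnan(bnri) or np.isnan(rc):
        raise ValueError("cannot classify NaN metrics")
    if bnri > BNRI_THRESHOLD:
        return "HeS"
    if bnri < -BNRI_THRESHOLD:
        return "HoS"
    if rc > RC_THRESHOLD:
        return "DL"
    if rc < -RC_THRESHOLD:
        return "HD"
    return "DR"


def classify_vector(bnri: np.ndarray, rc: np.ndarray,
                    direct: np.ndarray | None = None) -> np.ndarray:
    """Vectorized :func:`classify`.

    Pair-bins with undefined RC give empty-string labels (excluded).  A
    NaN betaNRI with a defined RC (bin observed on one side only) carries
    no phylogenetic evidence and is classified by RC alone.  When
    ``direct`` is given (+1 above / -1 below the two-sided empirical null
    quantiles / 0 otherwise) the selection step uses it instead of the
    +/-1.96 standard-effect-size thresholds.
    """
    bnri = np.asarray(bnri, float)
    rc = np.asarray(rc, float)
    out = np.full(bnri.shape, "", dtype=object)
    valid = ~np.isnan(rc)
    if direct is not None:
        sig = np.asarray(direct, float)
        high = valid & (sig > 0)
        low = valid & (sig < 0)
    else:
        bnri_eff = np.where(np.isnan(bnri), 0.0, bnri)
        high = valid & (bnri_eff > BNRI_THRESHOLD)
        low = valid & (bnri_eff < -BNRI_THRESHOLD)
    out[high] = "HeS"
    out[low] = "HoS"
    rest = valid & ~high & ~low
    out[rest & (rc > RC_THRESHOLD)] = "DL"
    out[rest & (rc < -RC_THRESHOLD)] = "HD"
    out[rest & (np.abs(rc) <= RC_THRESHOLD)] = "DR"
    return out


def _weights(f_uk, f_vk, labels):
    """Per-bin pair weights (f_uk + f_vk)/2, with excluded bins (empty
    label) dropped and the rest renormalized."""
    w = (np.asarray(f_uk, float) + np.asarray(f_vk, float)) / 2.0
    keep = np.array([bool(l) for l in labels])
    w = np.where(keep, w, 0.0)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("no included bins for this pair")
    if not np.isclose(tot, 1.0, atol=1e-9):
        w = w / tot
    return w


def pair_importance(labels, f_uk, f_vk) -> pd.Series:
    """Relative importance of each process for one pair of communities:
    ``P_tau_uv = sum_k ((f_uk + f_vk)/2) W_tau_uvk``.

    Excluded pair-bins (empty label) are dropped and the remaining weights
    renormalized (with a warning) so the fractions sum to 1.
    """
    w = (np.asarray(f_uk, float) + np.asarray(f_vk, float)) / 2.0
    keep = np.array([bool(l) for l in labels])
    if not np.isclose(w[keep].sum(), 1.0, atol=1e-9):
        warnings.warn("pair weights do not sum to 1; renormalizing")
    w = _weights(f_uk, f_vk, labels)
    out = pd.Series(0.0, index=list(PROCESSES))
    for lab, wi in zip(labels, w):
        if lab:
            out[lab] += wi
    return out


def bin_importance(labels_by_pair, f_uk_by_pair, f_vk_by_pair) -> pd.Series:
    """Relative importance of each process for one bin across ``m`` pairs:
    abundance-weighted fraction of pairs the bin spent under each process."""
    w = (np.asarray(f_uk_by_pair, float)
         + np.asarray(f_vk_by_pair, float)) / 2.0
    keep = np.array([bool(l) for l in labels_by_pair])
    w = np.where(keep, w, 0.0)
    tot = w.sum()
    out = pd.Series(np.nan if tot == 0 else 0.0, index=list(PROCESSES))
    if tot == 0:
        return out
    for lab, wi in zip(labels_by_pair, w):
        if lab:
            out[lab] += wi / tot
    return out


def group_importance(pair_imps: pd.DataFrame) -> pd.Series:
    """Group-level relative importance: mean over pairs of the per-pair
    importances (equals the abundance-weighted bin sum when no pair-bin was
    excluded)."""
    return pair_imps[list(PROCESSES)].mean(axis=0)


def bin_contributions(long: pd.DataFrame) -> pd.DataFrame:
    """Per-bin contribution to each process over a group of pairs.

    ``BP_tau_k`` is the pair-averaged weighted operator (so that
    ``sum_k BP_tau_k`` equals the group importance ``P_tau``);
    ``BRP_tau_k = BP_tau_k / P_tau`` (missing when ``P_tau`` is 0).
    ``long`` needs columns pair, bin, label, weight (renormalized per pair).
    """
    m = long["pair"].nunique()
    kept = long[long["label"].astype(bool)]
    bp = (kept.pivot_table(index="bin", columns="label", values="weight",
                           aggfunc="sum", fill_value=0.0) / m)
    bp = bp.reindex(index=sorted(long["bin"].unique()),
                    columns=list(PROCESSES), fill_value=0.0)
    p_tau = bp.sum(axis=0)
    brp = bp.divide(p_tau, axis=1)
    brp[p_tau[p_tau == 0].index] = np.nan
    bp.columns = [f"BP_{c}" for c in bp.columns]
    brp.columns = [f"BRP_{c}" for c in brp.columns]
    out = pd.concat([bp, brp], axis=1)
    out.index.name = "bin"
    return out


@dataclass
class IcampResult:
    """Everything produced by one run: the bins, the per-(pair, bin) null
    model metrics and labels, per-pair process fractions, per-bin process
    importances and contributions, and group summaries."""

    bins: BinSet
    metrics: pd.DataFrame          # long per (pair, bin)
    pair_importances: pd.DataFrame  # per pair x processes
    bin_importances: pd.DataFrame   # per bin x processes
    contributions: pd.DataFrame     # per bin: BP / BRP
    group_summary: pd.Series        # processes -> fraction

    @property
    def stochasticity(self) -> float:
        """Summed importance of homogenizing dispersal, dispersal
        limitation and drift at group level."""
        return float(self.group_summary[["HD", "DL", "DR"]].sum())


def _binning(table, tree, dist, algorithm, ds, nmin):
    if algorithm == "tree":
        return bin_by_tree(tree, ds, nmin, dist=dist)
    mean_ra = (table.abundance / table.abundance.sum(axis=0)).mean(axis=1)
    if algorithm == "centroid":
        return bin_by_centroid(dist, mean_ra, ds, nmin)
    if algorithm == "pairwise":
        return bin_by_pairwise(dist, mean_ra, ds, nmin)
    raise ValueError(f"unknown binning algorithm {algorithm!r}")


def run_icamp(table: CommunityTable, tree, ds: float = 0.2, nmin: int = 24,
              n_rand: int = DEFAULT_RANDOMIZATIONS, seed: int = 0,
              binning: str = "tree", phylo_scope: str = "within_bin",
              taxo_weights: str = "mean_ra",
              significance: str = "ses",
              bins: BinSet | None = None,
              dist: PhyloDistMatrix | None = None) -> IcampResult:
    """Full pipeline: binning, bin-wise null models, classification and
    integration to pair / bin / group importances.

    ``table`` must hold counts (the taxonomic null preserves totals and
    richness exactly); its taxa must match the tree tips.  Deterministic
    given ``seed``.
    """
    if dist is None:
        dist = cophenetic_distances(tree)
    if list(dist.taxa_ids) != list(table.taxa_ids):
        dist = dist.subset(table.taxa_ids)
    if bins is None:
        if binning == "tree":
            tip_names = {t.name for t in tree.tips()}
            if tip_names != set(table.taxa_ids):
                tree = tree.shear(table.taxa_ids)
        bins = _binning(table, tree, dist, binning, ds, nmin)
    metrics = pair_bin_metrics(table, dist, bins, n_rand=n_rand, seed=seed,
                               phylo_scope=phylo_scope,
                               taxo_weights=taxo_weights)
    if significance == "direct":
        metrics["label"] = classify_vector(metrics["bNRI"], metrics["RC"],
                                           direct=metrics["direct"])
    elif significance == "ses":
        metrics["label"] = classify_vector(metrics["bNRI"], metrics["RC"])
    else:
        raise ValueError(f"unknown significance {significance!r}")

    rel = to_relative(table).abundance
    K = bins.n_bins
    f_bk = np.vstack([rel[bins.members(k)].sum(axis=0) for k in range(K)])
    samp_index = {s: i for i, s in enumerate(table.sample_ids)}

    metrics["pair"] = metrics["sample_u"] + "|" + metrics["sample_v"]
    u_idx = metrics["sample_u"].map(samp_index).to_numpy()
    v_idx = metrics["sample_v"].map(samp_index).to_numpy()
    k_arr = metrics["bin"].to_numpy()
    w_raw = (f_bk[k_arr, u_idx] + f_bk[k_arr, v_idx]) / 2.0
    w_raw = np.where(metrics["label"].to_numpy() == "", 0.0, w_raw)
    metrics["weight_raw"] = w_raw
    wsum = metrics.groupby("pair")["weight_raw"].transform("sum")
    metrics["weight"] = metrics["weight_raw"] / wsum

    onehot = pd.get_dummies(metrics["label"]).reindex(
        columns=list(PROCESSES), fill_value=0).astype(float)
    weighted = onehot.mul(metrics["weight"], axis=0)
    weighted["pair"] = metrics["pair"]
    pair_imps = weighted.groupby("pair", sort=False).sum()

    # per-bin importance with raw (unrenormalized) weights, per the
    # bin-level definition
    weighted_bin = onehot.mul(metrics["weight_raw"], axis=0)
    weighted_bin["bin"] = metrics["bin"]
    num = weighted_bin.groupby("bin").sum()
    den = metrics.groupby("bin")["weight_raw"].sum()
    bin_imps = num.divide(den, axis=0)

    contrib = bin_contributions(metrics[["pair", "bin", "label", "weight"]])
    group = group_importance(pair_imps)
    return IcampResult(bins=bins, metrics=metrics,
                       pair_importances=pair_imps, bin_importances=bin_imps,
                       contributions=contrib, group_summary=group)
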