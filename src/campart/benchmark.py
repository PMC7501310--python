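"""End-to-end benchmark orchestration: simulate, analyse, score.

Runs the three phylogenetic-signal scenarios (15 situations each, 24
communities per situation), applies the bin-based pipeline and the
entire-community baseline (QPEN) to every dataset, and scores the estimates
against the simulator's per-pair ground truth with the quantitative
(CCC-derived) and qualitative (confusion-cell) performance metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from campart.community_sim import (SimulationConfig, simulate_tree,
                                   simulate_trait, mzsm_metacommunity)
from campart.evaluation import (dominant_process, qualitative_scores,
                                quantitative_scores)
from campart.phylo_binning import bin_by_tree, cophenetic_distances
from campart.process_partition import PROCESSES, run_icamp
from campart.qpen import run_qpen

__all__ = ["ScenarioResult", "run_scenario", "run_all_scenarios",
           "scenario_scores", "qpen_scores"]

STOCHASTIC = ["DL", "HD", "DR"]


@dataclass
class ScenarioResult:
    """Per-pair estimates and expectations pooled over the 15 situations."""

    scenario: str
    pairs: pd.DataFrame          # est_/exp_ columns per process + stoch
    qpen_groups: pd.DataFrame    # per situation x geometry class
    achieved_k: float
    n_bins: list = field(default_factory=list)


def run_scenario(scenario: str, seed: int, config: SimulationConfig = None,
                 n_rand: int = 200, nmin: int = 24, ds: float = 0.2,
                 tree=None, dist=None, with_qpen: bool = True,
                 qpen_n_rand: int = 200, significance: str = "direct",
                 progress: bool = False) -> ScenarioResult:
    """Simulate one scenario's 15 situations and analyse every dataset.

    The estimator sees exactly what it would see in practice: the taxa
    table, the tree, and the binning parameters (``nmin``, ``ds``); ground
    truth is used only for scoring.
    """
    config = config or SimulationConfig()
    scen_id = {"LPS": 1, "MPS": 2, "HPS": 3}.get(scenario, 9)
    ss = np.random.SeedSequence([seed, scen_id])
    seeds = ss.generate_state(40) % (2**31 - 1)
    if tree is None:
        tree = simulate_tree(config.n_tips, seed=int(seeds[0]))
        dist = None
    if dist is None:
        dist = cophenetic_distances(tree)
    trait = None
    for extra in range(4):
        try:
            trait, achieved_k = simulate_trait(
                tree, scenario, seed=int(seeds[1]) + 7919 * extra,
                lps_model=config.lps_model, max_attempts=60)
            break
        except RuntimeError:
            if extra == 3:
                raise
    meta = mzsm_metacommunity(tree, config.J, config.theta,
                              seed=int(seeds[2]))
    bins = bin_by_tree(tree, config.ds, nmin, dist=dist)

    from campart.community_sim import situation_mixes, simulate_dataset, \
        _situation_name

    pair_rows = []
    qpen_rows = []
    n_bins = []
    for i, mix in enumerate(situation_mixes()):
        dataset = simulate_dataset(
            tree, trait, meta, mix, config, seed=int(seeds[3 + i]),
            scenario=scenario, situation=_situation_name(mix),
            achieved_k=achieved_k, dist=dist, bins=bins)
        res = run_icamp(dataset.table, tree, ds=ds, nmin=nmin,
                        n_rand=n_rand, seed=int(seeds[20 + i]), dist=dist,
                        bins=bins, significance=significance)
        n_bins.append(res.bins.n_bins)
        est = res.pair_importances
        exp = dataset.expected.loc[est.index]
        block = pd.DataFrame(index=est.index)
        for p in PROCESSES:
            block[f"est_{p}"] = est[p]
            block[f"exp_{p}"] = exp[p]
        block["est_stoch"] = est[STOCHASTIC].sum(axis=1)
        block["exp_stoch"] = exp[STOCHASTIC].sum(axis=1)
        block["est_dom"] = dominant_process(est).values
        block["exp_dom"] = dominant_process(exp[list(PROCESSES)]).values
        block["situation"] = dataset.situation
        block["geometry"] = exp["geometry"].values
        pair_rows.append(block)

        if with_qpen:
            qres = run_qpen(dataset.table, dist=dist, n_rand=qpen_n_rand,
                            seed=int(seeds[20 + i]))
            qp = qres.pairs

            def plot_group(u, v):
                pu, pv = dataset.plot_map[u], dataset.plot_map[v]
                return pu if pu == pv else "|".join(sorted((pu, pv)))

            groups = [plot_group(u, v)
                      for u, v in zip(qp["sample_u"], qp["sample_v"])]
            qp = qp.assign(group=groups)
            exp_g = exp.assign(group=[
                plot_group(*p.split("|")) for p in exp.index])
            for g, sub in qp.groupby("group"):
                frac = sub["label"].value_counts(normalize=True)
                frac = frac.reindex(list(PROCESSES), fill_value=0.0)
                exp_mean = exp_g.loc[exp_g["group"] == g,
                                     list(PROCESSES)].mean()
                row = {"situation": dataset.situation, "group": g,
                       "est_dom": frac.idxmax(),
                       "exp_dom": exp_mean.idxmax()}
                for p in PROCESSES:
                    row[f"est_{p}"] = float(frac[p])
                    row[f"exp_{p}"] = float(exp_mean[p])
                qpen_rows.append(row)
        if progress:
            print(f"  {scenario} situation {i + 1}/15 done", flush=True)

    pairs = pd.concat(pair_rows)
    qpen_groups = pd.DataFrame(qpen_rows) if qpen_rows else pd.DataFrame()
    return ScenarioResult(scenario=scenario, pairs=pairs,
                          qpen_groups=qpen_groups, achieved_k=achieved_k,
                          n_bins=n_bins)


def run_all_scenarios(seed: int, config: SimulationConfig = None,
                      n_rand: int = 200, scenarios=("LPS", "MPS", "HPS"),
                      with_qpen: bool = True, progress: bool = False):
    """Run every scenario on one shared tree (sub-seeded from ``seed``)."""
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    tree_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
    tree = simulate_tree(config.n_tips, seed=tree_seed)
    dist = cophenetic_distances(tree)
    out = {}
    for scen in scenarios:
        out[scen] = run_scenario(scen, seed, config=config, n_rand=n_rand,
                                 tree=tree, dist=dist, with_qpen=with_qpen,
                                 progress=progress)
        if progress:
            print(f"{scen} finished (K={out[scen].achieved_k:.2f})",
                  flush=True)
    return out


def scenario_scores(result: ScenarioResult) -> dict:
    """Quantitative and qualitative scores for one scenario's pooled pairs.

    Returns stochasticity qACC/qPRC, per-process qACC/qPRC, and the
    qualitative dominant-process scores (overall and per process).
    """
    pairs = result.pairs
    qacc, qprc = quantitative_scores(pairs["exp_stoch"], pairs["est_stoch"])
    per_process = {}
    for p in PROCESSES:
        pa, pp = quantitative_scores(pairs[f"exp_{p}"], pairs[f"est_{p}"])
        per_process[p] = {"qACC": pa, "qPRC": pp}
    qual = qualitative_scores(pairs["exp_dom"], pairs["est_dom"])
    return {
        "stoch_qACC": qacc,
        "stoch_qPRC": qprc,
        "per_process": per_process,
        "qual_overall": qual.overall,
        "qual_per_process": qual.per_process,
    }


def qpen_scores(result: ScenarioResult) -> dict:
    """Qualitative scores of the entire-community baseline over its
    (situation x geometry-class) groups."""
    g = result.qpen_groups
    qual = qualitative_scores(g["exp_dom"], g["est_dom"])
    return {"qual_overall": qual.overall,
            "qual_per_process": qual.per_process,
            "n_groups": len(g)}
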