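"""Performance metrics for estimated vs expected process importances.

Quantitative agreement is scored with the two factors of Lin's concordance
correlation coefficient: accuracy qACC (penalising location and scale
shifts) and precision qPRC (the Pearson correlation), both on population
moments.  Qualitative agreement scores the identification of the dominant
process per turnover through one-vs-rest confusion counts (accuracy,
precision, sensitivity, specificity).  Bootstrap and permutation helpers
mirror the inference used for method comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from campart.process_partition import PROCESSES

__all__ = [
    "quantitative_scores",
    "qualitative_scores",
    "dominant_process",
    "bootstrap_compare",
    "cohens_d",
    "permutation_test",
    "PerformanceScores",
]


def quantitative_scores(expected, estimated):
    """(qACC, qPRC) between expected ``x`` and estimated ``y`` vectors.

    qACC = 2 s_x s_y / (s_x^2 + s_y^2 + (mu_x - mu_y)^2) and
    qPRC = cov(y, x) / (s_x s_y), with population (divide-by-n) moments.
    qPRC is NaN when either vector has zero variance.
    """
    x = np.asarray(expected, dtype=float)
    y = np.asarray(estimated, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    sx = x.std(ddof=0)
    sy = y.std(ddof=0)
    mx, my = x.mean(), y.mean()
    qacc = 2.0 * sx * sy / (sx**2 + sy**2 + (mx - my) ** 2)
    if sx == 0 or sy == 0:
        return float(qacc), float("nan")
    cov = float(np.mean((x - mx) * (y - my)))
    return float(qacc), float(cov / (sx * sy))


def dominant_process(importances: pd.DataFrame,
                     processes=PROCESSES) -> pd.Series:
    """Dominant process per row; ties broken by the fixed process order
    (HeS, HoS, DL, HD, DR) with a '*' suffix flagging the tie."""
    sub = importances[list(processes)]
    vals = sub.to_numpy()
    best = vals.argmax(axis=1)
    ties = (vals == vals[np.arange(len(vals)), best][:, None]).sum(axis=1)
    labels = [processes[b] + ("*" if t > 1 else "")
              for b, t in zip(best, ties)]
    return pd.Series(labels, index=importances.index, name="dominant")


@dataclass
class PerformanceScores:
    """One-vs-rest confusion-based scores, overall and per process."""

    overall: dict
    per_process: pd.DataFrame
    counts: pd.DataFrame = field(repr=False, default=None)

    def __getitem__(self, key):
        return self.overall[key]


def qualitative_scores(expected_labels, estimated_labels,
                       processes=PROCESSES) -> PerformanceScores:
    """Confusion-cell scores for dominant-process identification.

    Every turnover contributes one cell per process: a true positive for
    the correctly identified dominant process (or a false positive for a
    wrongly claimed one, paired with a false negative for the actual one),
    and true negatives for all other processes.  Overall scores sum the
    cells over processes.
    """
    exp = [str(l).rstrip("*") for l in expected_labels]
    est = [str(l).rstrip("*") for l in estimated_labels]
    if len(exp) != len(est):
        raise ValueError("label vectors must have equal length")
    cells = pd.DataFrame(0, index=list(processes),
                         columns=["TP", "TN", "FP", "FN"])
    for e, s in zip(exp, est):
        for p in processes:
            if e == p and s == p:
                cells.loc[p, "TP"] += 1
            elif e == p and s != p:
                cells.loc[p, "FN"] += 1
            elif e != p and s == p:
                cells.loc[p, "FP"] += 1
            else:
                cells.loc[p, "TN"] += 1

    def scores(row):
        tp, tn, fp, fn = row["TP"], row["TN"], row["FP"], row["FN"]
        with np.errstate(invalid="ignore"):
            return {
                "ACC": (tp + tn) / max(tp + tn + fp + fn, 1),
                "PRC": tp / (tp + fp) if tp + fp else np.nan,
                "SST": tp / (tp + fn) if tp + fn else np.nan,
                "SPC": tn / (tn + fp) if tn + fp else np.nan,
            }

    per_proc = pd.DataFrame({p: scores(cells.loc[p]) for p in processes}).T
    overall = scores(cells.sum(axis=0))
    return PerformanceScores(overall=overall, per_process=per_proc,
                             counts=cells)


def bootstrap_compare(scores_a, scores_b, n_boot: int = 1000,
                      seed: int = 0) -> float:
    """One-sided bootstrap p that method A does not outperform method B.

    Situations are resampled with replacement (paired); p is the fraction
    of bootstrap replicates where mean(A) <= mean(B).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    rng = np.random.default_rng(seed)
    am = a[rng.integers(0, len(a), size=(n_boot, len(a)))].mean(axis=1)
    bm = b[rng.integers(0, len(b), size=(n_boot, len(b)))].mean(axis=1)
    # ties count half so two identical methods give p near 0.5
    return float(np.mean(am < bm) + 0.5 * np.mean(am == bm))


def cohens_d(x, y):
    """Cohen's d (pooled-SD standardised mean difference) and its
    conventional magnitude class."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
    d = 0.0 if pooled == 0 else (x.mean() - y.mean()) / pooled
    # guard the class boundaries against float round-off
    ad = round(abs(d), 12)
    if ad > 0.8:
        label = "large"
    elif ad > 0.5:
        label = "medium"
    elif ad > 0.2:
        label = "small"
    else:
        label = "negligible"
    return float(d), label


def permutation_test(x, y, n_perm: int = 1000, seed: int = 0,
                     statistic: str = "mean_diff") -> float:
    """Two-sided label-permutation test for a group difference in means."""
    if statistic != "mean_diff":
        raise ValueError("only the mean difference statistic is provided")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        px = pooled[perm[:len(x)]]
        py = pooled[perm[len(x):]]
        count += abs(px.mean() - py.mean()) >= obs - 1e-15
    return (count + 1) / (n_perm + 1)
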