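"""Link process importances to environmental factors via matrix statistics.

The per-pair relative importance of a process forms a pairwise matrix; for
every measured factor both the pairwise difference |f_u - f_v| and the
pairwise mean (f_u + f_v)/2 are candidate explanatory matrices.  Mantel,
partial Mantel and multiple regression on distance matrices (MRM, with
forward AIC model selection) relate them, with permutations optionally
constrained within blocks (e.g. plot identity in a repeated-measures
design).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from campart._matrixstats import (block_permutations, condensed,
                                  mantel_permutation_test)
from campart.data_io import EnvTable

__all__ = [
    "pair_factor_matrices",
    "log_shift_transform",
    "mantel",
    "partial_mantel",
    "mrm_forward_aic",
]


def pair_factor_matrices(env: EnvTable) -> dict:
    """Pairwise |difference| and mean matrices for every factor.

    Returns ``{factor: {'diff': DataFrame, 'mean': DataFrame}}`` with
    samples as both index and columns.
    """
    out = {}
    ids = env.sample_ids
    for fac in env.factor_names:
        v = env.values[fac].to_numpy(dtype=float)
        diff = np.abs(v[:, None] - v[None, :])
        mean = (v[:, None] + v[None, :]) / 2.0
        out[fac] = {
            "diff": pd.DataFrame(diff, index=ids, columns=ids),
            "mean": pd.DataFrame(mean, index=ids, columns=ids),
        }
    return out


def log_shift_transform(x) -> np.ndarray:
    """Natural-log transform tolerant of zero and negative values.

    All values are shifted by subtracting the minimum; resulting zeros are
    replaced by 0.05 times the minimum positive value (about -3.00 on the
    natural-log scale relative to it) before taking logs.
    """
    x = np.asarray(x, dtype=float)
    y = x - x.min()
    pos = y[y > 0]
    if len(pos) == 0:
        raise ValueError("degenerate (all-equal) vector")
    y = np.where(y == 0, 0.05 * pos.min(), y)
    return np.log(y)


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, pd.DataFrame):
        m = m.to_numpy()
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    return m


def _logit_response(proc: np.ndarray) -> np.ndarray:
    """Quasibinomial logit working response for fraction-valued matrices,
    with fractions squeezed away from 0 and 1."""
    eps = 1e-4
    p = np.clip(proc, eps, 1 - eps)
    return np.log(p / (1 - p))


def mantel(proc, factor, n_perm: int = 999, blocks=None, seed: int = 0,
           model: str = "linear"):
    """Mantel test between a process matrix and a factor matrix.

    Returns ``(r_squared, p)``; p is two-sided from ``n_perm`` label
    permutations of the factor matrix, restricted within ``blocks`` when
    given.  ``model='logit'`` applies a logit link to the (fraction-valued)
    process matrix before correlating, approximating a quasibinomial
    regression on distances.
    """
    a = _as_matrix(proc)
    b = _as_matrix(factor)
    if model == "logit":
        a = _logit_response(a)
    elif model != "linear":
        raise ValueError(f"unknown model {model!r}")
    r, p = mantel_permutation_test(a, b, n_perm, seed=seed,
                                   alternative="two-sided", blocks=blocks)
    return (np.nan if np.isnan(r) else float(r * r)), p


def _residual_matrix(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of condensed(y) on condensed(x), reshaped to a symmetric
    matrix with zero diagonal."""
    n = y.shape[0]
    yv, xv = condensed(y), condensed(x)
    X = np.column_stack([np.ones_like(xv), xv])
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    res = yv - X @ beta
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = res
    return out + out.T


def partial_mantel(proc, factor_a, control, n_perm: int = 999, blocks=None,
                   seed: int = 0):
    """Partial Mantel: correlation of the process and factor matrices after
    removing the (linear) effect of a control matrix from both."""
    y = _as_matrix(proc)
    a = _as_matrix(factor_a)
    c = _as_matrix(control)
    ry = _residual_matrix(y, c)
    ra = _residual_matrix(a, c)
    r, p = mantel_permutation_test(ry, ra, n_perm, seed=seed,
                                   alternative="two-sided", blocks=blocks)
    return (np.nan if np.isnan(r) else float(r * r)), p


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std(ddof=0)
    return (v - v.mean()) / (s if s > 0 else 1.0)


def mrm_forward_aic(proc, factors: dict, n_perm: int = 999, blocks=None,
                    seed: int = 0, log_transform: bool = True):
    """Multiple regression on distance matrices with forward AIC selection.

    ``factors`` maps names to square matrices.  Candidate predictors are
    (optionally) log-shift-transformed and standardised; terms enter while
    they lower the AIC of the OLS fit on condensed matrices.  Permutation p
    values per coefficient permute the response matrix labels within
    blocks.  Returns a dict with ``terms``, ``coefficients`` (standardised),
    ``r_squared``, ``aic`` and per-term ``p_values``.
    """
    y_mat = _as_matrix(proc)
    y = condensed(y_mat)
    n = y_mat.shape[0]
    preds = {}
    for name, m in factors.items():
        v = condensed(_as_matrix(m))
        if log_transform:
            v = log_shift_transform(v)
        preds[name] = _standardize(v)

    def fit(names, resp):
        X = np.column_stack([np.ones_like(resp)]
                            + [preds[nm] for nm in names])
        beta, *_ = np.linalg.lstsq(X, resp, rcond=None)
        res = resp - X @ beta
        rss = float(res @ res)
        k = X.shape[1]
        nn = len(resp)
        aic = nn * np.log(max(rss / nn, 1e-300)) + 2 * (k + 1)
        ss_tot = float(((resp - resp.mean()) ** 2).sum())
        r2 = 1.0 - rss / ss_tot if ss_tot > 0 else np.nan
        return beta, aic, r2

    selected = []
    _, best_aic, _ = fit([], y)
    improved = True
    while improved:
        improved = False
        best_candidate = None
        for name in preds:
            if name in selected:
                continue
            _, aic, _ = fit(selected + [name], y)
            if aic < best_aic - 1e-9:
                best_aic, best_candidate = aic, name
        if best_candidate is not None:
            selected.append(best_candidate)
            improved = True
    beta, aic, r2 = fit(selected, y)

    p_values = {}
    if selected and n_perm > 0:
        rng = np.random.default_rng(seed)
        perms = block_permutations(n, n_perm, rng, blocks=blocks)
        exceed = np.zeros(len(selected))
        for p_idx in perms:
            yp = condensed(y_mat[np.ix_(p_idx, p_idx)])
            b_p, _, _ = fit(selected, yp)
            exceed += np.abs(b_p[1:]) >= np.abs(beta[1:]) - 1e-15
        for i, name in enumerate(selected):
            p_values[name] = (exceed[i] + 1) / (n_perm + 1)
    return {
        "terms": list(selected),
        "coefficients": dict(zip(selected, beta[1:])),
        "intercept": float(beta[0]),
        "r_squared": float(r2),
        "aic": float(aic),
        "p_values": p_values,
    }
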