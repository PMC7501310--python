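"""Low-level permutation machinery for distance-matrix correlations.

Used by the within-bin phylogenetic-signal test and the environment-linkage
statistics.  Permutations act on object labels: rows and columns of one
matrix are permuted jointly, optionally restricted within blocks (e.g. plot
identity in a repeated-measures design).
"""

from __future__ import annotations

import numpy as np

__all__ = ["condensed", "pearson_condensed", "block_permutations",
           "mantel_permutation_test"]


def condensed(m: np.ndarray) -> np.ndarray:
    """Upper-triangle (i < j) entries of a square symmetric matrix."""
    m = np.asarray(m, dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def pearson_condensed(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r between the condensed forms of two square matrices."""
    x, y = condensed(a), condensed(b)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def block_permutations(n: int, n_perm: int, rng: np.random.Generator,
                       blocks=None) -> np.ndarray:
    """Sample ``n_perm`` permutations of ``range(n)``, each restricted to
    shuffle indices only within their block."""
    perms = np.empty((n_perm, n), dtype=np.intp)
    if blocks is None:
        for i in range(n_perm):
            perms[i] = rng.permutation(n)
        return perms
    blocks = np.asarray(blocks)
    if blocks.shape[0] != n:
        raise ValueError("blocks length must equal the number of objects")
    groups = [np.flatnonzero(blocks == b) for b in np.unique(blocks)]
    base = np.arange(n)
    for i in range(n_perm):
        p = base.copy()
        for g in groups:
            p[g] = g[rng.permutation(len(g))]
        perms[i] = p
    return perms


def mantel_permutation_test(a: np.ndarray, b: np.ndarray, n_perm: int,
                            seed: int, alternative: str = "two-sided",
                            blocks=None):
    """Mantel test: Pearson correlation between two distance/response
    matrices, with a label-permutation null applied to ``b``.

    Returns ``(r, p)``.  p uses the add-one rule
    ``(#{extreme permutations} + 1) / (n_perm + 1)``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    r_obs = pearson_condensed(a, b)
    if np.isnan(r_obs):
        return np.nan, np.nan
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    perms = block_permutations(n, n_perm, rng, blocks=blocks)
    x = condensed(a)
    x = (x - x.mean()) / x.std()
    count = 0
    for p in perms:
        y = condensed(b[np.ix_(p, p)])
        sy = y.std()
        if sy == 0:
            r_p = 0.0
        else:
            r_p = float(np.mean(x * (y - y.mean()) / sy))
        if alternative == "greater":
            extreme = r_p >= r_obs
        elif alternative == "less":
            extreme = r_p <= r_obs
        else:
            extreme = abs(r_p) >= abs(r_obs)
        count += bool(extreme)
    return r_obs, (count + 1) / (n_perm + 1)
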