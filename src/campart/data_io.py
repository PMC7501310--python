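"""Readers, writers and preprocessing for community tables, trees and metadata.

The canonical on-disk formats are plain TSV for taxa-by-sample abundance
tables and sample metadata, and Newick for phylogenies.  Abundances may be
counts or relative abundances; several operations (rarefaction, the
taxonomic null model) require counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CommunityTable",
    "EnvTable",
    "read_community_table",
    "write_community_table",
    "read_tree",
    "write_tree",
    "read_env_table",
    "match_taxa",
    "to_relative",
    "rarefy",
    "trim_by_average_abundance",
    "trim_by_cumulative_abundance",
]


@dataclass
class CommunityTable:
    """A taxa x samples abundance matrix with identifiers.

    Parameters
    ----------
    taxa_ids : list of str
        Unique taxon identifiers (rows).
    sample_ids : list of str
        Unique sample (community) identifiers (columns).
    abundance : ndarray, shape (n_taxa, n_samples)
        Non-negative counts or relative abundances.
    is_relative : bool
        If True every sample column sums to 1 (within 1e-9).
    """

    taxa_ids: list
    sample_ids: list
    abundance: np.ndarray
    is_relative: bool = False

    def __post_init__(self):
        self.taxa_ids = list(self.taxa_ids)
        self.sample_ids = list(self.sample_ids)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.taxa_ids), len(self.sample_ids)):
            raise ValueError("abundance shape does not match id lengths")
        if len(set(self.taxa_ids)) != len(self.taxa_ids):
            raise ValueError("duplicate taxon IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if np.any(self.abundance < 0):
            raise ValueError("negative abundance")
        colsum = self.abundance.sum(axis=0)
        if np.any(colsum == 0):
            raise ValueError("all-zero sample column(s)")
        if self.is_relative and np.any(np.abs(colsum - 1.0) > 1e-9):
            raise ValueError("is_relative set but columns do not sum to 1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=self.taxa_ids,
                            columns=self.sample_ids)

    def select_taxa(self, taxa) -> "CommunityTable":
        """Subset (and reorder) to the given taxa; abundances unchanged."""
        idx = {t: i for i, t in enumerate(self.taxa_ids)}
        rows = [idx[t] for t in taxa]
        sub = self.abundance[rows]
        if np.any(sub.sum(axis=0) == 0):
            raise ValueError("taxon subset empties at least one sample")
        # a taxon subset generally breaks the sum-to-1 property
        return CommunityTable(list(taxa), self.sample_ids, sub,
                              is_relative=False)


@dataclass
class EnvTable:
    """Per-sample environmental factors (real values, factor-specific units)."""

    values: pd.DataFrame  # samples x factors
    annotations: dict = field(default_factory=dict)

    @property
    def sample_ids(self):
        return list(self.values.index)

    @property
    def factor_names(self):
        return list(self.values.columns)


def read_community_table(path, orientation: str = "taxa_rows") -> CommunityTable:
    """Read a TSV abundance table.

    ``orientation='taxa_rows'`` expects taxa as rows and samples as columns;
    ``'samples_rows'`` the transpose.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "samples_rows":
        df = df.T
    elif orientation != "taxa_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}") from exc
    if np.any(mat < 0):
        raise ValueError("negative abundance")
    colsum = mat.sum(axis=0)
    is_rel = bool(np.all(np.abs(colsum - 1.0) <= 1e-9))
    return CommunityTable([str(i) for i in df.index],
                          [str(c) for c in df.columns], mat,
                          is_relative=is_rel)


def write_community_table(table: CommunityTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t")


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; every non-root branch must have a length."""
    tree = TreeNode.read(str(path), format="newick")
    tips = list(tree.tips())
    names = [t.name for t in tips]
    if len(set(names)) != len(names):
        raise ValueError("duplicate tip labels")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(
                "missing branch length(s): phylogenetic distances undefined")
        if node.length < 0:
            raise ValueError("negative branch length")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_env_table(path) -> EnvTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return EnvTable(values=df.astype(float))


def match_taxa(table: CommunityTable, tree: TreeNode):
    """Intersect the table's taxa with the tree's tips and align order.

    Returns the pruned (table, tree).  Warns with the number of taxa dropped
    from each side; raises if the intersection is empty.
    """
    tips = {t.name for t in tree.tips()}
    shared = [t for t in table.taxa_ids if t in tips]
    if not shared:
        raise ValueError("no taxa shared between table and tree")
    n_drop_table = table.n_taxa - len(shared)
    n_drop_tree = len(tips) - len(shared)
    if n_drop_table or n_drop_tree:
        warnings.warn(
            f"match_taxa: dropped {n_drop_table} table taxa and "
            f"{n_drop_tree} tree tips not shared")
    new_table = table.select_taxa(shared)
    new_tree = tree.shear(shared)
    return new_table, new_tree


def to_relative(table: CommunityTable) -> CommunityTable:
    """Convert each sample column to relative abundances (sums to 1)."""
    colsum = table.abundance.sum(axis=0)
    if np.any(colsum == 0):
        raise ValueError("all-zero sample column")
    rel = table.abundance / colsum
    return CommunityTable(table.taxa_ids, table.sample_ids, rel,
                          is_relative=True)


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Randomly draw ``depth`` individuals without replacement per sample."""
    counts = table.abundance
    if table.is_relative or not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefy requires integer counts")
    counts = np.round(counts).astype(np.int64)
    colsum = counts.sum(axis=0)
    if depth <= 0 or depth > colsum.min():
        raise ValueError(
            f"depth {depth} exceeds the smallest sample total {colsum.min()}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    keep = out.sum(axis=1) > 0
    return CommunityTable([t for t, k in zip(table.taxa_ids, keep) if k],
                          table.sample_ids, out[keep].astype(float))


def _mean_relative_abundance(table: CommunityTable) -> np.ndarray:
    rel = table.abundance / table.abundance.sum(axis=0)
    return rel.mean(axis=1)


def trim_by_average_abundance(table: CommunityTable,
                              keep_rank: int) -> CommunityTable:
    """Keep the ``keep_rank`` taxa with the highest mean relative abundance.

    Ties are broken lexicographically by taxon ID so the result is
    deterministic.
    """
    if keep_rank < 1 or keep_rank > table.n_taxa:
        raise ValueError("keep_rank out of range")
    mean_ra = _mean_relative_abundance(table)
    order = sorted(range(table.n_taxa),
                   key=lambda i: (-mean_ra[i], table.taxa_ids[i]))
    keep = sorted(order[:keep_rank])
    sub = table.abundance[keep]
    return CommunityTable([table.taxa_ids[i] for i in keep],
                          table.sample_ids, sub,
                          is_relative=False)


def trim_by_cumulative_abundance(table: CommunityTable,
                                 fraction: float) -> CommunityTable:
    """Keep, per sample, the minimal abundance-ranked prefix reaching
    ``fraction`` of the sample total; retain the union across samples."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    marked = np.zeros(table.n_taxa, dtype=bool)
    for j in range(table.n_samples):
        col = table.abundance[:, j]
        order = sorted(range(table.n_taxa),
                       key=lambda i: (-col[i], table.taxa_ids[i]))
        target = fraction * col.sum()
        run = 0.0
        for i in order:
            if col[i] <= 0:
                break
            marked[i] = True
            run += col[i]
            if run >= target - 1e-12:
                break
    keep = np.flatnonzero(marked)
    return CommunityTable([table.taxa_ids[i] for i in keep],
                          table.sample_ids, table.abundance[keep],
                          is_relative=False)
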