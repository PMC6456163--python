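"""Ontogenetic trees from mutation presence/absence across samples.

Samples of one plant are related by the somatic mutations they share: two
leaves from the same branch carry the branch's mutations and so sit close
together. A neighbor-joining tree on the pairwise count of differing
mutation columns (raw Hamming distance — branch lengths then read as
mutation counts) visualises the developmental history, and bootstrap
resampling of mutation columns attaches support to each split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj


def presence_matrix(mutations, samples) -> pd.DataFrame:
    """Samples x mutations 0/1 matrix from called candidates.

    A cell is 1 iff the sample belongs to the mutation's focal set. Mutations
    with no carrier among ``samples`` are dropped; an empty result is an
    error (no tree can be built from nothing).
    """
    samples = list(samples)
    cols: dict[str, list[int]] = {}
    for mut in mutations:
        col = [1 if s in mut.focal_samples else 0 for s in samples]
        if any(col):
            cols[str(mut.site)] = col
    if not cols:
        raise ValueError("no mutations with carriers among the given samples")
    return pd.DataFrame(cols, index=samples)


def hamming_distances(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise raw counts of differing mutation columns."""
    values = matrix.to_numpy(dtype=np.int8)
    n = len(matrix)
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = np.abs(values - values[i]).sum(axis=1)
    return DistanceMatrix(d, ids=list(matrix.index))


def nj_tree(matrix: pd.DataFrame) -> TreeNode:
    """Neighbor-joining tree on the raw Hamming distances.

    Deterministic given the input row order (ties resolved by the first
    minimal pair). Three samples yield the unique unrooted star with branch
    lengths from the three-point formulas.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 samples for a tree")
    dm = hamming_distances(matrix)
    if len(matrix) == 3:
        a, b, c = dm.ids
        dab, dac, dbc = dm[a, b], dm[a, c], dm[b, c]
        la = (dab + dac - dbc) / 2
        lb = (dab + dbc - dac) / 2
        lc = (dac + dbc - dab) / 2
        return TreeNode.read([f"({a}:{la},{b}:{lb},{c}:{lc});"])
    return nj(dm)


def tree_splits(tree: TreeNode, taxa: list[str]) -> set[frozenset]:
    """Nontrivial bipartitions of ``taxa``, canonicalised to the side not
    containing the first taxon (so splits compare across rootings)."""
    taxa_set = frozenset(taxa)
    anchor = taxa[0]
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if not side or side == taxa_set:
            continue
        if anchor in side:
            side = taxa_set - side
        if len(side) >= 2 and len(taxa_set - side) >= 2:
            splits.add(side)
    return splits


def bootstrap_support(
    matrix: pd.DataFrame,
    reps: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[frozenset, float]:
    """Bootstrap split support (percent) for the NJ tree of ``matrix``.

    Mutation columns are resampled with replacement ``reps`` times; each
    replicate's NJ tree contributes its splits, and each split of the
    original tree is reported with the percentage of replicates containing
    it.
    """
    if len(matrix) < 4:
        raise ValueError("bootstrap support needs at least 4 samples")
    if rng is None:
        rng = np.random.default_rng(seed)
    taxa = list(matrix.index)
    base = tree_splits(nj_tree(matrix), taxa)
    counts = {s: 0 for s in base}
    n_cols = matrix.shape[1]
    for _ in range(reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        resampled = matrix.iloc[:, idx]
        resampled.columns = [f"c{i}" for i in range(n_cols)]
        for split in tree_splits(nj_tree(resampled), taxa):
            if split in counts:
                counts[split] += 1
    return {s: 100.0 * c / reps for s, c in counts.items()}
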