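"""Nonparametric bootstrap support on neighbor-joining trees.

Alignment columns are resampled with replacement, a tree is rebuilt per
replicate (ML pairwise distances + NJ), and each internal bipartition of the
reference tree receives the percentage of replicates containing it.
"""

from __future__ import annotations

import dendropy
import numpy as np

from ..alnio import Alignment
from .distances import distance_matrix
from .models import SubstModel
from .nj import nj_tree
from .search import tree_bipartitions


def _internal_bips(tree: dendropy.Tree) -> set[frozenset]:
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for side in tree_bipartitions(tree):
        if 2 <= len(side) <= len(labels) - 2:
            out.add(min(side, labels - side, key=sorted))
    return out


def resample_columns(alignment: Alignment, rng: np.random.Generator) -> Alignment:
    L = alignment.n_columns
    cols = rng.integers(0, L, size=L)
    rows = {i: "".join(alignment.rows[i][c] for c in cols) for i in alignment.ids}
    return Alignment(ids=list(alignment.ids), rows=rows, labels=dict(alignment.labels))


def bootstrap_support(data, model: SubstModel, n_reps: int = 100,
                      seed: int = 0, reference_tree: dendropy.Tree | None = None,
                      min_reps: int = 100) -> dendropy.Tree:
    """NJ tree with internal-edge support in [0, 100] from ``n_reps`` replicates."""
    if n_reps < min_reps:
        raise ValueError(f"n_reps must be >= {min_reps}")
    aln = data.alignment if hasattr(data, "alignment") else data
    rng = np.random.default_rng(seed)
    if reference_tree is None:
        reference_tree = nj_tree(distance_matrix(aln, model))
    ref = reference_tree.clone(depth=1)
    labels = frozenset(lf.taxon.label for lf in ref.leaf_node_iter())
    counts: dict[frozenset, int] = {b: 0 for b in _internal_bips(ref)}
    for _ in range(n_reps):
        rep_aln = resample_columns(aln, rng)
        rep_tree = nj_tree(distance_matrix(rep_aln, model))
        rep_bips = _internal_bips(rep_tree)
        for b in counts:
            if b in rep_bips:
                counts[b] += 1
    for nd in ref.postorder_node_iter():
        if nd.is_leaf() or nd is ref.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if not (2 <= len(side) <= len(labels) - 2):
            continue
        key = min(side, labels - side, key=sorted)
        support = 100.0 * counts[key] / n_reps
        nd.label = f"{support:g}"
    return ref
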