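"""Saitou-Nei neighbor joining with deterministic tie-breaking.

Used as the starting tree for the NNI likelihood search and as the per-
replicate tree builder for nonparametric bootstrap support.  Ties in the
Q-criterion are broken lexicographically on the (sorted) pair of smallest
taxon labels contained in the two clusters, so the output is a pure function
of the distance matrix.  Negative branch length estimates are clamped to 0.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .distances import DistanceMatrix


def nj_tree(dm: DistanceMatrix,
            taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted; basal trifurcation) from a distance matrix."""
    n0 = len(dm.taxa)
    if n0 < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    newick = _nj_newick(dm)
    tree = dendropy.Tree.get(
        data=newick, schema="newick",
        taxon_namespace=taxon_namespace or dendropy.TaxonNamespace(),
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree.is_rooted = False
    return tree


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _nj_newick(dm: DistanceMatrix) -> str:
    labels = list(dm.taxa)
    D = dm.values.copy()
    # cluster state: newick fragment and the smallest taxon label it contains
    frags = [_quote(t) for t in labels]
    mins = list(labels)
    active = list(range(len(labels)))

    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cands = np.argwhere(q <= qmin + 1e-12)
        best = min(
            ((tuple(sorted((mins[active[i]], mins[active[j]]))), i, j)
             for i, j in cands if i < j),
        )
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        # distances from the new node to every other active cluster
        ks = [a for a in active if a not in (i, j)]
        dnew = 0.5 * (D[i, ks] + D[j, ks] - dij)
        dnew = np.maximum(dnew, 0.0)
        D[i, ks] = dnew
        D[ks, i] = dnew
        frags[i] = f"({frags[i]}:{li:.10g},{frags[j]}:{lj:.10g})"
        mins[i] = min(mins[i], mins[j])
        active.remove(j)

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    order = sorted([(mins[a], a, la), (mins[b], b, lb), (mins[c], c, lc)])
    parts = ",".join(f"{frags[k]}:{l:.10g}" for _, k, l in order)
    return f"({parts});"
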