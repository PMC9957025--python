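"""Maximum-likelihood tree search by NNI hill climbing, optionally constrained.

The search starts from a neighbor-joining tree on ML pairwise distances and
repeatedly evaluates all nearest-neighbor-interchange rearrangements,
accepting the best improvement until none remains.  Candidate rearrangements
are scored with a single branch-length optimisation sweep; the accepted tree
is then fully re-optimised.

A *clan* constraint (a taxon set that must be separated from all other taxa
by a single edge of the unrooted tree — the unrooted analogue of a clade) is
honoured by building a constraint-respecting start tree (NJ within the clan
and NJ on the remaining taxa, joined on one edge) and by rejecting any NNI
that breaks the clan.  This mirrors constrained ML searches used to test
whether, e.g., all carriers of an insertion element could form a clan.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .distances import DistanceMatrix, distance_matrix
from .likelihood import EncodedData, PruningEngine
from .models import SubstModel
from .nj import nj_tree

_PLACEHOLDER = "__clan_attach__"


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Leaf-label sets under each edge (both trivial and internal)."""
    out: set[frozenset] = set()
    for nd in tree.postorder_node_iter():
        if nd is tree.seed_node:
            continue
        leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        out.add(leaves)
    return out


def forms_clan(tree: dendropy.Tree, taxa: set) -> bool:
    """True iff ``taxa`` are separated from the rest by a single edge."""
    taxa = frozenset(taxa)
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    if len(taxa) <= 1 or len(all_taxa - taxa) <= 1:
        return True
    bips = tree_bipartitions(tree)
    return taxa in bips or (all_taxa - taxa) in bips


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted RF distance via symmetric difference of internal bipartitions."""
    labels = frozenset(lf.taxon.label for lf in t1.leaf_node_iter())
    if labels != frozenset(lf.taxon.label for lf in t2.leaf_node_iter()):
        raise ValueError("trees must share a leaf set")

    def internal(tree):
        out = set()
        for side in tree_bipartitions(tree):
            if 2 <= len(side) <= len(labels) - 2:
                out.add(min(side, labels - side, key=sorted))
        return out

    return len(internal(t1) ^ internal(t2))


def _nni_edge_indices(tree: dendropy.Tree) -> list[int]:
    """Postorder indices of child endpoints of internal edges."""
    nodes = list(tree.postorder_node_iter())
    out = []
    for k, nd in enumerate(nodes):
        if nd.is_leaf() or nd is tree.seed_node:
            continue
        out.append(k)
    return out


def _apply_nni(tree: dendropy.Tree, v_index: int, second: bool) -> dendropy.Node:
    """Swap a child of internal node ``v`` with a sibling subtree, in place.

    Returns ``v``, the child endpoint of the rearranged central edge.
    """
    nodes = list(tree.postorder_node_iter())
    v = nodes[v_index]
    u = v.parent_node
    c = next(ch for ch in u.child_nodes() if ch is not v)
    a = v.child_nodes()[1 if second else 0]
    u.remove_child(c)
    v.remove_child(a)
    u.add_child(a)
    v.add_child(c)
    return v


def _rooted_subtree(dm: DistanceMatrix, members: list[str], others: list[str],
                    ns: dendropy.TaxonNamespace) -> dendropy.Node:
    """A rooted subtree over ``members``, rooted at its attachment point."""
    if len(members) == 1:
        nd = dendropy.Node()
        leaf = dendropy.Node()
        leaf.taxon = ns.require_taxon(label=members[0])
        leaf.edge.length = 0.0
        nd.add_child(leaf)
        return nd
    if len(members) == 2:
        nd = dendropy.Node()
        half = max(dm.get(members[0], members[1]) / 2.0, 0.0)
        for m in members:
            leaf = dendropy.Node()
            leaf.taxon = ns.require_taxon(label=m)
            leaf.edge.length = half
            nd.add_child(leaf)
        return nd
    # NJ over members plus a placeholder summarising the other side, then
    # root at the placeholder's attachment and drop it.
    idx = {t: i for i, t in enumerate(dm.taxa)}
    mi = [idx[m] for m in members]
    oi = [idx[o] for o in others]
    sub = dm.values[np.ix_(mi, mi)]
    ph_col = dm.values[np.ix_(mi, oi)].mean(axis=1)
    n = len(members) + 1
    vals = np.zeros((n, n))
    vals[: n - 1, : n - 1] = sub
    vals[: n - 1, n - 1] = ph_col
    vals[n - 1, : n - 1] = ph_col
    t = nj_tree(DistanceMatrix(members + [_PLACEHOLDER], vals), taxon_namespace=ns)
    ph = next(lf for lf in t.leaf_node_iter() if lf.taxon.label == _PLACEHOLDER)
    t.reroot_at_node(ph.parent_node, suppress_unifurcations=False)
    ph.parent_node.remove_child(ph)
    root = t.seed_node
    root.parent_node = None
    return root


def constrained_nj_tree(dm: DistanceMatrix, clans) -> dendropy.Tree:
    """NJ start tree in which each of the given clans is guaranteed to be a clan.

    ``clans`` is one taxon set or a list of pairwise-disjoint taxon sets.
    Each clan is collapsed to a supertaxon (mean linkage distances), NJ is
    run on supertaxa plus the remaining taxa, and each supertaxon leaf is
    replaced by the NJ subtree over its members rooted at the attachment.
    """
    if clans and isinstance(next(iter(clans)), str):
        clans = [set(clans)]
    clans = [set(c) for c in clans]
    for a in range(len(clans)):
        for b in range(a + 1, len(clans)):
            if clans[a] & clans[b]:
                raise ValueError("constraint clans must be pairwise disjoint")
    clans = [c for c in clans
             if 2 <= len(c) <= len(dm.taxa) - 2]
    if not clans:
        return nj_tree(dm)
    idx = {t: i for i, t in enumerate(dm.taxa)}
    member_of: dict[str, int] = {}
    for k, c in enumerate(clans):
        for t in c:
            member_of[t] = k
    singles = [t for t in dm.taxa if t not in member_of]
    items = [f"__clan{k}__" for k in range(len(clans))] + singles
    n = len(items)
    vals = np.zeros((n, n))

    def group_idx(item: str) -> list[int]:
        if item.startswith("__clan"):
            return [idx[t] for t in sorted(clans[int(item[6:-2])])]
        return [idx[item]]

    for a in range(n):
        for b in range(a + 1, n):
            block = dm.values[np.ix_(group_idx(items[a]), group_idx(items[b]))]
            vals[a, b] = vals[b, a] = block.mean()
    skeleton = nj_tree(DistanceMatrix(items, vals))
    ns = dendropy.TaxonNamespace()
    for k, clan in enumerate(clans):
        members = sorted(clan)
        others = sorted(set(dm.taxa) - clan)
        sub_root = _rooted_subtree(dm, members, others, ns)
        leaf = next(lf for lf in skeleton.leaf_node_iter()
                    if lf.taxon.label == f"__clan{k}__")
        sub_root.edge.length = leaf.edge.length
        parent = leaf.parent_node
        parent.remove_child(leaf)
        parent.add_child(sub_root)
    # rebuild on a clean namespace so supertaxon labels disappear
    tree = dendropy.Tree.get(data=skeleton.as_string(schema="newick",
                                                     unquoted_underscores=True),
                             schema="newick", taxon_namespace=ns,
                             preserve_underscores=True)
    tree.is_rooted = False
    if len(tree.seed_node.child_nodes()) == 2:
        tree.deroot()
    return tree


def ml_search(data, model: SubstModel, seed: int = 0,
              constraint: set | list[set] | None = None,
              start_tree: dendropy.Tree | None = None, bl_tol: float = 0.01,
              nni_tol: float = 1e-4, max_rounds: int = 50) -> tuple[dendropy.Tree, float]:
    """NNI hill-climbing ML search; returns the best tree and its lnL.

    With ``constraint`` the returned tree always has the constrained taxa as
    a clan, and its likelihood is never above the unconstrained optimum.
    """
    del seed  # the search is deterministic; kept for interface stability
    enc = EncodedData(data)
    taxa = set(enc.taxa)
    if len(taxa) < 4:
        raise ValueError("ML search requires at least 4 taxa")
    clans: list[set] = []
    if constraint:
        if isinstance(next(iter(constraint)), str):
            clans = [set(constraint)]
        else:
            clans = [set(c) for c in constraint]
        for c in clans:
            if not c <= taxa:
                raise ValueError(f"constraint taxa not in data: {sorted(c - taxa)}")
        clans = [c for c in clans if 2 <= len(c) <= len(taxa) - 2]
    effective = clans or None

    if start_tree is None:
        dm = distance_matrix(_as_alignment(data), model)
        start_tree = (constrained_nj_tree(dm, effective)
                      if effective is not None else nj_tree(dm))
    eng = PruningEngine(start_tree, enc, model)
    eng.optimize_branch_lengths(tol=bl_tol)
    tree = eng.export_tree()
    lnl = eng.lnl()[0]

    def full_opt(move):
        cand = tree.clone(depth=1)
        _apply_nni(cand, *move)
        ceng = PruningEngine(cand, enc, model)
        return ceng, ceng.optimize_branch_lengths(tol=bl_tol)

    for _ in range(max_rounds):
        scored: list[tuple[float, tuple[int, bool]]] = []
        for v_idx in _nni_edge_indices(tree):
            for second in (False, True):
                cand = tree.clone(depth=1)
                v = _apply_nni(cand, v_idx, second)
                if effective is not None and not all(forms_clan(cand, c) for c in effective):
                    continue
                # cheap score: re-optimise only the rearranged central edge
                ceng = PruningEngine(cand, enc, model)
                pos = list(cand.postorder_node_iter()).index(v)
                scored.append((ceng.optimize_edge(ceng.postorder[pos]), (v_idx, second)))
        if not scored:
            break
        scored.sort(key=lambda s: -s[0])
        improving = [mv for sc, mv in scored if sc > lnl]
        if improving:
            ceng, new_lnl = full_opt(improving[0])
        else:
            # near convergence the cheap score can miss a gain hidden in the
            # other branch lengths: verify the top candidates fully
            ceng, new_lnl = None, lnl
            for _, mv in scored[:3]:
                c_eng, c_lnl = full_opt(mv)
                if c_lnl > new_lnl + nni_tol:
                    ceng, new_lnl = c_eng, c_lnl
                    break
        if ceng is None or new_lnl <= lnl + nni_tol:
            if ceng is not None and new_lnl > lnl:
                tree, lnl = ceng.export_tree(), new_lnl
            break
        tree, lnl = ceng.export_tree(), new_lnl
    return tree, lnl


def _as_alignment(data):
    return data.alignment if hasattr(data, "alignment") else data
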