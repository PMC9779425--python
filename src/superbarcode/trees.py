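"""Tree plumbing: Newick I/O, rooting, ultrametrization, neighbor-joining.

Trees are :class:`dendropy.Tree` objects throughout; tip labels are specimen
ids.  Input polytomies are resolved into binary nodes deterministically (by
sorted descendant label) with zero-length branches, because the tree-based
delimitation models require binary trees.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

ULTRAMETRIC_TOL = 1e-8


class TreeError(ValueError):
    pass


def tree_from_string(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a binary dendropy tree."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        offset = getattr(exc, "col_num", None)
        raise TreeError(f"malformed Newick (near character {offset}): {exc}") from exc
    labels = tip_labels(tree)
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate tip labels")
    resolve_polytomies(tree)
    return tree


def read_tree(path: str | Path) -> dendropy.Tree:
    with open(path) as fh:
        return tree_from_string(fh.read())


def tree_to_string(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True,
                          suppress_rooting=True).strip() + "\n"


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_string(tree))


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def n_tips(tree: dendropy.Tree) -> int:
    return sum(1 for _ in tree.leaf_node_iter())


def _min_desc_label(node) -> str:
    return min(leaf.taxon.label for leaf in node.leaf_iter())


def resolve_polytomies(tree: dendropy.Tree) -> dendropy.Tree:
    """Resolve polytomies in place into binary nodes with zero-length branches.

    Children are combined pairwise in order of their smallest descendant tip
    label, so the resolution is deterministic for a given topology.
    """
    for node in list(tree.preorder_node_iter()):
        while len(node.child_nodes()) > 2:
            kids = sorted(node.child_nodes(), key=_min_desc_label)
            a, b = kids[0], kids[1]
            new = dendropy.Node()
            new.edge.length = 0.0
            node.remove_child(a)
            node.remove_child(b)
            new.add_child(a)
            new.add_child(b)
            node.add_child(new)
    return tree


def is_binary(tree: dendropy.Tree) -> bool:
    return all(len(n.child_nodes()) in (0, 2) for n in tree.preorder_node_iter())


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


def is_ultrametric(tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL) -> bool:
    d = list(tip_depths(tree).values())
    return (max(d) - min(d)) <= tol * max(1.0, max(d))


def node_ages(tree: dendropy.Tree) -> dict:
    """Node -> age (time before present). Requires an ultrametric tree."""
    ages: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            ages[node] = max(ages[c] + (c.edge.length or 0.0) for c in node.child_nodes())
    return ages


def _leaf_path(tree: dendropy.Tree, a, b) -> list:
    """Node path from leaf a to leaf b (inclusive)."""
    anc_a = []
    node = a
    while node is not None:
        anc_a.append(node)
        node = node.parent_node
    anc_set = set(id(n) for n in anc_a)
    up_b = []
    node = b
    while id(node) not in anc_set:
        up_b.append(node)
        node = node.parent_node
    lca = node
    path = anc_a[: anc_a.index(lca) + 1]
    return path + list(reversed(up_b))


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Return a midpoint-rooted binary copy of the tree.

    Deterministic: the diameter pair and any ties are resolved by tip
    label order; a midpoint falling exactly on a node is nudged into the
    adjacent edge.
    """
    t = tree.clone(depth=1)
    leaves = sorted(t.leaf_node_iter(), key=lambda n: n.taxon.label)

    def farthest_from(leaf):
        best = None
        for other in leaves:
            if other is leaf:
                continue
            path = _leaf_path(t, leaf, other)
            dist = 0.0
            for x, y in zip(path, path[1:]):
                edge_node = x if x.parent_node is y else y
                dist += edge_node.edge.length or 0.0
            if best is None or dist > best[0] + 1e-15:
                best = (dist, other)
        return best

    _, u = farthest_from(leaves[0])
    d_uv, v = farthest_from(u)
    path = _leaf_path(t, u, v)
    half = d_uv / 2.0
    # walk from u toward v until the cumulative length crosses the midpoint
    acc = 0.0
    for x, y in zip(path, path[1:]):
        child = x if x.parent_node is y else y  # the node owning this edge
        elen = child.edge.length or 0.0
        if acc + elen >= half - 1e-15:
            offset = min(max(half - acc, 0.0), elen)  # distance from x along edge
            if child is x:  # walking upward: x is the child end of the edge
                len_child_side, len_parent_side = offset, elen - offset
            else:  # walking downward: y is the child end
                len_child_side, len_parent_side = elen - offset, offset
            eps = 1e-12 * max(d_uv, 1.0)
            len_child_side = max(len_child_side, eps if elen > 0 else 0.0)
            len_parent_side = max(elen - len_child_side, 0.0)
            t.reroot_at_edge(child.edge, length1=len_parent_side,
                             length2=len_child_side, update_bipartitions=False)
            break
        acc += elen
    t.seed_node.edge.length = None
    resolve_polytomies(t)
    return t


def ultrametrize(tree: dendropy.Tree) -> dendropy.Tree:
    """Mean-path-length smoothing: make the tree ultrametric, topology unchanged.

    Each internal node's age is the mean of its node-to-tip path lengths;
    a child older than its parent is clamped just below the parent.  This is
    the uncalibrated special case of rate-smoothing dating methods and is
    used to prepare substitution trees for the mixed Yule-coalescent model.
    """
    if any(len(n.child_nodes()) > 2 for n in tree.preorder_node_iter()):
        raise TreeError("ultrametrize requires a binary tree")
    root_kids = len(tree.seed_node.child_nodes())
    if root_kids != 2:
        raise TreeError("ultrametrize requires a rooted binary tree; midpoint_root() first")
    t = tree.clone(depth=1)
    # bottom-up mean node-to-tip path length
    stats: dict = {}
    age: dict = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            stats[node] = (1, 0.0)
            age[node] = 0.0
        else:
            cnt = tot = 0.0
            for c in node.child_nodes():
                n_c, s_c = stats[c]
                cnt += n_c
                tot += s_c + n_c * (c.edge.length or 0.0)
            stats[node] = (cnt, tot)
            age[node] = tot / cnt
    # top-down clamp so child age < parent age
    eps = 1e-12 * max(age[t.seed_node], 1e-300)
    for node in t.preorder_node_iter():
        if node.parent_node is not None and not node.is_leaf():
            limit = age[node.parent_node] - eps
            if age[node] > limit:
                age[node] = max(limit, 0.0)
    for node in t.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = max(age[node.parent_node] - age[node], 0.0)
    t.seed_node.edge.length = None
    return t


def edge_clades(tree: dendropy.Tree) -> list[frozenset]:
    """Leaf-label set below every non-root node (one per edge)."""
    below: dict = {}
    out = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is not None:
            out.append(below[node])
    return out


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, each encoded as the side that
    excludes the lexicographically smallest tip label."""
    taxa = frozenset(tip_labels(tree))
    ref = min(taxa)
    n = len(taxa)
    out = set()
    for clade in edge_clades(tree):
        side = taxa - clade if ref in clade else clade
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def is_monophyletic(tree: dendropy.Tree, members: Iterable[str]) -> bool:
    """True iff some edge of the (unrooted) tree isolates exactly `members`.

    Singletons and the full tip set count as monophyletic.
    """
    s = frozenset(members)
    taxa = frozenset(tip_labels(tree))
    if len(s) <= 1 or s == taxa:
        return True
    comp = taxa - s
    for clade in edge_clades(tree):
        if clade == s or clade == comp:
            return True
    return False


def nj_tree(ids: list[str], d: np.ndarray) -> dendropy.Tree:
    """Neighbor-joining tree from a full symmetric distance matrix.

    Negative branch lengths (a known NJ artifact) are clamped to zero with a
    log note.  The returned tree is binary (basal trifurcation resolved
    deterministically) but should be treated as unrooted.
    """
    import skbio

    d = np.asarray(d, dtype=float)
    if d.shape[0] < 3:
        raise TreeError("neighbor-joining needs >= 3 taxa")
    if not np.isfinite(d).all():
        raise TreeError(
            "distance matrix has undefined entries; impute them or skip this window"
        )
    dm = skbio.DistanceMatrix(d, ids=ids)
    sk = skbio.tree.nj(dm)
    n_neg = 0
    for node in sk.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_neg += 1
    if n_neg:
        logger.info("clamped %d negative NJ branch lengths to 0", n_neg)
    return tree_from_string(str(sk))
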