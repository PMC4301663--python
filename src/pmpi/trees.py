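"""Gene-tree handling: Newick I/O, rooted MAST, induced branch lengths.

Real gene trees over overlapping taxon sets rarely agree topologically
(horizontal transfer, missing taxa), so branch lengths of a gene pair can
only be compared on a maximum agreement subtree (MAST): the largest leaf
subset on which both trees induce the same topology.  Edges not on the
induced tree are removed and degree-2 nodes are contracted while summing
the lengths of the contracted path, yielding one aligned edge-length vector
per tree over the common topology.

Trees are treated as rooted at a designated shared taxon (default: the
lexicographically smallest shared leaf) and the MAST is computed by the
classical dynamic program over node pairs, with a maximum-weight assignment
over child pairs at internal nodes.  Pairs whose MAST is smaller than a
leaf threshold are discarded before regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "TreeNode",
    "GeneTree",
    "MastResult",
    "read_newick",
    "read_newick_dir",
    "to_newick",
    "reroot_at_leaf",
    "restrict_to",
    "clade_lengths",
    "mast_pair",
    "is_agreement_subset",
    "pair_filter",
    "aligned_vectors",
]


@dataclass
class TreeNode:
    """A node with the length of the edge above it and its children."""

    label: str | None
    length: float
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class GeneTree:
    """A leaf-labelled tree with branch lengths, identified by gene id."""

    id: str
    root: TreeNode

    def leaf_labels(self) -> frozenset:
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(node.label)
            for c in node.children:
                walk(c)

        walk(self.root)
        if len(out) != len(set(out)):
            raise ValueError(f"tree {self.id}: duplicate leaf labels")
        return frozenset(out)


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def _convert(node: dendropy.Node, tree_id: str, missing_length: str) -> TreeNode:
    length = node.edge.length
    if length is None:
        if node.parent_node is None:
            length = 0.0  # no edge above the root
        elif missing_length == "zero":
            length = 0.0
        else:
            raise ValueError(
                f"tree {tree_id}: missing branch length above node "
                f"{node.taxon.label if node.taxon else '<internal>'} "
                "(pass missing_length='zero' to substitute 0)"
            )
    label = node.taxon.label if node.taxon is not None else None
    return TreeNode(
        label=label,
        length=float(length),
        children=[
            _convert(c, tree_id, missing_length) for c in node.child_nodes()
        ],
    )


def read_newick(path, missing_length: str = "error") -> list:
    """Parse a Newick file (possibly multi-tree) into GeneTree objects."""
    path = Path(path)
    try:
        trees = dendropy.TreeList.get(path=str(path), schema="newick")
    except Exception as exc:
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    out = []
    for i, t in enumerate(trees):
        tree_id = path.stem if len(trees) == 1 else f"{path.stem}_{i}"
        gt = GeneTree(id=tree_id, root=_convert(t.seed_node, tree_id, missing_length))
        gt.leaf_labels()  # validate uniqueness
        out.append(gt)
    return out


def read_newick_dir(directory, pattern: str = "*", missing_length: str = "error") -> list:
    """Read every Newick file in a directory (sorted by name)."""
    files = sorted(p for p in Path(directory).glob(pattern) if p.is_file())
    if not files:
        raise ValueError(f"no tree files matching {pattern!r} in {directory}")
    out = []
    for f in files:
        out.extend(read_newick(f, missing_length=missing_length))
    return out


def to_newick(tree: GeneTree) -> str:
    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.label}:{node.length:.17g}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{node.length:.17g}"

    inner = ",".join(render(c) for c in tree.root.children)
    return f"({inner});"


def write_newick(trees: Iterable[GeneTree], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in trees:
        (directory / f"{t.id}.nwk").write_text(to_newick(t) + "\n")


# ---------------------------------------------------------------------------
# Rerooting, restriction, clade-length extraction
# ---------------------------------------------------------------------------

def _adjacency(root: TreeNode):
    adj: dict = {id(root): []}

    def walk(node):
        for c in node.children:
            adj.setdefault(id(c), [])
            adj[id(node)].append((c, c.length))
            adj[id(c)].append((node, c.length))
            walk(c)

    walk(root)
    return adj


def reroot_at_leaf(tree: GeneTree, leaf_label: str) -> GeneTree:
    """Reroot on the edge above a designated leaf (outgroup position).

    The new root's children are the outgroup leaf (carrying the full length
    of its original pendant edge) and the rest of the tree (zero length on
    its side of the split); former degree-2 nodes, including the old root,
    are suppressed with path lengths summed, so all leaf-to-leaf path
    lengths are preserved.
    """
    leaves = {}

    def collect(node):
        if node.is_leaf:
            leaves[node.label] = node
        for c in node.children:
            collect(c)

    collect(tree.root)
    if leaf_label not in leaves:
        raise ValueError(f"tree {tree.id}: no leaf {leaf_label!r}")
    leaf = leaves[leaf_label]
    adj = _adjacency(tree.root)

    def orient(node: TreeNode, parent: TreeNode, length: float) -> TreeNode:
        kids = [
            orient(nb, node, w) for nb, w in adj[id(node)] if nb is not parent
        ]
        if not kids:
            return TreeNode(label=node.label, length=length, children=[])
        if len(kids) == 1:  # suppress degree-2 node (e.g. the old root)
            kids[0].length += length
            return kids[0]
        return TreeNode(label=None, length=length, children=kids)

    (neighbor, w), = adj[id(leaf)]
    new_root = TreeNode(
        label=None,
        length=0.0,
        children=[
            TreeNode(label=leaf_label, length=w, children=[]),
            orient(neighbor, leaf, 0.0),
        ],
    )
    return GeneTree(id=tree.id, root=new_root)


def restrict_to(tree: GeneTree, leaves) -> GeneTree:
    """Induced subtree on a leaf subset, contracting degree-2 nodes.

    Contracted paths keep their total length, so leaf-to-leaf distances
    within the subset are conserved.
    """
    leaves = set(leaves)

    def prune(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            if node.label in leaves:
                return TreeNode(label=node.label, length=node.length, children=[])
            return None
        kids = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length += node.length
            return kids[0]
        return TreeNode(label=None, length=node.length, children=kids)

    root = prune(tree.root)
    if root is None:
        raise ValueError(f"tree {tree.id}: no leaves from {sorted(leaves)} present")
    root.length = 0.0
    return GeneTree(id=tree.id, root=root)


def clade_lengths(tree: GeneTree, merge_root_split: bool = True) -> dict:
    """Map each edge to (leafset below it) -> length.

    With ``merge_root_split`` (the default for rooted-at-outgroup trees) the
    two edges incident to a binary root — the same split of an unrooted tree
    — are merged into a single entry keyed by the smaller side, lengths
    summed.
    """
    out: dict = {}

    def walk(node: TreeNode) -> frozenset:
        if node.is_leaf:
            key = frozenset([node.label])
        else:
            key = frozenset().union(*(walk(c) for c in node.children))
        out[key] = out.get(key, 0.0) + node.length
        return key

    all_leaves = frozenset().union(*(walk(c) for c in tree.root.children))
    if merge_root_split and len(tree.root.children) == 2:
        ka = frozenset(_leafset(tree.root.children[0]))
        kb = all_leaves - ka
        canonical = min(ka, kb, key=lambda s: (len(s), tuple(sorted(s))))
        other = kb if canonical == ka else ka
        if other != canonical and other in out:
            out[canonical] = out.get(canonical, 0.0) + out.pop(other)
    return out


def _leafset(node: TreeNode) -> set:
    if node.is_leaf:
        return {node.label}
    return set().union(*(_leafset(c) for c in node.children))


# ---------------------------------------------------------------------------
# Maximum agreement subtree
# ---------------------------------------------------------------------------

@dataclass
class MastResult:
    """A maximum agreement leaf set and the aligned induced edge lengths.

    ``aligned`` has one row per edge of the common induced topology (keyed
    by the sorted leaf labels below it) with the corresponding path lengths
    in each tree.
    """

    tree_a: str
    tree_b: str
    leaf_set: frozenset
    aligned: pd.DataFrame

    @property
    def size(self) -> int:
        return len(self.leaf_set)

    def vectors(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.aligned["len_a"].to_numpy(dtype=float),
            self.aligned["len_b"].to_numpy(dtype=float),
        )


def _postorder(root: TreeNode):
    order = []

    def walk(node):
        for c in node.children:
            walk(c)
        order.append(node)

    walk(root)
    return order


def _mast_dp(root_a: TreeNode, root_b: TreeNode):
    """Classical rooted-MAST DP; returns (size, leaf set) deterministically.

    At an internal/internal pair the candidates are the maximum-weight
    assignment between child subtrees and the diagonal descents into either
    tree; ties prefer the assignment case, then descent into the first tree,
    matching a fixed, documented tie-break.
    """
    nodes_a = _postorder(root_a)
    nodes_b = _postorder(root_b)
    ia = {id(n): i for i, n in enumerate(nodes_a)}
    ib = {id(n): i for i, n in enumerate(nodes_b)}
    leafset_a = [frozenset(_leafset(n)) for n in nodes_a]
    leafset_b = [frozenset(_leafset(n)) for n in nodes_b]
    m = np.zeros((len(nodes_a), len(nodes_b)), dtype=int)

    def value(a: TreeNode, b: TreeNode) -> int:
        return m[ia[id(a)], ib[id(b)]]

    def match_case(a: TreeNode, b: TreeNode):
        w = np.array(
            [[value(ca, cb) for cb in b.children] for ca in a.children]
        )
        rows, cols = linear_sum_assignment(w, maximize=True)
        return int(w[rows, cols].sum()), list(zip(rows, cols))

    for i, a in enumerate(nodes_a):
        for j, b in enumerate(nodes_b):
            if a.is_leaf and b.is_leaf:
                m[i, j] = int(a.label == b.label)
            elif a.is_leaf:
                m[i, j] = int(a.label in leafset_b[j])
            elif b.is_leaf:
                m[i, j] = int(b.label in leafset_a[i])
            else:
                best, _ = match_case(a, b)
                for ca in a.children:
                    best = max(best, value(ca, b))
                for cb in b.children:
                    best = max(best, value(a, cb))
                m[i, j] = best

    def rebuild(a: TreeNode, b: TreeNode) -> frozenset:
        v = value(a, b)
        if v == 0:
            return frozenset()
        if a.is_leaf:
            return frozenset([a.label])
        if b.is_leaf:
            return frozenset([b.label])
        mv, pairs = match_case(a, b)
        if mv == v:
            return frozenset().union(
                *(
                    rebuild(a.children[r], b.children[c])
                    for r, c in pairs
                    if value(a.children[r], b.children[c]) > 0
                )
            )
        for ca in a.children:
            if value(ca, b) == v:
                return rebuild(ca, b)
        for cb in b.children:
            if value(a, cb) == v:
                return rebuild(a, cb)
        raise AssertionError("inconsistent MAST backtrack")

    size = int(m[ia[id(root_a)], ib[id(root_b)]])
    return size, rebuild(root_a, root_b)


def _empty_result(t1: GeneTree, t2: GeneTree) -> MastResult:
    return MastResult(
        tree_a=t1.id,
        tree_b=t2.id,
        leaf_set=frozenset(),
        aligned=pd.DataFrame(columns=["edge", "len_a", "len_b"]),
    )


def mast_pair(t1: GeneTree, t2: GeneTree, outgroup: str | None = None) -> MastResult:
    """Maximum agreement subtree of two gene trees, with aligned lengths.

    Both trees are rooted at ``outgroup`` (default: lexicographically
    smallest shared leaf) and the rooted MAST is computed by dynamic
    programming; the induced trees on the agreement set are then reduced to
    per-split path lengths and aligned by split identity.  No shared leaves
    yield an empty result (the pair is skipped downstream).
    """
    shared = t1.leaf_labels() & t2.leaf_labels()
    if not shared:
        return _empty_result(t1, t2)
    if outgroup is None:
        outgroup = min(shared)
    elif outgroup not in shared:
        raise ValueError(f"outgroup {outgroup!r} not shared by both trees")
    if len(shared) == 1:
        return MastResult(
            tree_a=t1.id,
            tree_b=t2.id,
            leaf_set=frozenset(shared),
            aligned=pd.DataFrame(columns=["edge", "len_a", "len_b"]),
        )

    r1 = reroot_at_leaf(restrict_to(t1, shared), outgroup)
    r2 = reroot_at_leaf(restrict_to(t2, shared), outgroup)
    _, leaf_set = _mast_dp(r1.root, r2.root)
    if len(leaf_set) < 2:
        return MastResult(
            tree_a=t1.id, tree_b=t2.id, leaf_set=leaf_set,
            aligned=pd.DataFrame(columns=["edge", "len_a", "len_b"]),
        )

    m1 = clade_lengths(restrict_to(r1, leaf_set))
    m2 = clade_lengths(restrict_to(r2, leaf_set))
    if set(m1) != set(m2):
        raise AssertionError(
            f"induced topologies disagree on the computed agreement set "
            f"for pair ({t1.id}, {t2.id})"
        )
    keys = sorted(m1, key=lambda s: (len(s), tuple(sorted(s))))
    aligned = pd.DataFrame(
        {
            "edge": ["|".join(sorted(k)) for k in keys],
            "len_a": [m1[k] for k in keys],
            "len_b": [m2[k] for k in keys],
        }
    )
    return MastResult(tree_a=t1.id, tree_b=t2.id, leaf_set=leaf_set, aligned=aligned)


def is_agreement_subset(
    t1: GeneTree, t2: GeneTree, leaves, outgroup: str | None = None
) -> bool:
    """Do the two trees induce the same rooted topology on this leaf set?

    Uses the same rooting convention as :func:`mast_pair` (outgroup defaults
    to the smallest shared leaf of the *full* trees) so it serves as the
    brute-force oracle for the DP.
    """
    shared = t1.leaf_labels() & t2.leaf_labels()
    leaves = set(leaves)
    if not leaves <= shared:
        return False
    if len(leaves) <= 1:
        return True
    if outgroup is None:
        outgroup = min(shared)
    r1 = reroot_at_leaf(restrict_to(t1, shared), outgroup)
    r2 = reroot_at_leaf(restrict_to(t2, shared), outgroup)
    try:
        # rooted comparison: do NOT merge the root split, or rootedness is
        # lost whenever the outgroup is outside the tested leaf set
        k1 = set(clade_lengths(restrict_to(r1, leaves), merge_root_split=False))
        k2 = set(clade_lengths(restrict_to(r2, leaves), merge_root_split=False))
    except ValueError:
        return False
    return k1 == k2


def pair_filter(results: Mapping, min_leaves: int = 10) -> list:
    """Keys of pairs whose MAST has at least ``min_leaves`` leaves."""
    if min_leaves < 3:
        raise ValueError("min_leaves must be >= 3")
    return [key for key, res in results.items() if res.size >= min_leaves]


def aligned_vectors(results: Mapping, min_leaves: int = 10) -> dict:
    """Aligned MAST edge-length vectors for the retained pairs."""
    out = {}
    for key in pair_filter(results, min_leaves):
        res = results[key]
        out[(res.tree_a, res.tree_b)] = res.vectors()
    return out
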