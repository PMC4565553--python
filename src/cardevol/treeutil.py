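"""Tree utilities shared by the likelihood, reconstruction and rooting code.

Public trees are ``dendropy.Tree`` objects (Newick dialect: unrooted trees
are stored with an arbitrary trifurcating root; internal labels, if present,
are preserved).  ``LinearTree`` is a post-order array view used by the
numerical routines; internal nodes are identified externally by the frozenset
of their descendant leaf labels ("clades"), which is stable across tools and
topologies.
"""

from __future__ import annotations

import dendropy
import numpy as np

__all__ = [
    "parse_tree",
    "tree_to_newick",
    "clone_tree",
    "LinearTree",
    "leafset",
    "find_branch_node",
    "bipartition_lengths",
]


def parse_tree(source) -> dendropy.Tree:
    """Parse a Newick tree from a string or a path."""
    text = str(source)
    if "(" in text:
        return dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    return dendropy.Tree.get(path=text, schema="newick",
                             preserve_underscores=True)


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def leafset(node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


class LinearTree:
    """Post-order array view of a dendropy tree.

    Node ``i`` has parent ``parent[i]`` (-1 for the root, which is the last
    node), branch length ``lengths[i]`` on the edge to its parent, children
    ``children[i]``, and descendant leaf labels ``leafsets[i]``.
    """

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        self.tree = tree
        self.nodes = nodes
        self.n_nodes = n
        self.root = n - 1
        self.parent = np.full(n, -1, dtype=int)
        self.lengths = np.zeros(n)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.labels: list[str | None] = [None] * n
        self.leafsets: list[frozenset] = [frozenset()] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
            if nd.edge.length is not None:
                self.lengths[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None:
                    raise ValueError("leaf without a taxon label")
                self.labels[i] = nd.taxon.label
                self.leafsets[i] = frozenset([nd.taxon.label])
            else:
                self.leafsets[i] = frozenset().union(
                    *(self.leafsets[c] for c in self.children[i])
                )
        self.leaf_indices = [i for i in range(n) if not self.children[i]]
        self.internal_indices = [i for i in range(n) if self.children[i]]
        self.taxon_labels = frozenset(self.labels[i] for i in self.leaf_indices)

    def clades(self) -> dict[frozenset, int]:
        """Internal-node index keyed by descendant leaf set."""
        return {self.leafsets[i]: i for i in self.internal_indices}

    def branch_nodes(self):
        """Indices of nodes that subtend a branch (everything but the root)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    def write_lengths_back(self) -> None:
        """Push ``self.lengths`` back onto the dendropy tree's edges."""
        for i, nd in enumerate(self.nodes):
            if self.parent[i] >= 0:
                nd.edge.length = float(self.lengths[i])

    def total_length(self) -> float:
        return float(self.lengths[[i for i in range(self.n_nodes)
                                   if self.parent[i] >= 0]].sum())


def find_branch_nodes(lin: LinearTree, clade) -> list[int]:
    """All branches (by the node below each) whose leaf-set bipartition
    matches ``clade`` — the given side or its complement.

    A single unrooted branch can correspond to several edges of a rooted
    tree: both root-adjacent edges when the root lies on the branch, plus
    any degree-2 chain created by rerooting.  All of them are returned so
    the unrooted branch is treated as one unit regardless of rooting.
    """
    target = frozenset(clade)
    complement = lin.taxon_labels - target
    hits = [
        i for i in range(lin.n_nodes)
        if i != lin.root
        and (lin.leafsets[i] == target or lin.leafsets[i] == complement)
    ]
    if not hits:
        raise ValueError(f"no branch with bipartition {sorted(target)}")
    return hits


def find_branch_node(lin: LinearTree, clade) -> int:
    """First branch matching the bipartition (see ``find_branch_nodes``)."""
    return find_branch_nodes(lin, clade)[0]


def bipartition_lengths(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Branch lengths keyed by the (unrooted) bipartition each edge induces,
    normalized to the side not containing the alphabetically first taxon.
    Used to compare trees irrespective of rooting and node order."""
    lin = LinearTree(tree)
    anchor = min(lin.taxon_labels)
    out: dict[frozenset, float] = {}
    for i in lin.branch_nodes():
        side = lin.leafsets[i]
        if anchor in side:
            side = lin.taxon_labels - side
        if not side:  # edge to the root in a rooted tree
            continue
        out[side] = out.get(side, 0.0) + lin.lengths[i]
    return out
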