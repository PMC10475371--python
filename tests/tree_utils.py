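"""Random additive trees and edge-map comparison for NJ tests.

A random unrooted binary tree is grown by repeatedly joining two
random active subtrees; leaf-to-leaf path lengths give an exactly
additive distance matrix, the independent truth NJ must recover.
Trees are compared as maps bipartition -> branch length, which is
invariant to the placement of the trifurcating root.
"""

import numpy as np

from herdgen.clustering import TreeNode
from herdgen.relatedness import DistanceMatrix


def random_binary_tree(n_leaves, rng, min_len=0.1, max_len=2.0):
    nodes = [TreeNode(label=f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a = nodes.pop(j)
        b = nodes.pop(i)
        nodes.append(
            TreeNode(children=[(a, float(rng.uniform(min_len, max_len))),
                               (b, float(rng.uniform(min_len, max_len)))])
        )
    root = TreeNode(
        children=[(nd, float(rng.uniform(min_len, max_len))) for nd in nodes]
    )
    return root


def leaf_distances(tree):
    """Exact path-length distance matrix between all leaves."""
    labels = sorted(tree.leaf_labels())
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n))

    def depths(node, acc):
        if node.is_leaf():
            return {node.label: acc}
        out = {}
        for child, length in node.children:
            out.update(depths(child, acc + length))
        return out

    def walk(node):
        # combine leaf depths across child subtrees at this node
        sub = []
        for child, length in node.children:
            sub.append(depths(child, length))
            walk(child)
        for a in range(len(sub)):
            for b in range(a + 1, len(sub)):
                for la, da in sub[a].items():
                    for lb, db in sub[b].items():
                        D[idx[la], idx[lb]] = D[idx[lb], idx[la]] = da + db

    walk(tree)
    return DistanceMatrix(values=D, labels=labels)


def edge_map(tree, all_leaves):
    """Map canonical bipartition -> branch length (root edges merged).

    For the trifurcating root the three edges are genuine edges of the
    unrooted tree; every (parent, child) edge is keyed by the smaller
    side of the leaf bipartition it induces.
    """
    all_leaves = frozenset(all_leaves)
    edges = {}

    def side_key(leaves):
        side = frozenset(leaves)
        other = all_leaves - side
        return min(side, other, key=lambda s: (len(s), sorted(s)))

    def walk(node):
        for child, length in node.children:
            below = frozenset(child.leaf_labels())
            key = side_key(below)
            edges[key] = edges.get(key, 0.0) + length
            walk(child)

    walk(tree)
    return edges
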