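"""Independent brute-force oracles used to validate the library.

These deliberately avoid the library's vectorized code paths: distances are
summed edge-by-edge along explicit root paths, and unweighted PD/MPD/VPD are
computed from first principles.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np


def root_path(node: dendropy.Node) -> list[dendropy.Node]:
    path = []
    while node is not None:
        path.append(node)
        node = node.parent_node
    return path


def path_sum_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Patristic distance by explicit path enumeration."""
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    pa, pb = root_path(leaves[a]), root_path(leaves[b])
    ids_b = {id(n): i for i, n in enumerate(pb)}
    for i, n in enumerate(pa):
        if id(n) in ids_b:  # first common ancestor
            up = pa[:i]
            down = pb[: ids_b[id(n)]]
            return sum(x.edge.length or 0.0 for x in up + down)
    raise AssertionError("no common ancestor found")


def branch_length_sum(tree: dendropy.Tree) -> float:
    """Unweighted Faith's PD of a whole tree: sum of all branch lengths."""
    return sum(
        nd.edge.length or 0.0
        for nd in tree.preorder_node_iter()
        if nd is not tree.seed_node
    )


def pairwise_values(tree: dendropy.Tree) -> list[float]:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    return [
        path_sum_distance(tree, a, b) for a, b in itertools.combinations(labels, 2)
    ]


def plain_mpd(tree: dendropy.Tree) -> float:
    return float(np.mean(pairwise_values(tree)))


def plain_vpd(tree: dendropy.Tree) -> float:
    """Population variance of the pairwise distances."""
    return float(np.var(pairwise_values(tree)))
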