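"""Conversions between :class:`RootedTree` objects and flat kernel arrays."""

from __future__ import annotations

import numpy as np

from .trees import Node, RootedTree


def tree_to_arrays(tree: RootedTree, tip_order: list[str]):
    """Encode a binary rooted tree with ages as (parent, child0, child1, age).

    Tips receive indices by position in ``tip_order``; internal nodes are
    numbered ``n..2n-2`` in postorder.
    """
    n = len(tip_order)
    index = {label: i for i, label in enumerate(tip_order)}
    N = 2 * n - 1
    parent = np.full(N, -1, np.int64)
    child0 = np.full(N, -1, np.int64)
    child1 = np.full(N, -1, np.int64)
    age = np.zeros(N, np.float64)
    nxt = [n]
    idx: dict[int, int] = {}

    for node in tree.postorder():
        if node.is_tip:
            i = index[node.label]
        else:
            i = nxt[0]
            nxt[0] += 1
            c0, c1 = node.children
            child0[i] = idx[id(c0)]
            child1[i] = idx[id(c1)]
            parent[idx[id(c0)]] = i
            parent[idx[id(c1)]] = i
        idx[id(node)] = i
        age[i] = node.age if node.age is not None else 0.0
    return parent, child0, child1, age


def arrays_to_tree(parent, child0, child1, age, tip_labels: list[str]) -> RootedTree:
    N = parent.shape[0]
    n = (N + 1) // 2
    nodes = [Node(tip_labels[i] if i < n else None, age=float(age[i])) for i in range(N)]
    root = None
    for i in range(N):
        if parent[i] < 0 and (i >= n or N == 1):
            root = nodes[i]
        if child0[i] >= 0:
            nodes[i].add_child(nodes[child0[i]])
            nodes[i].add_child(nodes[child1[i]])
    tree = RootedTree(root)
    tree.lengths_from_ages()
    return tree
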