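"""Rooted phylogenetic trees with node ages or branch lengths.

The internal representation is a plain parent/child node structure.  Clock
trees (simulated gene trees, species trees, MCMC samples) carry node *ages*
measured in expected substitutions per site, with tips at age 0; unrooted
maximum-likelihood trees carry per-branch *lengths*.  Conversions between the
two are explicit (:meth:`RootedTree.ages_from_lengths`,
:meth:`RootedTree.lengths_from_ages`), never implicit.

Newick text is parsed with :mod:`dendropy` and re-serialised by this module in
a canonical form (children ordered by their lexicographically smallest
descendant tip), which makes topology comparison, hashing and tie-breaking
deterministic.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "Node",
    "RootedTree",
    "parse_newick",
    "write_newick",
    "clades",
    "recovery_frequency",
    "modal_topology",
    "midpoint_root",
    "population_tree",
]


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree operations."""


class Node:
    __slots__ = ("label", "children", "parent", "length", "age")

    def __init__(self, label=None, length=None, age=None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length  # branch length above this node
        self.age = age  # node age (clock trees); tips at 0

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or '(internal)'}>"


class RootedTree:
    """A rooted tree over uniquely labelled tips.

    Internal nodes are binary except, optionally, a trifurcating root used to
    represent an unrooted topology (``allow_unrooted=True`` on validation).
    """

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------
    # traversal / basic queries
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_tip]

    def n_tips(self) -> int:
        return sum(1 for n in self.postorder() if n.is_tip)

    def validate(self, allow_unrooted: bool = False) -> None:
        labels = self.tip_labels()
        if len(labels) < 2:
            raise TreeError("tree must have at least 2 tips")
        if len(set(labels)) != len(labels):
            dup = [l for l, c in Counter(labels).items() if c > 1]
            raise TreeError(f"duplicate tip labels: {dup}")
        for node in self.postorder():
            if node.is_tip:
                continue
            k = len(node.children)
            if k == 2:
                continue
            if k == 3 and node is self.root and allow_unrooted:
                continue
            raise TreeError(
                f"non-binary internal node with {k} children"
                + (" (root)" if node is self.root else "")
            )
        # parent age strictly greater than child age when ages present
        for node in self.postorder():
            if node.parent is not None and node.age is not None and node.parent.age is not None:
                if not node.parent.age > node.age:
                    raise TreeError(
                        f"parent age {node.parent.age} not greater than child age {node.age}"
                    )

    # ------------------------------------------------------------------
    # age / length conversions
    def has_ages(self) -> bool:
        return all(n.age is not None for n in self.postorder())

    def has_lengths(self) -> bool:
        return all(n.length is not None for n in self.postorder() if n.parent is not None)

    def lengths_from_ages(self) -> None:
        for node in self.postorder():
            if node.parent is not None:
                node.length = node.parent.age - node.age

    def ages_from_lengths(self, rel_tol: float = 1e-6) -> None:
        """Set node ages from branch lengths; requires an ultrametric tree."""
        depth = {self.root: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                depth[node] = depth[node.parent] + (node.length or 0.0)
        height = max(depth[t] for t in self.tips())
        tol = rel_tol * max(height, 1.0)
        for t in self.tips():
            if abs(depth[t] - height) > tol:
                raise TreeError("tree is not ultrametric; cannot assign ages")
        for node in self.postorder():
            node.age = 0.0 if node.is_tip else height - depth[node]

    # ------------------------------------------------------------------
    def copy(self) -> "RootedTree":
        def rec(node: Node) -> Node:
            new = Node(node.label, node.length, node.age)
            for c in node.children:
                new.add_child(rec(c))
            return new

        return RootedTree(rec(self.root))

    def clade(self, node: Node) -> frozenset:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n.label)
            stack.extend(n.children)
        return frozenset(out)

    def mrca(self, labels: Iterable[str]) -> Node:
        want = frozenset(labels)
        missing = want - frozenset(self.tip_labels())
        if missing:
            raise TreeError(f"tips not on tree: {sorted(missing)}")
        best = None
        for node in self.postorder():
            if want <= self.clade(node):
                best = node
                break  # postorder: first containing node is the MRCA
        return best

    # ------------------------------------------------------------------
    # canonical form
    def canonicalise(self) -> None:
        """Order children by their lexicographically smallest descendant tip."""
        mintip: dict[Node, str] = {}
        for node in self.postorder():
            if node.is_tip:
                mintip[node] = node.label
            else:
                node.children.sort(key=lambda c: mintip[c])
                mintip[node] = mintip[node.children[0]]

    def newick(self, lengths: bool = True, fmt: str = "%.10g") -> str:
        return write_newick(self, lengths=lengths, fmt=fmt)

    def canonical_newick(self, lengths: bool = False, fmt: str = "%.10g") -> str:
        t = self.copy()
        t.canonicalise()
        return write_newick(t, lengths=lengths, fmt=fmt)

    def topology_key(self) -> str:
        return self.canonical_newick(lengths=False)

    def __repr__(self):  # pragma: no cover
        return f"RootedTree({self.canonical_newick(lengths=False)})"


# ----------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str, rooted: bool = True) -> RootedTree:
    """Parse a Newick string into a :class:`RootedTree`.

    With ``rooted=True`` (default) every internal node must be binary; with
    ``rooted=False`` a trifurcating root (the usual representation of an
    unrooted tree) is also accepted.  If branch lengths are present and the
    tree is ultrametric, node ages are filled in as well.
    """
    if not isinstance(text, str) or not text.strip():
        raise TreeError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy reports the offending position
        raise TreeError(f"malformed Newick: {exc}") from exc

    def rec(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else None
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(rec(child))
        return node

    tree = RootedTree(rec(dtree.seed_node))
    tree.validate(allow_unrooted=not rooted)
    if tree.has_lengths():
        try:
            tree.ages_from_lengths()
        except TreeError:
            pass  # non-clock tree: keep lengths only
    return tree


def write_newick(tree: RootedTree, lengths: bool = True, fmt: str = "%.10g") -> str:
    use_lengths = lengths and (tree.has_lengths() or tree.has_ages())
    if use_lengths and not tree.has_lengths():
        tree = tree.copy()
        tree.lengths_from_ages()

    def rec(node: Node) -> str:
        if node.is_tip:
            s = node.label
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
        if use_lengths and node.parent is not None:
            s += ":" + (fmt % (node.length if node.length is not None else 0.0))
        return s

    return rec(tree.root) + ";"


# ----------------------------------------------------------------------
# clade operations


def clades(tree: RootedTree, include_root: bool = True) -> set[frozenset]:
    """The set of tip-label sets, one per internal node (root included)."""
    out = set()
    for node in tree.internal_nodes():
        if node is tree.root and not include_root:
            continue
        out.add(tree.clade(node))
    return out


def recovery_frequency(
    true_tree: RootedTree, inferred: Sequence[RootedTree]
) -> dict[frozenset, float]:
    """Fraction of inferred trees containing each non-root clade of the true tree."""
    if not inferred:
        raise TreeError("no inferred trees given")
    tipset = frozenset(true_tree.tip_labels())
    for t in inferred:
        if frozenset(t.tip_labels()) != tipset:
            raise TreeError("inferred tree has a different tip set")
    target = clades(true_tree, include_root=False)
    counts = {c: 0 for c in target}
    for t in inferred:
        have = clades(t)
        for c in target:
            if c in have:
                counts[c] += 1
    return {c: counts[c] / len(inferred) for c in target}


def modal_topology(samples: Sequence[RootedTree], burn_in_fraction: float = 0.0) -> RootedTree:
    """Most frequently sampled topology among post-burn-in samples.

    Node ages of the returned tree are the per-clade means over the samples of
    the winning topology (when samples carry ages).  Ties between topologies
    are broken towards the lexicographically smallest canonical Newick string.
    """
    if not 0.0 <= burn_in_fraction < 1.0:
        raise TreeError("burn_in_fraction must be in [0, 1)")
    kept = list(samples)[int(len(samples) * burn_in_fraction):]
    if not kept:
        raise TreeError("no samples left after burn-in")
    groups: dict[str, list[RootedTree]] = defaultdict(list)
    for t in kept:
        groups[t.topology_key()].append(t)
    best_count = max(len(v) for v in groups.values())
    best = min(k for k, v in groups.items() if len(v) == best_count)
    members = groups[best]
    result = parse_newick(best)
    if all(t.has_ages() for t in members):
        mean_age: dict[frozenset, float] = {}
        for node in result.internal_nodes():
            c = result.clade(node)
            mean_age[c] = float(np.mean([t.mrca(c).age for t in members]))
        for node in result.postorder():
            node.age = 0.0 if node.is_tip else mean_age[result.clade(node)]
        result.lengths_from_ages()
    return result


# ----------------------------------------------------------------------
# midpoint rooting


def midpoint_root(tree: RootedTree) -> RootedTree:
    """Root an unrooted tree at the midpoint of its longest tip-to-tip path.

    The input may be a binary rooted tree (its degree-2 root is suppressed) or
    a tree with a trifurcating root.  Ties for the longest path — including
    the all-zero branch length case — are broken towards the lexicographically
    smallest tip pair, and a midpoint falling exactly on a node is placed on
    the edge nearer the first tip of that pair.
    """
    tree.validate(allow_unrooted=True)
    if not tree.has_lengths():
        raise TreeError("midpoint rooting requires branch lengths")
    for node in tree.postorder():
        if node.parent is not None and node.length < 0:
            raise TreeError("negative branch length")

    # unrooted adjacency; suppress a degree-2 root
    adj: dict[Node, list[tuple[Node, float]]] = defaultdict(list)
    for node in tree.postorder():
        if node.parent is not None:
            adj[node].append((node.parent, node.length))
            adj[node.parent].append((node, node.length))
    root = tree.root
    if len(root.children) == 2:
        a, b = root.children
        merged = a.length + b.length
        adj[a] = [(n, l) for n, l in adj[a] if n is not root] + [(b, merged)]
        adj[b] = [(n, l) for n, l in adj[b] if n is not root] + [(a, merged)]
        del adj[root]

    tips = sorted((n for n in adj if n.is_tip), key=lambda n: n.label)
    if len(tips) < 2:
        raise TreeError("midpoint rooting needs at least 2 tips")

    def paths_from(src: Node) -> dict[Node, tuple[float, Node | None]]:
        dist = {src: (0.0, None)}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, l in adj[u]:
                if v not in dist:
                    dist[v] = (dist[u][0] + l, u)
                    stack.append(v)
        return dist

    best = None  # (distance, label_a, label_b, tip_a, dist_map)
    for a in tips:
        dist = paths_from(a)
        for b in tips:
            if b.label <= a.label:
                continue
            d = dist[b][0]
            key = (-d, a.label, b.label)
            if best is None or key < best[0]:
                best = (key, a, b, dist)
    _, a, b, dist = best
    total = dist[b][0]

    # walk back from b to a, collecting the path
    path = [b]
    while path[-1] is not a:
        path.append(dist[path[-1]][1])
    path.reverse()  # a ... b
    half = total / 2.0
    cum = 0.0
    u = path[0]
    for v in path[1:]:
        edge = next(l for n, l in adj[u] if n is v)
        if cum + edge >= half or v is path[-1]:
            break
        cum += edge
        u = v
    # root on edge (u, v), at distance (half - cum) from u
    offset_u = half - cum
    offset_v = edge - offset_u

    new_root = Node()
    visited = {id(new_root)}

    def build(node: Node, came_from: Node | None, length: float, parent: Node) -> None:
        fresh = Node(node.label, length=length)
        parent.add_child(fresh)
        for nbr, l in adj[node]:
            if nbr is came_from:
                continue
            build(nbr, node, l, fresh)

    build(u, v, offset_u, new_root)
    build(v, u, offset_v, new_root)
    out = RootedTree(new_root)
    out.validate()
    return out


# ----------------------------------------------------------------------
# population-level topology extraction


def population_tree(tree: RootedTree, popmap: dict[str, str]) -> RootedTree:
    """Collapse each (monophyletic) population of a sequence tree to a tip.

    ``popmap`` maps sequence labels to population labels.  Raises
    :class:`TreeError` if some population is not monophyletic on ``tree``.
    """
    pops: dict[str, frozenset] = {}
    grouped = defaultdict(set)
    for seq, pop in popmap.items():
        grouped[pop].add(seq)
    for pop, members in grouped.items():
        pops[pop] = frozenset(members)
    missing = frozenset(popmap) - frozenset(tree.tip_labels())
    if missing:
        raise TreeError(f"sequences not on tree: {sorted(missing)}")
    for pop, members in pops.items():
        if tree.clade(tree.mrca(members)) != members:
            raise TreeError(f"population {pop} not monophyletic on tree")

    def rec(node: Node) -> Node:
        cl = tree.clade(node)
        for pop, members in pops.items():
            if cl == members:
                return Node(pop)
        new = Node()
        for c in node.children:
            new.add_child(rec(c))
        return new

    out = RootedTree(rec(tree.root))
    out.validate()
    return out
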