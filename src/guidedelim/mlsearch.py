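"""Constrained maximum-likelihood guide trees from the mitochondrial locus.

The ML arm of the study mimics standard ML phylogenetics practice: an unrooted gene tree
is estimated from the single mitochondrial alignment with the sequences of
each population constrained to be monophyletic, the tree is midpoint rooted,
and the population-level rooted topology is extracted as the guide tree.
The substitution model is JC69 (the model the data are simulated under).

Search strategy: neighbour joining on JC-corrected distances builds the
population-level backbone and average-linkage (UPGMA) trees resolve each
population's subtree; branch lengths are then optimised by exact coordinate
ascent (each branch has a 1-D profile likelihood that is solved for its
stationary point), and nearest-neighbour interchanges restricted to backbone
edges — which provably preserve the monophyly constraints — hill-climb to a
local ML optimum.  Everything is deterministic given the data.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from collections import defaultdict

import numpy as np
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
import skbio

from .seqio import Alignment, compress_patterns
from .trees import Node, RootedTree, TreeError, midpoint_root, parse_newick, population_tree

__all__ = ["MlSearchConfig", "ml_guide_tree", "optimize_branch_lengths",
           "jc_distance_matrix"]

_MAX_BRANCH = 8.0  # cap for saturated distances / branch lengths


@dataclass(frozen=True)
class MlSearchConfig:
    """Settings for the constrained ML search."""

    tolerance: float = 1e-4      # log-likelihood improvement to keep sweeping
    max_sweeps: int = 12         # branch-length sweeps per optimisation call
    max_nni_rounds: int = 12     # hill-climbing rounds over backbone edges

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


# ----------------------------------------------------------------------
# distances and starting trees


def jc_distance_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise JC69 distances d = -(3/4) ln(1 - 4p/3), capped when saturated."""
    X = aln.data
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = (X[i] != X[i + 1:]).mean(axis=1)
        arg = 1.0 - 4.0 * diff / 3.0
        d = np.where(arg > 1e-8, -0.75 * np.log(np.maximum(arg, 1e-8)), _MAX_BRANCH)
        D[i, i + 1:] = np.minimum(d, _MAX_BRANCH)
    return D + D.T


def _upgma_subtree(labels: list[str], D: np.ndarray) -> Node:
    """Rooted average-linkage subtree over ``labels`` (ultrametric heights/2)."""
    if len(labels) == 1:
        return Node(labels[0], length=0.0)
    Z = average(squareform(D, checks=False))
    nodes = [Node(l) for l in labels]
    heights = [0.0] * len(labels)
    for a, b, h, _ in Z:
        parent = Node()
        for k in (int(a), int(b)):
            nodes[k].length = h / 2.0 - heights[k]
            parent.add_child(nodes[k])
        nodes.append(parent)
        heights.append(h / 2.0)
    return nodes[-1]


def _nj_backbone(pop_labels: list[str], D: np.ndarray) -> RootedTree:
    """Unrooted neighbour-joining tree over populations (trifurcating root)."""
    if len(pop_labels) == 2:
        root = Node()
        for i, l in enumerate(pop_labels):
            root.add_child(Node(l, length=max(D[0, 1] / 2.0, 0.0)))
        return RootedTree(root)
    dm = skbio.DistanceMatrix(D, ids=pop_labels)
    njt = skbio.tree.nj(dm)
    newick = str(njt).strip()
    tree = parse_newick(newick, rooted=False)
    _unroot_in_place(tree)
    for node in tree.postorder():  # NJ can yield tiny negative lengths
        if node.parent is not None and (node.length is None or node.length < 0):
            node.length = 0.0
    return tree


def _unroot_in_place(tree: RootedTree) -> None:
    """Convert a binary-root representation to a trifurcating root."""
    root = tree.root
    if len(root.children) != 2:
        return
    a, b = root.children
    if a.is_tip and b.is_tip:
        return
    keep, other = (a, b) if not a.is_tip else (b, a)
    other.length = (other.length or 0.0) + (keep.length or 0.0)
    keep.parent = None
    keep.length = None
    keep.add_child(other)
    tree.root = keep


# ----------------------------------------------------------------------
# likelihood machinery on an (unrooted) tree with arbitrary root degree


class _MLState:
    """Caches for coordinate-ascent branch optimisation on one topology."""

    def __init__(self, tree: RootedTree, tipdata: np.ndarray, weights: np.ndarray,
                 labels: list[str]):
        self.tree = tree
        self.weights = weights
        idx = {l: i for i, l in enumerate(labels)}
        self.nodes = list(tree.postorder())
        self.down: dict[int, np.ndarray] = {}
        self.M: dict[int, np.ndarray] = {}
        P = tipdata.shape[1]
        self.onehot = np.zeros((len(labels), P, 4))
        for i in range(len(labels)):
            self.onehot[i, np.arange(P), tipdata[i]] = 1.0
        self.tip_index = idx

    def _down_of(self, node: Node) -> np.ndarray:
        if node.is_tip:
            return self.onehot[self.tip_index[node.label]]
        return self.down[id(node)]

    def _edge_M(self, node: Node) -> np.ndarray:
        d = self._down_of(node)
        e = math.exp(-4.0 * (node.length or 0.0) / 3.0)
        S = d.sum(axis=1, keepdims=True)
        return 0.25 * (1.0 - e) * S + e * d

    def down_pass(self) -> None:
        for node in self.nodes:
            if node.is_tip:
                continue
            prod = None
            for c in node.children:
                m = self._edge_M(c)
                self.M[id(c)] = m
                prod = m if prod is None else prod * m
            self.down[id(node)] = prod

    def loglik(self) -> float:
        L = 0.25 * self.down[id(self.tree.root)].sum(axis=1)
        return float(self.weights @ np.log(np.maximum(L, 1e-300)))

    # -- exact 1-D branch optimisation --------------------------------
    @staticmethod
    def _solve_edge(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
        """Maximise sum w log(a + b e) over e in (0, 1]; returns optimal e."""

        def deriv(e):
            return float(np.sum(w * b / np.maximum(a + b * e, 1e-300)))

        if deriv(1.0) >= 0.0:
            return 1.0
        e_min = math.exp(-4.0 * _MAX_BRANCH / 3.0)
        if deriv(e_min) <= 0.0:
            return e_min
        lo, hi = e_min, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if deriv(mid) > 0.0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def optimize_edges(self, subset: set[int] | None = None) -> None:
        """One preorder sweep of exact per-edge optimisation.

        Caches are updated along the walk, so each edge sees exact
        conditionals and the likelihood cannot decrease.
        """
        self.down_pass()
        root = self.tree.root
        out: dict[int, np.ndarray] = {}

        stack = [(c, root) for c in reversed(root.children)]
        while stack:
            node, parent = stack.pop()
            if parent is root:
                o = np.full_like(self.M[id(node)], 0.25)
            else:
                o = out[id(parent)].copy()
            for s in parent.children:
                if s is not node:
                    o = o * self.M[id(s)]
            if subset is None or id(node) in subset:
                d = self._down_of(node)
                Sd = d.sum(axis=1)
                So = o.sum(axis=1)
                dot = (o * d).sum(axis=1)
                a = 0.25 * Sd * So
                b = dot - a
                e = self._solve_edge(a, b, self.weights)
                node.length = -0.75 * math.log(e)
                self.M[id(node)] = self._edge_M(node)
            # conditional "from above" at node, for its children
            e = math.exp(-4.0 * (node.length or 0.0) / 3.0)
            So = o.sum(axis=1, keepdims=True)
            out[id(node)] = 0.25 * (1.0 - e) * So + e * o
            for c in reversed(node.children):
                stack.append((c, node))
        self.down_pass()


def _optimize(tree: RootedTree, tipdata, weights, labels, cfg: MlSearchConfig,
              sweeps: int | None = None, subset: set[int] | None = None) -> float:
    st = _MLState(tree, tipdata, weights, labels)
    st.down_pass()
    cur = st.loglik()
    for _ in range(sweeps if sweeps is not None else cfg.max_sweeps):
        st.optimize_edges(subset)
        new = st.loglik()
        if new - cur < cfg.tolerance:
            cur = max(new, cur)
            break
        cur = new
    return cur


def optimize_branch_lengths(tree: RootedTree, aln: Alignment,
                            cfg: MlSearchConfig = MlSearchConfig()) -> tuple[RootedTree, float]:
    """ML branch lengths on a fixed topology under JC69.

    Returns a copy of the tree with optimised lengths and its log-likelihood.
    Lengths are non-negative; coordinate sweeps stop once the improvement
    falls below the configured tolerance.
    """
    if set(tree.tip_labels()) != set(aln.labels):
        raise TreeError("tree tips and alignment labels do not match")
    work = tree.copy()
    for node in work.postorder():
        if node.parent is not None and (node.length is None or node.length < 0):
            node.length = 0.05
    tipdata, weights = compress_patterns(aln)
    ll = _optimize(work, tipdata, weights, aln.labels, cfg)
    return work, ll


# ----------------------------------------------------------------------
# constrained NNI search


def _population_clades(tree: RootedTree, popmap: dict[str, str]):
    """Internal nodes whose clade is a union of >= 2 complete populations.

    NNIs across these backbone edges rearrange whole populations and can
    never break the monophyly constraints.
    """
    members = defaultdict(set)
    for seq, pop in popmap.items():
        members[pop].add(seq)
    full = {pop: frozenset(m) for pop, m in members.items()}
    eligible = []
    for node in tree.internal_nodes():
        if node is tree.root:
            continue
        cl = tree.clade(node)
        pops = [p for p, m in full.items() if m <= cl]
        if len(pops) >= 2 and cl == frozenset().union(*(full[p] for p in pops)):
            eligible.append(node)
    return eligible


def _nni_neighbours(tree: RootedTree, node: Node):
    """The two NNI rearrangements across the edge above ``node``.

    Yields (child_of_node, sibling) pairs to swap; applied to a copied tree
    by the caller.
    """
    parent = node.parent
    siblings = [c for c in parent.children if c is not node]
    for c in node.children:
        for s in siblings:
            yield c, s
            break  # one sibling suffices: swapping with either gives the
            # same unrooted bipartition change when parent is binary
    # for a trifurcating root parent, both siblings give distinct topologies
    if len(siblings) == 2:
        for c in node.children:
            yield c, siblings[1]


def _apply_swap(tree: RootedTree, c: Node, s: Node) -> None:
    pc, ps = c.parent, s.parent
    pc.children[pc.children.index(c)] = s
    ps.children[ps.children.index(s)] = c
    c.parent, s.parent = ps, pc


def ml_guide_tree(mito: Alignment, popmap: dict[str, str],
                  cfg: MlSearchConfig = MlSearchConfig()) -> RootedTree:
    """Constrained ML tree for the mitochondrial locus, midpoint rooted and
    collapsed to the population level.

    Every population is constrained monophyletic throughout the search; the
    returned tree has one tip per population.  Deterministic given the data.
    """
    pops = sorted(set(popmap.values()))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    missing = set(mito.labels) - set(popmap)
    if missing:
        raise ValueError(f"sequences missing from population map: {sorted(missing)}")

    D = jc_distance_matrix(mito)
    li = {l: i for i, l in enumerate(mito.labels)}
    by_pop = defaultdict(list)
    for l in mito.labels:
        by_pop[popmap[l]].append(l)

    # population-mean distances -> NJ backbone
    Dpop = np.zeros((len(pops), len(pops)))
    for i, p in enumerate(pops):
        for j, q in enumerate(pops):
            if j <= i:
                continue
            rows = [li[x] for x in by_pop[p]]
            cols = [li[x] for x in by_pop[q]]
            Dpop[i, j] = Dpop[j, i] = D[np.ix_(rows, cols)].mean()
    backbone = _nj_backbone(pops, Dpop)

    # graft UPGMA subtrees in place of population tips
    for tip in backbone.tips():
        labels = by_pop[tip.label]
        sub = _upgma_subtree(labels, D[np.ix_([li[x] for x in labels],
                                              [li[x] for x in labels])])
        sub.length = tip.length if tip.length is not None else 0.01
        parent = tip.parent
        parent.children[parent.children.index(tip)] = sub
        sub.parent = parent
    full = RootedTree(backbone.root)
    full.validate(allow_unrooted=True)

    tipdata, weights = compress_patterns(mito)
    labels = mito.labels
    best_ll = _optimize(full, tipdata, weights, labels, cfg)

    # constrained NNI hill climbing (best-improvement per round)
    for _ in range(cfg.max_nni_rounds):
        best_move = None
        for node in _population_clades(full, popmap):
            for c, s in _nni_neighbours(full, node):
                saved = [(x, x.length) for x in (c, s, node, node.parent)
                         if x is not None]
                _apply_swap(full, c, s)
                around = {id(x) for x in (c, s, node)}
                if node.parent is not None:
                    around.add(id(node.parent))
                ll = _optimize(full, tipdata, weights, labels, cfg,
                               sweeps=2, subset=around)
                if best_move is None or ll > best_move[0]:
                    best_move = (ll, c, s)
                _apply_swap(full, s, c)  # undo (swap back)
                for x, length in saved:
                    x.length = length
        if best_move is None:
            break
        ll, c, s = best_move
        if ll <= best_ll + cfg.tolerance:
            break
        _apply_swap(full, c, s)
        best_ll = _optimize(full, tipdata, weights, labels, cfg)

    rooted = midpoint_root(full)
    try:
        return population_tree(rooted, popmap)
    except TreeError:
        # the midpoint fell inside a population subtree: fall back to rooting
        # on the longest edge whose clade is a union of complete populations
        # (such an edge always exists — e.g. any population MRCA's edge)
        members = defaultdict(set)
        for seq, pop in popmap.items():
            members[pop].add(seq)
        pop_sets = list(map(frozenset, members.values()))
        all_tips = frozenset(popmap)
        cand = []
        for node in full.postorder():
            if node.parent is None:
                continue
            cl = full.clade(node)
            if cl == all_tips:
                continue
            pops_in = [p for p in pop_sets if p <= cl]
            if pops_in and cl == frozenset().union(*pops_in):
                cand.append(node)
        edge_node = max(cand, key=lambda n: (n.length or 0.0,
                                             sorted(full.clade(n))))
        rooted = _root_on_edge(full, edge_node)
        return population_tree(rooted, popmap)


def _root_on_edge(tree: RootedTree, node: Node) -> RootedTree:
    """Root an unrooted tree at the midpoint of the edge above ``node``."""
    work = tree.copy()
    # find the corresponding node in the copy via clades
    target_clade = tree.clade(node)
    target = next(n for n in work.postorder() if work.clade(n) == target_clade)
    half = (target.length or 0.0) / 2.0

    def build(n: Node, came_from: Node | None) -> Node:
        """Copy the unrooted subtree seen from ``n`` arriving via ``came_from``."""
        fresh = Node(n.label)
        for c in n.children:
            if c is came_from:
                continue
            cc = build(c, n)
            cc.length = c.length
            fresh.add_child(cc)
        if n.parent is not None and n.parent is not came_from:
            up = build(n.parent, n)
            up.length = n.length
            fresh.add_child(up)
        return fresh

    new_root = Node()
    below = build(target, target.parent)
    below.length = half
    above = build(target.parent, target)
    above.length = half
    new_root.add_child(below)
    new_root.add_child(above)
    out = RootedTree(new_root)
    # suppress any unary node created where the old trifurcating root was
    _suppress_unary(out)
    out.validate()
    return out


def _suppress_unary(tree: RootedTree) -> None:
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder()):
            if not node.is_tip and len(node.children) == 1 and node.parent is not None:
                child = node.children[0]
                child.length = (child.length or 0.0) + (node.length or 0.0)
                parent = node.parent
                parent.children[parent.children.index(node)] = child
                child.parent = parent
                changed = True
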