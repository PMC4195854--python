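"""Tree structures: Newick I/O, clades, recovery, MAP topology, midpoint rooting."""

import itertools

import dendropy
import numpy as np
import pytest

from guidedelim.trees import (RootedTree, Node, TreeError, clades, midpoint_root,
                              modal_topology, parse_newick, population_tree,
                              recovery_frequency, write_newick)


def _random_clock_tree(rng, labels):
    nodes = [Node(l, age=0.0) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = Node(age=max(a.age, b.age) + rng.uniform(0.05, 1.0))
        parent.add_child(nodes.pop(j))
        parent.add_child(nodes.pop(i))
        nodes.append(parent)
    t = RootedTree(nodes[0])
    t.lengths_from_ages()
    return t


# ----------------------------------------------------------------------
# Newick parsing and round trips


def test_parse_simple_clock_tree():
    t = parse_newick("((A:1,B:1):1,C:2);")
    assert sorted(t.tip_labels()) == ["A", "B", "C"]
    assert t.root.age == pytest.approx(2.0)
    assert t.mrca(["A", "B"]).age == pytest.approx(1.0)


def test_parse_rejects_single_tip():
    with pytest.raises(TreeError):
        parse_newick("(A:1);")


def test_parse_rejects_malformed():
    with pytest.raises(TreeError):
        parse_newick("((A:1,B:1):1,C:2")
    with pytest.raises(TreeError):
        parse_newick("")


def test_parse_rejects_multifurcation_when_rooted():
    with pytest.raises(TreeError):
        parse_newick("(A:1,B:1,C:1);", rooted=True)
    t = parse_newick("(A:1,B:1,C:1);", rooted=False)  # unrooted representation
    assert t.n_tips() == 3


def test_parse_rejects_duplicate_labels():
    with pytest.raises(TreeError):
        parse_newick("((A:1,A:1):1,C:2);")


def test_newick_round_trip_on_random_trees():
    rng = np.random.default_rng(5)
    for k in range(20):
        n = int(rng.integers(3, 9))
        t = _random_clock_tree(rng, [f"t{i}" for i in range(n)])
        canon = t.canonical_newick(lengths=True)
        assert parse_newick(canon).canonical_newick(lengths=True) == canon


# ----------------------------------------------------------------------
# clades and recovery frequencies


def test_clades_of_study_topologies():
    cat = parse_newick("(((A,B),C),D);")
    assert clades(cat) == {frozenset("AB"), frozenset("ABC"), frozenset("ABCD")}
    bal = parse_newick("((A,B),(C,D));")
    assert clades(bal) == {frozenset("AB"), frozenset("CD"), frozenset("ABCD")}


@pytest.mark.parametrize("n", range(4, 9))
def test_caterpillar_has_nested_clades(n):
    newick = "t0"
    for i in range(1, n):
        newick = f"({newick},t{i})"
    t = parse_newick(newick + ";")
    cl = clades(t)
    assert len(cl) == n - 1
    assert cl == {frozenset(f"t{i}" for i in range(k)) for k in range(2, n + 1)}


def test_recovery_all_and_half():
    true = parse_newick("(((A,B),C),D);")
    other = parse_newick("(((A,C),B),D);")
    freq = recovery_frequency(true, [true] * 10)
    assert all(v == 1.0 for v in freq.values())
    freq = recovery_frequency(true, [true, other] * 5)
    assert freq[frozenset("AB")] == 0.5
    assert freq[frozenset("ABC")] == 1.0


def test_recovery_tip_mismatch_raises():
    with pytest.raises(TreeError):
        recovery_frequency(parse_newick("((A,B),C);"),
                           [parse_newick("((A,B),D);")])


def test_recovery_matches_bipartition_oracle():
    """Independent check by brute-force bipartition counting on random trees."""
    rng = np.random.default_rng(11)
    labels = [f"t{i}" for i in range(8)]
    true = _random_clock_tree(rng, labels)
    sample = [_random_clock_tree(rng, labels) for _ in range(100)]

    def biparts(tree):  # rooted clades as frozensets, brute force via tip sets
        out = set()
        for node in tree.internal_nodes():
            if node is not tree.root:
                out.add(tree.clade(node))
        return out

    freq = recovery_frequency(true, sample)
    for cl, val in freq.items():
        brute = sum(cl in biparts(t) for t in sample) / len(sample)
        if cl != frozenset(labels):
            assert val == pytest.approx(brute)


def test_recovery_invariant_to_label_permutation():
    rng = np.random.default_rng(3)
    labels = [f"t{i}" for i in range(6)]
    true = _random_clock_tree(rng, labels)
    sample = [_random_clock_tree(rng, labels) for _ in range(30)]
    freq = recovery_frequency(true, sample)
    perm = dict(zip(labels, np.roll(labels, 2)))

    def relabel(tree):
        t = tree.copy()
        for node in t.postorder():
            if node.is_tip:
                node.label = perm[node.label]
        return t

    freq2 = recovery_frequency(relabel(true), [relabel(t) for t in sample])
    for cl, v in freq.items():
        assert freq2[frozenset(perm[x] for x in cl)] == pytest.approx(v)


# ----------------------------------------------------------------------
# modal (MAP) topology


def test_modal_topology_identical_samples():
    t = parse_newick("((A:1,B:1):1,C:2);")
    assert modal_topology([t] * 5).topology_key() == t.topology_key()


def test_modal_topology_tie_breaks_lexicographically():
    a = parse_newick("((A:1,B:1):1,C:2);")
    b = parse_newick("((A:1,C:1):1,B:2);")
    win = modal_topology([a, b, b, a])
    assert win.topology_key() == min(a.topology_key(), b.topology_key())


def test_modal_topology_burn_in_count():
    a = parse_newick("((A:1,B:1):1,C:2);")
    b = parse_newick("((A:1,C:1):1,B:2);")
    # 3000 samples; burn-in fraction chosen to keep exactly the last 2200
    samples = [a] * 800 + [b] * 2200
    win = modal_topology(samples, burn_in_fraction=800 / 3000)
    assert win.topology_key() == b.topology_key()


def test_modal_topology_mean_ages():
    def tree_with_root_age(x):
        t = parse_newick("((A:1,B:1):1,C:2);")
        t.root.age = x
        for node in t.root.children:
            if not node.is_tip:
                node.age = x / 2
        t.lengths_from_ages()
        return t

    win = modal_topology([tree_with_root_age(x) for x in (1.0, 2.0, 3.0)])
    assert win.root.age == pytest.approx(2.0)


def test_modal_topology_empty_raises():
    with pytest.raises(TreeError):
        modal_topology([])


# ----------------------------------------------------------------------
# midpoint rooting


def test_midpoint_two_tips_symmetric():
    t = midpoint_root(parse_newick("(A:1,B:1);"))
    lengths = sorted(n.length for n in t.postorder() if n.parent is not None)
    assert lengths == pytest.approx([1.0, 1.0])


def test_midpoint_three_tip_asymmetric():
    # longest path B-A has length 4; midpoint sits 2 from B, i.e. 1 unit
    # into B's pendant edge from the junction
    t = midpoint_root(parse_newick("(A:1,B:3,C:1);", rooted=False))
    b = next(n for n in t.postorder() if n.label == "B")
    assert b.length == pytest.approx(2.0)
    other = next(c for c in t.root.children if c is not b)
    assert other.length == pytest.approx(1.0)  # to the old junction


def test_midpoint_requires_lengths_and_nonnegative():
    t = parse_newick("((A,B),C);")
    with pytest.raises(TreeError):
        midpoint_root(t)


def test_midpoint_recovers_clock_root():
    """Removing the root of a clock tree and midpoint rooting restores its split."""
    rng = np.random.default_rng(21)
    hits = 0
    for _ in range(50):
        n = int(rng.integers(4, 9))
        t = _random_clock_tree(rng, [f"t{i}" for i in range(n)])
        true_split = {t.clade(c) for c in t.root.children}
        rerooted = midpoint_root(t)
        new_split = {rerooted.clade(c) for c in rerooted.root.children}
        hits += new_split == true_split
    assert hits == 50


def test_midpoint_preserves_bipartitions_and_matches_dendropy():
    rng = np.random.default_rng(9)
    for _ in range(10):
        t = _random_clock_tree(rng, [f"t{i}" for i in range(7)])
        # perturb lengths so the midpoint is informative but the tree non-clock
        for node in t.postorder():
            if node.parent is not None:
                node.length *= rng.uniform(0.5, 2.0)
                node.age = None
        mid = midpoint_root(t)

        def unrooted_biparts(tree):
            tips = frozenset(tree.tip_labels())
            out = set()
            for node in tree.internal_nodes():
                cl = tree.clade(node)
                side = min(cl, tips - cl, key=sorted)
                if 2 <= len(side) <= len(tips) - 2:  # non-trivial splits only
                    out.add(side)
            return out

        assert unrooted_biparts(mid) == unrooted_biparts(t)
        # independent implementation: dendropy's midpoint rooting
        d = dendropy.Tree.get(data=write_newick(t), schema="newick")
        d.reroot_at_midpoint(update_bipartitions=True)
        dmid = parse_newick(d.as_string(schema="newick").replace("[&R] ", ""))
        assert {mid.clade(c) for c in mid.root.children} == \
            {dmid.clade(c) for c in dmid.root.children}


# ----------------------------------------------------------------------
# population-tree extraction


def test_population_tree_collapses_monophyletic_groups():
    t = parse_newick("(((a1:1,a2:1):2,(b1:1,b2:1):2):1,(c1:2,c2:2):2);")
    popmap = {s: s[0].upper() for s in t.tip_labels()}
    pt = population_tree(t, popmap)
    assert clades(pt) == {frozenset("AB"), frozenset("ABC")}


def test_population_tree_rejects_paraphyly():
    t = parse_newick("(((a1:1,b1:1):2,a2:3):1,b2:4);")
    with pytest.raises(TreeError):
        population_tree(t, {s: s[0].upper() for s in t.tip_labels()})
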