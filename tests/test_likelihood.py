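"""Probability-kernel checks: JC69, pruning likelihood, MSC density, priors."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate

from guidedelim.likelihood import (PriorConfig, jc69_transition, log_likelihood,
                                   msc_log_density)
from guidedelim.seqio import ALPHABET, Alignment
from guidedelim.species_model import SpeciesTreeModel, build_species_tree
from guidedelim.trees import RootedTree, Node, parse_newick


# ----------------------------------------------------------------------
# JC69 transition probabilities


def test_jc69_identity_at_zero():
    assert np.allclose(jc69_transition(0.0), np.eye(4))


def test_jc69_stationary_at_infinity():
    assert np.allclose(jc69_transition(500.0), np.full((4, 4), 0.25))


def test_jc69_closed_form_and_rows():
    t = 0.1
    P = jc69_transition(t)
    e = math.exp(-4 * t / 3)
    assert np.allclose(np.diag(P), 0.25 + 0.75 * e)
    assert np.allclose(P[0, 1], 0.25 - 0.25 * e)
    assert np.allclose(P.sum(axis=1), 1.0)


def test_jc69_rejects_negative():
    with pytest.raises(ValueError):
        jc69_transition(-0.01)


@pytest.mark.parametrize("s,t", [(0.03, 0.07), (0.5, 1.2), (0.0, 0.4)])
def test_jc69_chapman_kolmogorov(s, t):
    lhs = jc69_transition(s) @ jc69_transition(t)
    assert np.allclose(lhs, jc69_transition(s + t), atol=1e-12)


# ----------------------------------------------------------------------
# pruning likelihood vs exhaustive-state oracle


def _brute_force_loglik(tree: RootedTree, aln: Alignment) -> float:
    """Sum over all internal-state assignments, one site at a time."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_tip]
    idx = {l: i for i, l in enumerate(aln.labels)}
    total = 0.0
    for site in range(aln.n_sites):
        site_lik = 0.0
        for states in itertools.product(range(4), repeat=len(internals)):
            assign = dict(zip(map(id, internals), states))
            p = 0.25  # root state frequency
            ok = 1.0
            for node in nodes:
                if node.parent is None:
                    continue
                s_par = assign[id(node.parent)]
                s_me = (assign[id(node)] if not node.is_tip
                        else int(aln.data[idx[node.label], site]))
                t = node.parent.age - node.age
                e = math.exp(-4 * t / 3)
                ok *= (0.25 + 0.75 * e) if s_par == s_me else (0.25 - 0.25 * e)
            site_lik += p * ok
        total += math.log(site_lik)
    return total


def _random_clock_tree(rng, labels):
    nodes = [Node(l, age=0.0) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = Node(age=max(a.age, b.age) + rng.uniform(0.02, 0.3))
        parent.add_child(nodes.pop(j))
        parent.add_child(nodes.pop(i))
        nodes.append(parent)
    t = RootedTree(nodes[0])
    t.lengths_from_ages()
    return t


@pytest.mark.parametrize("n_tips,n_sites", [(2, 6), (3, 5), (4, 4)])
def test_pruning_matches_exhaustive_oracle(n_tips, n_sites):
    rng = np.random.default_rng(100 + n_tips)
    labels = [f"t{i}" for i in range(n_tips)]
    for _ in range(5):
        tree = _random_clock_tree(rng, labels)
        aln = Alignment(labels, rng.integers(0, 4, size=(n_tips, n_sites)).astype("int8"))
        assert log_likelihood(tree, aln) == pytest.approx(
            _brute_force_loglik(tree, aln), abs=1e-9)


def test_single_site_identical_tips_at_zero_distance():
    tree = parse_newick("(a:0,b:0);")
    aln = Alignment.from_strings(["a", "b"], ["T", "T"])
    assert log_likelihood(tree, aln) == pytest.approx(math.log(0.25))


def test_likelihood_invariant_to_site_and_sequence_order():
    rng = np.random.default_rng(7)
    labels = ["a", "b", "c", "d"]
    tree = _random_clock_tree(rng, labels)
    aln = Alignment(labels, rng.integers(0, 4, size=(4, 40)).astype("int8"))
    ll = log_likelihood(tree, aln)
    perm = rng.permutation(40)
    aln2 = Alignment(labels, aln.data[:, perm])
    assert log_likelihood(tree, aln2) == pytest.approx(ll)
    order = [2, 0, 3, 1]
    aln3 = Alignment([labels[i] for i in order], aln.data[order])
    assert log_likelihood(tree, aln3) == pytest.approx(ll)


def test_likelihood_label_mismatch_raises():
    tree = parse_newick("(a:1,b:1);")
    aln = Alignment.from_strings(["a", "x"], ["T", "C"])
    with pytest.raises(ValueError):
        log_likelihood(tree, aln)


# ----------------------------------------------------------------------
# MSC gene-tree density


def _single_species_model(theta):
    # a 2-species tree whose root is so old that both tips act as one deme
    tree = parse_newick("(A:1,B:1);")
    for node in tree.postorder():
        node.age = 0.0 if node.is_tip else 50.0
    tree.lengths_from_ages()
    th = {tree.clade(n): theta for n in tree.postorder()}
    return SpeciesTreeModel(tree, th)


def _gene_tree_two(t, labels=("A^0", "B^0")):
    a, b = Node(labels[0], age=0.0), Node(labels[1], age=0.0)
    r = Node(age=t)
    r.add_child(a)
    r.add_child(b)
    gt = RootedTree(r)
    gt.lengths_from_ages()
    return gt


def test_msc_two_lineages_closed_form():
    theta = 0.01
    model = build_species_tree(1, "low")
    # two sequences from species A: density of TMRCA t is (2/theta) e^(-2t/theta)
    popmap = {"A^0": "A", "A^1": "A"}
    for t in (1e-9, 0.001, 0.004):
        gt = _gene_tree_two(t, ("A^0", "A^1"))
        expect = math.log(2 / 0.002) - 2 * t / 0.002
        assert msc_log_density(gt, model, popmap) == pytest.approx(expect, rel=1e-9)


def test_msc_density_integrates_to_one_two_lineages():
    model = build_species_tree(1, "low")
    popmap = {"A^0": "A", "A^1": "A"}

    def dens(t):
        return math.exp(msc_log_density(_gene_tree_two(t, ("A^0", "A^1")),
                                        model, popmap))

    val, err = integrate.quad(dens, 0, 0.1, limit=200)
    assert val == pytest.approx(1.0, abs=1e-6)


def test_msc_density_integrates_to_one_three_lineages():
    """Joint density over ordered coalescent times (t1 < t2) of 3 lineages."""
    model = build_species_tree(1, "low")
    popmap = {f"A^{i}": "A" for i in range(3)}

    def gene_tree(t1, t2):
        a = [Node(f"A^{i}", age=0.0) for i in range(3)]
        u = Node(age=t1)
        u.add_child(a[0])
        u.add_child(a[1])
        r = Node(age=t2)
        r.add_child(u)
        r.add_child(a[2])
        gt = RootedTree(r)
        gt.lengths_from_ages()
        return gt

    def dens(t2, t1):
        return math.exp(msc_log_density(gene_tree(t1, t2), model, popmap))

    # 3 possible labelled topologies contribute equally by exchangeability
    val, err = integrate.dblquad(dens, 0, 0.05, lambda t1: t1, lambda t1: 0.08,
                                 epsabs=1e-10)
    assert 3 * val == pytest.approx(1.0, abs=1e-5)


def test_msc_cross_species_minimum_age():
    """A coalescence of lineages from two species younger than their
    divergence has zero density."""
    model = build_species_tree(1, "low")  # tau_AB = 0.001
    popmap = {"A^0": "A", "B^0": "B"}
    young = _gene_tree_two(0.0005)
    old = _gene_tree_two(0.0015)
    assert msc_log_density(young, model, popmap) == -np.inf
    assert msc_log_density(old, model, popmap) > -np.inf


def test_msc_density_matches_simulator_moments():
    """The simulator's TMRCA distribution matches the density's expectation:
    two lineages in one panmictic species coalesce with mean theta/2."""
    from guidedelim.simulate import simulate_gene_tree

    model1 = _single_species_model(0.02)
    pm = {"A^0": "A", "A^1": "A"}

    def dens(t):
        gt = _gene_tree_two(t, ("A^0", "A^1"))
        return math.exp(msc_log_density(gt, model1, pm))

    mean_quad = integrate.quad(lambda t: t * dens(t), 0, 1.0, limit=300)[0]
    assert mean_quad == pytest.approx(0.01, rel=1e-4)
    rng = np.random.default_rng(42)
    draws = np.array([
        simulate_gene_tree(model1, {"A": 2, "B": 1}, rng).mrca(["A^0", "A^1"]).age
        for _ in range(4000)])
    se = draws.std() / math.sqrt(len(draws))
    assert abs(draws.mean() - mean_quad) < 3.5 * se


# ----------------------------------------------------------------------
# priors


def test_prior_config_study_values():
    low = PriorConfig.for_rate("low")
    assert low.tau0_mean == pytest.approx(1 / 333)
    assert low.theta_mean == pytest.approx(1 / 500)
    high = PriorConfig.for_rate("high")
    assert (high.tau0_rate, high.theta_rate) == (33.0, 50.0)


def test_prior_config_validation():
    with pytest.raises(ValueError):
        PriorConfig(tau0_rate=-1)
    with pytest.raises(ValueError):
        PriorConfig(model_prior="bogus")
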