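"""rjMCMC delimitation: model enumeration, oracle agreement, prior recovery."""

import itertools

import numpy as np
import pytest

from guidedelim.delimit import (RjmcmcConfig, count_models, enumerate_models,
                                rjmcmc_delimit)
from guidedelim.likelihood import PriorConfig
from guidedelim.oracle import oracle_posterior
from guidedelim.simulate import ReplicateConfig, simulate_alignment, \
    simulate_gene_tree, simulate_replicate
from guidedelim.species_model import SpeciesTreeModel
from guidedelim.trees import clades, parse_newick

GUIDE1 = "((((A1,A2),(B1,B2)),(C1,C2)),(D1,D2));"
GUIDE2 = "(((A1,A2),(B1,B2)),((C1,C2),(D1,D2)));"


# ----------------------------------------------------------------------
# model enumeration


def _brute_force_models(guide):
    """All ancestor-closed subsets of internal nodes, by direct enumeration."""
    internals = [guide.clade(n) for n in guide.internal_nodes()]
    parent = {}
    for node in guide.internal_nodes():
        if node.parent is not None:
            parent[guide.clade(node)] = guide.clade(node.parent)
    models = set()
    for r in range(len(internals) + 1):
        for subset in itertools.combinations(internals, r):
            s = frozenset(subset)
            if all(c not in parent or parent[c] in s for c in s):
                models.add(s)
    return models


def test_two_tip_guide_has_two_models():
    guide = parse_newick("(P1,P2);")
    models = enumerate_models(guide)
    assert len(models) == 2
    assert frozenset() in models


@pytest.mark.parametrize("newick,expected", [(GUIDE1, 23), (GUIDE2, 26)])
def test_study_guide_tree_model_counts(newick, expected):
    guide = parse_newick(newick)
    models = enumerate_models(guide)
    assert len(models) == expected == count_models(guide)
    assert set(models) == _brute_force_models(guide)


def test_model_count_recursion_on_random_trees():
    from guidedelim.trees import Node, RootedTree

    rng = np.random.default_rng(6)
    for _ in range(5):
        n = int(rng.integers(3, 8))
        nodes = [Node(f"t{i}") for i in range(n)]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            p = Node()
            p.add_child(nodes.pop(j))
            p.add_child(nodes.pop(i))
            nodes.append(p)
        guide = RootedTree(nodes[0])

        def recursion(node):
            if node.is_tip:
                return 1
            a, b = node.children
            return 1 + recursion(a) * recursion(b)

        assert count_models(guide) == recursion(guide.root)
        assert set(enumerate_models(guide)) == _brute_force_models(guide)


# ----------------------------------------------------------------------
# prior recovery (likelihood-off chains)


def _dummy_alignment(pops, n_per_pop, n_sites, seed):
    from guidedelim.seqio import Alignment

    rng = np.random.default_rng(seed)
    labels = [f"{p}^{i}" for p in pops for i in range(n_per_pop)]
    aln = Alignment(labels,
                    rng.integers(0, 4, size=(len(labels), n_sites)).astype("int8"))
    return aln, {l: l.split("^")[0] for l in labels}


def test_likelihood_off_two_tip_split_probability_half():
    aln, popmap = _dummy_alignment(["P1", "P2"], 2, 30, 0)
    guide = parse_newick("(P1,P2);")
    cfg = RjmcmcConfig(burn_in=2000, n_samples=20000, sample_interval=1, n_runs=2)
    post = rjmcmc_delimit([aln], guide, popmap, PriorConfig.for_rate("low"),
                          cfg, seed=11, likelihood_on=False)
    assert post.prob(["P1", "P2"]) == pytest.approx(0.5, abs=0.03)


def test_likelihood_off_recovers_tau0_prior_mean():
    """Conditional on the root being split, tau0 follows its G(1, 333) prior."""
    aln, popmap = _dummy_alignment(["P1", "P2", "P3"], 2, 30, 1)
    guide = parse_newick("((P1,P2),P3);")
    prior = PriorConfig.for_rate("low")
    cfg = RjmcmcConfig(burn_in=3000, n_samples=50000, sample_interval=1,
                       n_runs=2)
    post = rjmcmc_delimit([aln], guide, popmap, prior, cfg, seed=13,
                          likelihood_on=False)
    assert post.tau0_mean == pytest.approx(prior.tau0_mean, rel=0.02)


# ----------------------------------------------------------------------
# agreement with the enumeration + simulation oracle


def _fixture_two_pops(seed, n_per_pop=2, n_sites=200, tau=0.004, theta=0.002):
    t = parse_newick("(P1,P2);")
    for n in t.postorder():
        n.age = 0.0 if n.is_tip else tau
    t.lengths_from_ages()
    model = SpeciesTreeModel(t, {t.clade(n): theta for n in t.postorder()})
    rng = np.random.default_rng(seed)
    gt = simulate_gene_tree(model, {"P1": n_per_pop, "P2": n_per_pop}, rng)
    aln = simulate_alignment(gt, n_sites, rng)
    return aln, {l: l.split("^")[0] for l in aln.labels}


def _fixture_three_pops(seed, n_sites=200):
    t = parse_newick("((P1,P2),P3);")
    ages = {frozenset(["P1", "P2"]): 0.003, frozenset(["P1", "P2", "P3"]): 0.006}
    for n in t.postorder():
        n.age = 0.0 if n.is_tip else ages[t.clade(n)]
    t.lengths_from_ages()
    model = SpeciesTreeModel(t, {t.clade(n): 0.002 for n in t.postorder()})
    rng = np.random.default_rng(seed)
    gt = simulate_gene_tree(model, {p: 2 for p in ("P1", "P2", "P3")}, rng)
    aln = simulate_alignment(gt, n_sites, rng)
    return aln, {l: l.split("^")[0] for l in aln.labels}


def _tv_distance(p, q):
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


@pytest.mark.parametrize("fixture,guide_newick", [
    (_fixture_two_pops, "(P1,P2);"),
    (_fixture_three_pops, "((P1,P2),P3);"),
])
def test_rjmcmc_matches_oracle(fixture, guide_newick):
    aln, popmap = fixture(seed=3)
    guide = parse_newick(guide_newick)
    prior = PriorConfig.for_rate("low")
    orc = oracle_posterior([aln], guide, popmap, prior, n_draws=150_000, seed=9)
    cfg = RjmcmcConfig(burn_in=3000, n_samples=10000, sample_interval=2,
                       n_runs=2)
    post = rjmcmc_delimit([aln], guide, popmap, prior, cfg, seed=21)
    assert _tv_distance(orc["probs"], post.model_probs) < 0.03


def test_oracle_refuses_large_problems():
    aln, popmap = _dummy_alignment(["P1", "P2", "P3", "P4"], 1, 20, 2)
    with pytest.raises(ValueError):
        oracle_posterior([aln], parse_newick("((P1,P2),(P3,P4));"), popmap,
                         PriorConfig.for_rate("low"))


def test_oracle_probabilities_normalised():
    aln, popmap = _fixture_two_pops(seed=5)
    orc = oracle_posterior([aln], parse_newick("(P1,P2);"), popmap,
                           PriorConfig.for_rate("low"), n_draws=20_000)
    assert sum(orc["probs"].values()) == pytest.approx(1.0, abs=1e-9)


# ----------------------------------------------------------------------
# sampler contracts


def test_combining_runs_equals_pooling():
    aln, popmap = _fixture_two_pops(seed=7)
    guide = parse_newick("(P1,P2);")
    prior = PriorConfig.for_rate("low")
    cfg = RjmcmcConfig(burn_in=500, n_samples=2000, sample_interval=2, n_runs=2)
    post = rjmcmc_delimit([aln], guide, popmap, prior, cfg, seed=31)
    pooled = np.mean([r[frozenset(["P1", "P2"])] for r in post.per_run_split_prob])
    assert post.prob(["P1", "P2"]) == pytest.approx(pooled, abs=1e-12)


def test_seed_determinism():
    aln, popmap = _fixture_two_pops(seed=8)
    guide = parse_newick("(P1,P2);")
    cfg = RjmcmcConfig(burn_in=500, n_samples=2000, sample_interval=2, n_runs=2)
    a = rjmcmc_delimit([aln], guide, popmap, PriorConfig.for_rate("low"), cfg,
                       seed=41)
    b = rjmcmc_delimit([aln], guide, popmap, PriorConfig.for_rate("low"), cfg,
                       seed=41)
    assert a.split_prob == b.split_prob
    assert a.model_probs == b.model_probs


def test_samples_are_ancestor_closed():
    """Every retained sample's split set must be ancestor-closed."""
    rng = np.random.default_rng(17)
    ds = simulate_replicate(ReplicateConfig(1, "low", 3, 1), rng)
    guide = parse_newick(GUIDE1)
    cfg = RjmcmcConfig(burn_in=500, n_samples=2000, sample_interval=2, n_runs=1)
    post = rjmcmc_delimit(ds.nuclear_alignments, guide, ds.popmap,
                          PriorConfig.for_rate("low"), cfg, seed=51)
    S = post.raw_split_samples
    cl = post.node_clades
    internal = [i for i, c in enumerate(cl) if len(c) > 1]
    for i in internal:
        parents = [j for j in internal if cl[i] < cl[j]]
        if not parents:
            continue
        par = min(parents, key=lambda j: len(cl[j]))
        assert not np.any(S[:, i] & ~S[:, par].astype(bool))


def test_guide_popmap_mismatch_raises():
    aln, popmap = _fixture_two_pops(seed=9)
    with pytest.raises(ValueError):
        rjmcmc_delimit([aln], parse_newick("(X1,X2);"), popmap,
                       PriorConfig.for_rate("low"), RjmcmcConfig.scaled(), 1)
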