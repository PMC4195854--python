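"""Species-tree MCMC: prior recovery, forced cases, determinism, monotonicity."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from guidedelim.seqio import Alignment
from guidedelim.simulate import simulate_alignment, simulate_gene_tree
from guidedelim.species_model import SpeciesTreeModel, build_species_tree
from guidedelim.sptree_mcmc import (SpeciesTreeMcmcConfig, map_guide_tree,
                                    mcmc_species_tree)
from guidedelim.trees import clades


def _dummy_data(pops, n_per_pop, n_sites, seed):
    rng = np.random.default_rng(seed)
    labels = [f"{p}^{i}" for p in pops for i in range(n_per_pop)]
    aln = Alignment(labels,
                    rng.integers(0, 4, size=(len(labels), n_sites)).astype("int8"))
    return aln, {l: l.split("^")[0] for l in labels}


def test_config_validation():
    with pytest.raises(ValueError):
        SpeciesTreeMcmcConfig(100, 200, 1)
    with pytest.raises(ValueError):
        SpeciesTreeMcmcConfig(1000, 10, 1000)
    cfg = SpeciesTreeMcmcConfig.scaled(90_000)
    assert cfg.keep_last <= cfg.n_iterations // cfg.sample_interval


def test_prior_sampling_topologies_uniform():
    """Likelihood-off runs must reproduce the Yule prior: for three species,
    the three rooted topologies are equally likely."""
    aln, popmap = _dummy_data(["A1", "B1", "C1"], 1, 40, 0)
    cfg = SpeciesTreeMcmcConfig(1_200_000, 100, 1,
                                theta_min=1e-3, theta_max=0.1)
    samples = mcmc_species_tree([aln], popmap, cfg, seed=5,
                                likelihood_on=False, lambda_fixed=50.0)
    kept = samples[3000:]
    freqs = Counter(t.topology_key() for t in kept)
    assert len(freqs) == 3
    for count in freqs.values():
        assert abs(count / len(kept) - 1 / 3) < 0.06


def test_prior_sampling_root_age_distribution():
    """Fixed-lambda prior runs match the conditioned Yule root-height law:
    the root is the maximum of (n_tips - 1) iid Exponential(lambda) draws."""
    lam = 50.0
    aln, popmap = _dummy_data(["A1", "B1", "C1"], 1, 40, 1)
    cfg = SpeciesTreeMcmcConfig(1_200_000, 100, 1,
                                theta_min=1e-3, theta_max=0.1)
    samples = mcmc_species_tree([aln], popmap, cfg, seed=7,
                                likelihood_on=False, lambda_fixed=lam)
    roots = np.array([t.root.age for t in samples[3000:]])[::30]  # thin

    def cdf(x):
        return (1.0 - np.exp(-lam * np.asarray(x))) ** 2

    ks = stats.kstest(roots, cdf)
    assert ks.pvalue > 0.01


def test_two_population_forced_topology():
    rng = np.random.default_rng(2)
    model = build_species_tree(1, "high")
    gt = simulate_gene_tree(model, {"A": 3, "B": 3, "C": 1, "D": 1}, rng)
    aln = simulate_alignment(gt, 300, rng)
    keep = [l for l in aln.labels if l[0] in "AB"]
    sub = aln.take(keep)
    popmap = {l: l[0] for l in keep}
    cfg = SpeciesTreeMcmcConfig(20_000, 20, 100)
    samples = mcmc_species_tree([sub], popmap, cfg, seed=3)
    assert all(t.topology_key() == "(A,B);" for t in samples)


def test_seed_determinism():
    rng = np.random.default_rng(4)
    model = build_species_tree(1, "high")
    gt = simulate_gene_tree(model, {s: 2 for s in "ABCD"}, rng)
    aln = simulate_alignment(gt, 200, rng)
    popmap = {l: l.split("^")[0] for l in aln.labels}
    cfg = SpeciesTreeMcmcConfig(30_000, 30, 700)
    a = mcmc_species_tree([aln], popmap, cfg, seed=99)
    b = mcmc_species_tree([aln], popmap, cfg, seed=99)
    assert [t.canonical_newick(lengths=True) for t in a] == \
        [t.canonical_newick(lengths=True) for t in b]
    assert map_guide_tree(a, cfg.keep_last).topology_key() == \
        map_guide_tree(b, cfg.keep_last).topology_key()


def test_map_guide_tree_validation():
    with pytest.raises(ValueError):
        map_guide_tree([], 10)


def test_recovery_improves_with_divergence():
    """MAP recovery of the deep clade is non-decreasing in divergence depth."""
    base = build_species_tree(1, "high")
    ABC = frozenset(["A1", "A2", "B1", "B2", "C1", "C2"])
    cfg = SpeciesTreeMcmcConfig.scaled(100_000)
    rates = []
    for mult in (0.25, 1.0, 4.0):
        model = SpeciesTreeModel(base.tree.copy(),
                                 {c: v for c, v in base.theta.items()})
        for node in model.tree.postorder():
            if not node.is_tip:
                node.age = node.age * mult
        model.tree.lengths_from_ages()
        got = 0
        n = 10
        master = np.random.SeedSequence(int(100 * mult))
        for ss in master.spawn(n):
            rng = np.random.default_rng(ss)
            gt = simulate_gene_tree(model, {s: 6 for s in model.species}, rng)
            relabel = {}
            for l in gt.tip_labels():
                sp, i = l.split("^")
                relabel[l] = f"{sp}1^{i}" if int(i) < 3 else f"{sp}2^{int(i) - 3}"
            for node in gt.postorder():
                if node.is_tip:
                    node.label = relabel[node.label]
            aln = simulate_alignment(gt, 500, rng)
            popmap = {l: l.split("^")[0] for l in aln.labels}
            samples = mcmc_species_tree([aln], popmap, cfg,
                                        seed=int(rng.integers(1, 2**31 - 1)))
            got += ABC in clades(map_guide_tree(samples, cfg.keep_last))
        rates.append(got / n)
    assert rates[2] >= rates[0]
    assert rates[2] >= 0.7  # deep divergences are essentially always recovered
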