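"""Synthetic-data generator: species trees, MSC gene trees, JC69 sequences."""

import math

import numpy as np
import pytest
from scipy import stats

from guidedelim.seqio import read_fasta, read_popmap
from guidedelim.simulate import (ReplicateConfig, simulate_alignment,
                                 simulate_gene_tree, simulate_replicate,
                                 write_replicate)
from guidedelim.species_model import (MITO_LOCUS, NUCLEAR_LOCUS, LocusSpec,
                                      SpeciesTreeModel, build_species_tree,
                                      scale_for_locus)
from guidedelim.trees import clades, write_newick


# ----------------------------------------------------------------------
# study parameterisation


@pytest.mark.parametrize("tree_id,rate,taus,theta", [
    (1, "low", {"AB": 0.001, "ABC": 0.002, "ABCD": 0.003}, 0.002),
    (1, "high", {"AB": 0.01, "ABC": 0.02, "ABCD": 0.03}, 0.02),
    (2, "low", {"AB": 0.001, "CD": 0.001, "ABCD": 0.003}, 0.002),
    (2, "high", {"AB": 0.01, "CD": 0.01, "ABCD": 0.03}, 0.02),
])
def test_study_species_trees(tree_id, rate, taus, theta):
    model = build_species_tree(tree_id, rate)
    for clade_str, tau in taus.items():
        assert model.tau(frozenset(clade_str)) == pytest.approx(tau)
    assert all(v == pytest.approx(theta) for v in model.theta.values())
    assert model.root_age == max(model.tau(c) for c in
                                 [frozenset(s) for s in taus])


def test_tree1_is_caterpillar_tree2_balanced():
    assert clades(build_species_tree(1, "low").tree) == {
        frozenset("AB"), frozenset("ABC"), frozenset("ABCD")}
    assert clades(build_species_tree(2, "low").tree) == {
        frozenset("AB"), frozenset("CD"), frozenset("ABCD")}


def test_build_species_tree_rejects_unknown():
    with pytest.raises(ValueError):
        build_species_tree(3, "low")
    with pytest.raises(ValueError):
        build_species_tree(1, "medium")


def test_mitochondrial_scaling():
    model = build_species_tree(1, "low")
    assert scale_for_locus(model, NUCLEAR_LOCUS) is model  # identity
    mito = scale_for_locus(model, MITO_LOCUS)
    assert mito.root_age == pytest.approx(0.06)  # 0.003 * 20
    assert mito.theta[frozenset("ABCD")] == pytest.approx(0.01)  # 0.002 * 5
    with pytest.raises(ValueError):  # scaling is not idempotent
        scale_for_locus(mito, MITO_LOCUS)


# ----------------------------------------------------------------------
# gene-tree simulation


def _one_species(theta):
    model = build_species_tree(1, "low")
    tree = model.tree.copy()
    for node in tree.postorder():
        if not node.is_tip:
            node.age = node.age * 1e6  # push divergences out of reach
    tree.lengths_from_ages()
    return SpeciesTreeModel(tree, {c: theta for c in model.theta})


def test_tmrca_exponential_distribution():
    """Two lineages in one deme: TMRCA ~ Exponential(2/theta)."""
    theta = 0.01
    model = _one_species(theta)
    rng = np.random.default_rng(1)
    draws = np.array([
        simulate_gene_tree(model, {"A": 2, "B": 1, "C": 1, "D": 1}, rng)
        .mrca(["A^0", "A^1"]).age for _ in range(10_000)])
    se = theta / 2 / math.sqrt(len(draws))
    assert abs(draws.mean() - theta / 2) < 3 * se
    ks = stats.kstest(draws, "expon", args=(0, theta / 2))
    assert ks.pvalue > 0.01


def test_cross_species_coalescence_respects_tau():
    model = build_species_tree(1, "low")
    rng = np.random.default_rng(2)
    ages = [simulate_gene_tree(model, {s: 1 for s in "ABCD"}, rng)
            .mrca(["A^0", "B^0"]).age for _ in range(300)]
    assert min(ages) >= model.tau(frozenset("AB"))


def test_no_ils_when_ancestral_theta_vanishes():
    model = build_species_tree(1, "high")
    tiny = SpeciesTreeModel(model.tree.copy(),
                            {c: 1e-7 for c in model.theta})
    rng = np.random.default_rng(3)
    match = 0
    for _ in range(200):
        gt = simulate_gene_tree(tiny, {s: 1 for s in "ABCD"}, rng)
        relabel = {f"{s}^0": s for s in "ABCD"}
        for node in gt.postorder():
            if node.is_tip:
                node.label = relabel[node.label]
        match += clades(gt) == clades(model.tree)
    assert match >= 198  # ~100% without ancestral polymorphism


def test_gene_tree_ages_respect_species_constraints():
    from guidedelim.likelihood import msc_log_density

    model = build_species_tree(1, "high")
    rng = np.random.default_rng(4)
    for _ in range(50):
        gt = simulate_gene_tree(model, {s: 3 for s in "ABCD"}, rng)
        popmap = {l: l.split("^")[0] for l in gt.tip_labels()}
        assert np.isfinite(msc_log_density(gt, model, popmap))


# ----------------------------------------------------------------------
# sequence simulation


def test_zero_branch_lengths_give_identical_sequences():
    from guidedelim.trees import parse_newick

    gt = parse_newick("((x:0,y:0):0,z:0);")
    rng = np.random.default_rng(5)
    aln = simulate_alignment(gt, 200, rng)
    assert (aln.data == aln.data[0]).all()


def test_jc69_expected_divergence():
    """Two sequences at distance d differ at (3/4)(1 - e^(-4d/3)) of sites."""
    from guidedelim.trees import parse_newick

    d = 0.06
    gt = parse_newick(f"(x:{d / 2},y:{d / 2});")
    rng = np.random.default_rng(6)
    aln = simulate_alignment(gt, 100_000, rng)
    p = (aln.data[0] != aln.data[1]).mean()
    expect = 0.75 * (1 - math.exp(-4 * d / 3))
    se = math.sqrt(expect * (1 - expect) / aln.n_sites)
    assert abs(p - expect) < 3 * se


def test_pairwise_divergence_between_species():
    """One A vs one B sequence (tree 1, high rate): expected raw coalescent
    distance 2*tau_AB + theta = 0.04 before saturation correction."""
    model = build_species_tree(1, "high")
    rng = np.random.default_rng(7)
    dists = [2 * simulate_gene_tree(model, {s: 1 for s in "ABCD"}, rng)
             .mrca(["A^0", "B^0"]).age - 2 * model.tau(frozenset("AB"))
             for _ in range(4000)]
    # distance = 2*(tau + T) with T ~ Exp(2/theta): check E[2T] = theta
    se = np.std(dists) / math.sqrt(len(dists))
    assert abs(np.mean(dists) - 0.02) < 3.5 * se


def test_base_composition_uniform():
    from guidedelim.trees import parse_newick

    gt = parse_newick("(x:0.5,y:0.5);")
    rng = np.random.default_rng(8)
    aln = simulate_alignment(gt, 50_000, rng)
    freqs = np.bincount(aln.data.ravel(), minlength=4) / aln.data.size
    assert np.allclose(freqs, 0.25, atol=0.01)


# ----------------------------------------------------------------------
# replicate datasets


@pytest.mark.parametrize("npp,nloci,n_seqs", [(3, 1, 24), (5, 2, 40)])
def test_replicate_shapes(npp, nloci, n_seqs):
    rng = np.random.default_rng(9)
    ds = simulate_replicate(ReplicateConfig(1, "low", npp, nloci), rng)
    assert ds.mito_alignment.n_seqs == n_seqs
    assert ds.mito_alignment.n_sites == 1000
    assert len(ds.nuclear_alignments) == nloci
    for aln in ds.nuclear_alignments:
        assert (aln.n_seqs, aln.n_sites) == (n_seqs, 500)
    pops = ds.populations
    assert pops == sorted(f"{s}{i}" for s in "ABCD" for i in (1, 2))
    for pop in pops:
        assert sum(1 for p in ds.popmap.values() if p == pop) == npp
    assert ds.mito_alignment.labels == ds.nuclear_alignments[0].labels


def test_replicate_determinism():
    a = simulate_replicate(ReplicateConfig(1, "low", 3, 2),
                           np.random.default_rng(123))
    b = simulate_replicate(ReplicateConfig(1, "low", 3, 2),
                           np.random.default_rng(123))
    assert (a.mito_alignment.data == b.mito_alignment.data).all()
    for x, y in zip(a.nuclear_alignments, b.nuclear_alignments):
        assert (x.data == y.data).all()
    assert write_newick(a.mito_tree) == write_newick(b.mito_tree)


def test_replicate_round_trip(tmp_path):
    rng = np.random.default_rng(10)
    ds = simulate_replicate(ReplicateConfig(2, "high", 3, 1), rng, seed=10)
    write_replicate(ds, str(tmp_path))
    aln = read_fasta(tmp_path / "mito.fasta", kind="mitochondrial")
    assert aln.labels == ds.mito_alignment.labels
    assert (aln.data == ds.mito_alignment.data).all()
    assert read_popmap(tmp_path / "popmap.txt") == ds.popmap
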