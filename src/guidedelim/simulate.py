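"""Synthetic-data generation under the multispecies coalescent and JC69.

A replicate data set mirrors the study design: four species A-D, each
panmictic but split post hoc into two sampled populations (A1, A2, ...,
D1, D2) of 3 or 5 sequences; one mitochondrial locus of 1000 sites simulated
on the 20x-tau / 5x-theta scaled model; and 1 or 5 nuclear loci of 500 sites
each on the nuclear-scale model.  Because the species are panmictic, the
gene-tree simulator draws all ``2n`` lineages of a species from one
population and the sequences are then labelled into the two populations —
distributionally identical to sampling from two populations with zero
divergence.

All randomness flows from a :class:`numpy.random.Generator`; per-replicate
child seeds are derived with ``numpy.random.SeedSequence`` spawning, so any
single replicate can be regenerated independently of the rest of a study.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._arrays import arrays_to_tree
from .seqio import ALPHABET, Alignment, write_fasta, write_popmap
from .species_model import (MITO_LOCUS, NUCLEAR_LOCUS, LocusSpec,
                            SpeciesTreeModel, build_species_tree, scale_for_locus)
from .likelihood import species_model_to_arrays
from .trees import RootedTree, write_newick

__all__ = ["ReplicateConfig", "ReplicateDataset", "simulate_gene_tree",
           "simulate_alignment", "simulate_replicate", "write_replicate"]


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def simulate_gene_tree(model: SpeciesTreeModel, n_per_species: dict[str, int],
                       rng: np.random.Generator,
                       labels: list[str] | None = None) -> RootedTree:
    """Simulate one gene tree under the MSC on ``model``.

    ``n_per_species`` gives the number of sampled sequences per species.
    Tip labels default to ``"<species>^<i>"``.  Node ages are in expected
    substitutions per site; within a branch holding ``k`` lineages the
    waiting time to the next coalescence is Exponential(k(k-1)/theta).
    """
    sparent, schild0, schild1, sage, stheta, tips = species_model_to_arrays(model)
    tip_sp = []
    auto_labels = []
    for si, sp in enumerate(tips):
        cnt = n_per_species.get(sp, 0)
        if cnt < 1:
            raise ValueError(f"need at least one sequence for species {sp}")
        for i in range(cnt):
            tip_sp.append(si)
            auto_labels.append(f"{sp}^{i}")
    tip_sp = np.array(tip_sp, np.int64)
    if labels is None:
        labels = auto_labels
    if len(labels) != tip_sp.shape[0]:
        raise ValueError("label count does not match total sample size")
    n = tip_sp.shape[0]
    N = 2 * n - 1
    gparent = np.full(N, -1, np.int64)
    gchild0 = np.full(N, -1, np.int64)
    gchild1 = np.full(N, -1, np.int64)
    gage = np.zeros(N, np.float64)
    _kernels.seed_rng(_kernel_seed(rng))
    _kernels.sim_gene_tree(sparent, schild0, schild1, sage, stheta, tip_sp,
                           gparent, gchild0, gchild1, gage)
    return arrays_to_tree(gparent, gchild0, gchild1, gage, list(labels))


def simulate_alignment(gtree: RootedTree, length: int, rng: np.random.Generator,
                       kind: str = "nuclear") -> Alignment:
    """Simulate a JC69 alignment of ``length`` sites down a gene tree.

    The root state is uniform over T,C,A,G per site; sites are independent.
    """
    if length < 1:
        raise ValueError("length must be at least 1")
    if not gtree.has_ages():
        raise ValueError("gene tree must carry node ages")
    labels = gtree.tip_labels()
    from ._arrays import tree_to_arrays

    gparent, gchild0, gchild1, gage = tree_to_arrays(gtree, labels)
    N = gparent.shape[0]
    out = np.zeros((N, length), np.int8)
    _kernels.seed_rng(_kernel_seed(rng))
    _kernels.sim_sequences(gparent, gage, length, out)
    n = len(labels)
    return Alignment(list(labels), out[:n], kind)


@dataclass(frozen=True)
class ReplicateConfig:
    """Settings for one simulated replicate of the study design."""

    tree_id: int = 1
    rate: str = "low"
    n_per_population: int = 3
    n_nuclear_loci: int = 1
    mito_spec: LocusSpec = MITO_LOCUS
    nuclear_spec: LocusSpec = NUCLEAR_LOCUS

    def __post_init__(self):
        if self.n_per_population < 1:
            raise ValueError("n_per_population must be >= 1")
        if self.n_nuclear_loci < 1:
            raise ValueError("need at least one nuclear locus")


@dataclass
class ReplicateDataset:
    """One replicate: a mitochondrial locus plus nuclear loci and metadata."""

    config: ReplicateConfig
    model: SpeciesTreeModel          # nuclear-scale generating model
    mito_alignment: Alignment
    mito_tree: RootedTree
    nuclear_alignments: list[Alignment]
    nuclear_trees: list[RootedTree]
    popmap: dict[str, str]           # sequence label -> population (A1..D2)
    seed: int | None = None

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.popmap.values()))


def simulate_replicate(config: ReplicateConfig, rng: np.random.Generator,
                       seed: int | None = None) -> ReplicateDataset:
    """Simulate a full replicate data set for the study design.

    Each species contributes ``2 * n_per_population`` sequences; labels are
    assigned to the two populations of a species after simulation (the
    species is panmictic, so any assignment is exchangeable).  The same
    labels and population map apply to every locus; gene trees are
    independent across loci.
    """
    model = build_species_tree(config.tree_id, config.rate)
    mito_model = scale_for_locus(model, config.mito_spec)
    npp = config.n_per_population
    n_per_species = {sp: 2 * npp for sp in model.species}
    labels: list[str] = []
    popmap: dict[str, str] = {}
    for sp in model.species:
        for i in range(2 * npp):
            pop = f"{sp}1" if i < npp else f"{sp}2"
            label = f"{pop}^{(i % npp)}"
            labels.append(label)
            popmap[label] = pop

    mito_tree = simulate_gene_tree(mito_model, n_per_species, rng, labels)
    mito_aln = simulate_alignment(mito_tree, config.mito_spec.length, rng,
                                  kind="mitochondrial").take(labels)
    nuc_trees, nuc_alns = [], []
    for _ in range(config.n_nuclear_loci):
        t = simulate_gene_tree(model, n_per_species, rng, labels)
        nuc_trees.append(t)
        nuc_alns.append(
            simulate_alignment(t, config.nuclear_spec.length, rng).take(labels))
    return ReplicateDataset(config, model, mito_aln, mito_tree,
                            nuc_alns, nuc_trees, popmap, seed)


def write_replicate(ds: ReplicateDataset, directory: str) -> None:
    """Persist a replicate: FASTA per locus, true gene trees, Imap, manifest."""
    os.makedirs(directory, exist_ok=True)
    write_fasta(ds.mito_alignment, os.path.join(directory, "mito.fasta"))
    with open(os.path.join(directory, "mito.tre"), "w") as fh:
        fh.write(write_newick(ds.mito_tree) + "\n")
    for i, (aln, tree) in enumerate(zip(ds.nuclear_alignments, ds.nuclear_trees), 1):
        write_fasta(aln, os.path.join(directory, f"nuclear{i}.fasta"))
        with open(os.path.join(directory, f"nuclear{i}.tre"), "w") as fh:
            fh.write(write_newick(tree) + "\n")
    write_popmap(ds.popmap, os.path.join(directory, "popmap.txt"))
    manifest = {
        "tree_id": ds.config.tree_id,
        "rate": ds.config.rate,
        "n_per_population": ds.config.n_per_population,
        "n_nuclear_loci": ds.config.n_nuclear_loci,
        "seed": ds.seed,
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
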