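"""Species-tree models: topology, divergence times and population sizes.

A model is a rooted species tree whose internal nodes carry divergence times
``tau`` and whose every branch (extant and ancestral species alike) carries a
population-size parameter ``theta``; both are measured in expected
substitutions per site.  The two four-species study trees are

* tree 1, caterpillar ``(((A,B),C),D)`` with ages ``(tau_AB, tau_ABC, tau_root)``
* tree 2, balanced ``((A,B),(C,D))`` with ages ``(tau_AB, tau_CD, tau_root)``

at a low- or high-mutation-rate parameterisation (the high-rate values are the
low-rate values times ten).  The mitochondrial locus evolves with a 20-fold
higher mutation rate and a quarter of the (effective, maternal haploid)
population size, hence ``tau_mt = 20 tau_nuc`` and ``theta_mt = 5 theta_nuc``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .trees import RootedTree, parse_newick

__all__ = ["SpeciesTreeModel", "LocusSpec", "build_species_tree", "scale_for_locus",
           "MITO_LOCUS", "NUCLEAR_LOCUS"]

_TOPOLOGIES = {
    1: "(((A,B),C),D);",
    2: "((A,B),(C,D));",
}
_LOW_TAUS = {
    1: {frozenset("AB"): 0.001, frozenset("ABC"): 0.002, frozenset("ABCD"): 0.003},
    2: {frozenset("AB"): 0.001, frozenset("CD"): 0.001, frozenset("ABCD"): 0.003},
}
_LOW_THETA = 0.002


@dataclass
class SpeciesTreeModel:
    """A rooted species tree with per-node ages and per-branch theta."""

    tree: RootedTree
    theta: dict[frozenset, float]  # keyed by the clade below each branch
    scaled: bool = False  # True once mitochondrial scaling has been applied

    def __post_init__(self):
        self.tree.validate()
        if not self.tree.has_ages():
            raise ValueError("species tree must carry node ages (tau)")
        for node in self.tree.postorder():
            clade = self.tree.clade(node)
            if clade not in self.theta:
                raise ValueError(f"missing theta for branch above clade {sorted(clade)}")
            if self.theta[clade] <= 0:
                raise ValueError("theta must be positive")

    @property
    def species(self) -> list[str]:
        return sorted(self.tree.tip_labels())

    def tau(self, clade) -> float:
        return self.tree.mrca(frozenset(clade)).age

    @property
    def root_age(self) -> float:
        return self.tree.root.age


@dataclass(frozen=True)
class LocusSpec:
    """Locus kind with its length and mutation-rate / population-size scaling."""

    kind: str
    length: int
    tau_multiplier: float
    theta_multiplier: float

    def __post_init__(self):
        if self.kind not in ("mitochondrial", "nuclear"):
            raise ValueError("kind must be mitochondrial or nuclear")
        if self.length < 1:
            raise ValueError("length must be at least 1")


MITO_LOCUS = LocusSpec("mitochondrial", 1000, 20.0, 5.0)
NUCLEAR_LOCUS = LocusSpec("nuclear", 500, 1.0, 1.0)


def build_species_tree(tree_id: int, rate: str) -> SpeciesTreeModel:
    """The study's species-tree models (nuclear-locus parameterisation).

    Parameters
    ----------
    tree_id : {1, 2}
        1 = caterpillar ``(((A,B),C),D)``, 2 = balanced ``((A,B),(C,D))``.
    rate : {"low", "high"}
        High-rate divergence times and theta are ten times the low-rate ones.
    """
    if tree_id not in _TOPOLOGIES:
        raise ValueError(f"unknown tree id {tree_id!r}; expected 1 or 2")
    if rate not in ("low", "high"):
        raise ValueError(f"unknown rate {rate!r}; expected 'low' or 'high'")
    mult = 10.0 if rate == "high" else 1.0
    tree = parse_newick(_TOPOLOGIES[tree_id])
    taus = _LOW_TAUS[tree_id]
    for node in tree.postorder():
        node.age = 0.0 if node.is_tip else taus[tree.clade(node)] * mult
    tree.lengths_from_ages()
    theta = {tree.clade(n): _LOW_THETA * mult for n in tree.postorder()}
    return SpeciesTreeModel(tree=tree, theta=theta)


def scale_for_locus(model: SpeciesTreeModel, spec: LocusSpec) -> SpeciesTreeModel:
    """Apply a locus's tau/theta multipliers to a nuclear-scale model.

    Refuses to scale a model twice: mitochondrial scaling is not idempotent
    and an already-scaled model would silently compound the multipliers.
    """
    if spec.tau_multiplier == 1.0 and spec.theta_multiplier == 1.0:
        return model
    if model.scaled:
        raise ValueError("model already carries locus scaling; scale the nuclear-rate model")
    tree = model.tree.copy()
    for node in tree.postorder():
        node.age = node.age * spec.tau_multiplier
    tree.lengths_from_ages()
    theta = {c: v * spec.theta_multiplier for c, v in model.theta.items()}
    return SpeciesTreeModel(tree=tree, theta=theta, scaled=True)
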