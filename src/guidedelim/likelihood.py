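"""Probability kernels: JC69, pruning likelihood, MSC density, priors.

These are thin typed wrappers over the numba kernels in :mod:`._kernels`;
they accept the package's tree/alignment objects and are the API the rest of
the pipeline (and the tests) use.  Base frequencies are uniform throughout —
JC69 is both the generating and the analysis model in this study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._arrays import tree_to_arrays
from .seqio import Alignment, compress_patterns
from .species_model import SpeciesTreeModel
from .trees import RootedTree

__all__ = ["jc69_transition", "log_likelihood", "msc_log_density", "PriorConfig",
           "species_model_to_arrays"]


def jc69_transition(t: float) -> np.ndarray:
    """JC69 transition-probability matrix over a branch of length ``t``.

    Diagonal entries are ``1/4 + 3/4 e^(-4t/3)``, off-diagonals
    ``1/4 - 1/4 e^(-4t/3)``; rows sum to one.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    e = np.exp(-4.0 * t / 3.0)
    P = np.full((4, 4), 0.25 * (1.0 - e))
    np.fill_diagonal(P, 0.25 + 0.75 * e)
    return P


def log_likelihood(tree: RootedTree, aln: Alignment) -> float:
    """Felsenstein pruning log-likelihood of an alignment under JC69.

    The tree must carry node ages (clock) or branch lengths; site patterns
    are compressed before the pruning pass.
    """
    if set(tree.tip_labels()) != set(aln.labels):
        raise ValueError("tree tips and alignment labels do not match")
    work = tree
    if not work.has_ages():
        # pruning only uses branch lengths; fabricate additive "ages" by
        # rooting depths so that parent-child differences reproduce them
        work = tree.copy()
        _ages_from_unrooted_lengths(work)
    parent, child0, child1, age = tree_to_arrays(work, aln.labels)
    patterns, weights = compress_patterns(aln)
    N = parent.shape[0]
    P = patterns.shape[1]
    condL = np.zeros((N, P, 4))
    logsc = np.zeros((N, P))
    ll = _kernels.gene_loglik_full(parent, child0, child1, age,
                                   patterns, weights, condL, logsc)
    return float(ll)


def _ages_from_unrooted_lengths(tree: RootedTree) -> None:
    """Assign pseudo-ages so that age(parent) - age(child) = branch length.

    Valid for likelihood computation only (JC69 is reversible, so the root
    position and any additive re-parameterisation leave the likelihood
    unchanged); the resulting "ages" are not clock ages.
    """
    depth = {}
    for node in tree.preorder():
        depth[node] = 0.0 if node.parent is None else depth[node.parent] + node.length
    deepest = max(depth.values())
    for node in tree.postorder():
        node.age = deepest - depth[node]


def species_model_to_arrays(model: SpeciesTreeModel):
    """Flatten a species-tree model to kernel arrays.

    Returns ``(sparent, schild0, schild1, sage, stheta, tips)`` where ``tips``
    is the species-label order corresponding to tip indices ``0..ns-1``.
    """
    tips = model.species
    sparent, schild0, schild1, sage = tree_to_arrays(model.tree, tips)
    M = sparent.shape[0]
    stheta = np.zeros(M)
    # recover the clade under each node index to look up theta
    ns = len(tips)
    clade = [frozenset([t]) for t in tips] + [frozenset()] * (M - ns)
    for v in range(ns, M):
        clade[v] = clade[schild0[v]] | clade[schild1[v]]
    for v in range(M):
        stheta[v] = model.theta[clade[v]]
    return sparent, schild0, schild1, sage, stheta, tips


def msc_log_density(gtree: RootedTree, model: SpeciesTreeModel,
                    popmap: dict[str, str]) -> float:
    """Log density of a gene tree under the multispecies coalescent.

    ``popmap`` maps gene-tree tip labels to species labels.  Within a species
    branch holding ``j`` lineages, each realised coalescence contributes
    ``log(2/theta)`` and each inter-event interval ``-j(j-1) dt / theta``.
    Incompatible gene trees (a coalescence younger than the divergence of the
    species it joins) have density ``-inf``.
    """
    if not gtree.has_ages():
        raise ValueError("gene tree must carry node ages")
    sparent, schild0, schild1, sage, stheta, tips = species_model_to_arrays(model)
    labels = gtree.tip_labels()
    tip_sp = np.array([tips.index(popmap[l]) for l in labels], np.int64)
    gparent, gchild0, gchild1, gage = tree_to_arrays(gtree, labels)
    return float(_kernels.msc_logdensity(gparent, gchild0, gchild1, gage, tip_sp,
                                         sparent, schild0, schild1, sage, stheta))


@dataclass(frozen=True)
class PriorConfig:
    """Priors shared by the delimitation rjMCMC and related machinery.

    The root age tau0 and every theta take diffuse gamma priors G(shape, rate)
    with shape 1 and prior mean matching the generating value; non-root
    divergence times given tau0 follow the uniform (order-constrained) Dirichlet
    construction; the delimitation-model prior is uniform over the models the
    guide tree generates.  The species-tree MCMC instead uses the improper
    forms f(lambda) = 1/lambda and f(theta) = 1/theta.
    """

    tau0_shape: float = 1.0
    tau0_rate: float = 333.0
    theta_shape: float = 1.0
    theta_rate: float = 500.0
    model_prior: str = "uniform"  # or "orderings"

    def __post_init__(self):
        if min(self.tau0_shape, self.tau0_rate, self.theta_shape, self.theta_rate) <= 0:
            raise ValueError("gamma shapes and rates must be positive")
        if self.model_prior not in ("uniform", "orderings"):
            raise ValueError("model_prior must be 'uniform' or 'orderings'")

    @classmethod
    def for_rate(cls, rate: str, **kw) -> "PriorConfig":
        """The study priors: G(1,333)/G(1,500) at the low mutation rate
        (means 0.003 and 0.002) and G(1,33)/G(1,50) at the high rate."""
        if rate == "low":
            return cls(1.0, 333.0, 1.0, 500.0, **kw)
        if rate == "high":
            return cls(1.0, 33.0, 1.0, 50.0, **kw)
        raise ValueError(f"unknown rate {rate!r}")

    @property
    def tau0_mean(self) -> float:
        return self.tau0_shape / self.tau0_rate

    @property
    def theta_mean(self) -> float:
        return self.theta_shape / self.theta_rate
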