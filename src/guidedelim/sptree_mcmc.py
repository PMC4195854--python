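"""Bayesian species-tree inference from nuclear loci (the species-tree arm).

The sampler targets the joint posterior of the population (species) tree
topology and node ages, the per-branch theta, the Yule birth rate lambda, and
one gene tree per locus:

    p(S, tau, theta, lambda, {G_i} | X)
        ∝ Yule(S, tau | lambda) f(lambda) ∏ f(theta)
          ∏_i [ f(X_i | G_i) msc(G_i | S, tau, theta) ]

with the improper forms f(lambda) = 1/lambda and f(theta) = 1/theta (theta
truncated to a wide positive interval so the chain cannot drift along the
likelihood-flat directions of branches that host no coalescences).  Correct
assignment of sequences to the eight populations is given; sequences of a
population are *not* constrained monophyletic on the gene trees — the MSC
allows non-monophyly.

The guide tree for delimitation is the maximum a posteriori topology among
the retained samples, i.e. the modal sampled topology with per-clade mean
node ages.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._arrays import arrays_to_tree, tree_to_arrays
from .mlsearch import _upgma_subtree, jc_distance_matrix
from .seqio import Alignment, compress_patterns
from .trees import RootedTree, modal_topology

__all__ = ["SpeciesTreeMcmcConfig", "mcmc_species_tree", "map_guide_tree"]


@dataclass(frozen=True)
class SpeciesTreeMcmcConfig:
    """Chain settings for the species-tree MCMC.

    The study-scale defaults follow the full protocol (6e6 iterations,
    3000 samples taken every 2000, the last 2200 kept for the MAP tree);
    :meth:`scaled` gives the desk-scale variant used throughout the tests
    and the reproduction script (4e5 iterations, same keep fraction).
    """

    n_iterations: int = 6_000_000
    sample_interval: int = 2_000
    keep_last: int = 2_200
    theta_min: float = 1e-6
    theta_max: float = 1.0

    def __post_init__(self):
        if self.n_iterations < self.sample_interval:
            raise ValueError("chain shorter than one sampling interval")
        n_samples = self.n_iterations // self.sample_interval
        if not 0 < self.keep_last <= n_samples:
            raise ValueError("keep_last must be in (0, number of samples]")

    @classmethod
    def scaled(cls, n_iterations: int = 400_000) -> "SpeciesTreeMcmcConfig":
        interval = max(1, n_iterations // 1000)
        n_samples = n_iterations // interval
        keep = max(1, int(round(n_samples * 2200 / 3000)))
        return cls(n_iterations, interval, keep)


def _init_state(nuclear: list[Alignment], popmap: dict[str, str],
                cfg: SpeciesTreeMcmcConfig):
    """Heuristic, MSC-compatible starting state.

    Species tree: UPGMA on population-mean JC distances.  Gene trees: UPGMA
    per locus.  Species divergence times are then shrunk below the youngest
    cross-species coalescence they would conflict with, which guarantees a
    finite starting density.
    """
    labels = nuclear[0].labels
    for aln in nuclear[1:]:
        if aln.labels != labels:
            raise ValueError("all loci must share the same sequence labels")
    pops = sorted(set(popmap.values()))
    ns = len(pops)
    pop_idx = {p: i for i, p in enumerate(pops)}
    tip_sp = np.array([pop_idx[popmap[l]] for l in labels], np.int64)
    n = len(labels)
    li = {l: i for i, l in enumerate(labels)}

    # gene trees: UPGMA per locus, ages floored to be strictly increasing
    gtrees = []
    for aln in nuclear:
        D = jc_distance_matrix(aln)
        root = _upgma_subtree(labels, D)
        t = RootedTree(root)
        t.ages_from_lengths()
        for node in t.postorder():
            if not node.is_tip:
                node.age = max(node.age, max(c.age for c in node.children) + 1e-9,
                               1e-9)
        gtrees.append(tree_to_arrays(t, labels))

    # species tree: UPGMA on population-mean distances
    Dp = np.zeros((ns, ns))
    Dw = []
    for aln in nuclear:
        D = jc_distance_matrix(aln)
        for i, p in enumerate(pops):
            for j, q in enumerate(pops):
                if j <= i:
                    continue
                rows = [li[x] for x in labels if popmap[x] == p]
                cols = [li[x] for x in labels if popmap[x] == q]
                Dp[i, j] += D[np.ix_(rows, cols)].mean() / len(nuclear)
            rows = [li[x] for x in labels if popmap[x] == p]
            if len(rows) > 1:
                Dw.append(D[np.ix_(rows, rows)][np.triu_indices(len(rows), 1)].mean())
    Dp = Dp + Dp.T
    sp_tree = RootedTree(_upgma_subtree(pops, Dp / 2.0))  # ages ~ dist/2
    sp_tree.ages_from_lengths()
    for node in sp_tree.postorder():
        if not node.is_tip:
            node.age = max(node.age, max(c.age for c in node.children) * 1.05, 1e-8)
    sparent, schild0, schild1, sage = tree_to_arrays(sp_tree, pops)
    M = sparent.shape[0]

    # shrink species ages below conflicting cross coalescences (preorder)
    bound = np.full(M, np.inf)
    for gparent, gchild0, gchild1, gage in gtrees:
        N = gparent.shape[0]
        spof = np.zeros(N, np.int64)
        spof[:n] = tip_sp
        order = np.argsort(gage[n:]) + n
        for v in order:
            a, b = spof[gchild0[v]], spof[gchild1[v]]
            # species MRCA on the current species tree
            anc = set()
            x = a
            while x >= 0:
                anc.add(x)
                x = sparent[x]
            x = b
            while x not in anc:
                x = sparent[x]
            spof[v] = x
            bound[x] = min(bound[x], gage[v])
    root = int(np.where(sparent < 0)[0][0])
    for v in _preorder_internal(sparent, schild0, schild1, root):
        hi = min(bound[v] * 0.9, sage[v])
        if sparent[v] >= 0:
            hi = min(hi, sage[sparent[v]] * 0.95)
        sage[v] = max(hi, 1e-9)
        if sparent[v] >= 0 and sage[v] >= sage[sparent[v]]:
            sage[v] = sage[sparent[v]] * 0.5

    theta0 = float(np.clip(np.mean(Dw) if Dw else 1e-3, cfg.theta_min * 10,
                           cfg.theta_max / 10))
    stheta = np.full(M, max(theta0, 1e-5))
    B = sum(sage[sparent[v]] - sage[v] for v in range(M) if sparent[v] >= 0)
    lam0 = (ns - 1) / max(B, 1e-9)
    return pops, tip_sp, gtrees, sparent, schild0, schild1, sage, stheta, lam0, root


def _preorder_internal(sparent, schild0, schild1, root):
    out, stack = [], [root]
    while stack:
        v = stack.pop()
        if schild0[v] >= 0:
            out.append(v)
            stack.append(schild0[v])
            stack.append(schild1[v])
    return out


def mcmc_species_tree(nuclear: list[Alignment], popmap: dict[str, str],
                      cfg: SpeciesTreeMcmcConfig, seed: int,
                      likelihood_on: bool = True,
                      lambda_fixed: float | None = None) -> list[RootedTree]:
    """Run the species-tree MCMC and return the sampled species trees.

    ``lambda_fixed`` pins the Yule birth rate (used by the prior-sampling
    validation runs, where the improper 1/lambda prior would make the
    likelihood-free target improper); ``likelihood_on=False`` replaces the
    sequence likelihood by 1 for such runs.
    """
    if not nuclear:
        raise ValueError("need at least one nuclear locus")
    (pops, tip_sp, gtrees, sparent, schild0, schild1, sage, stheta,
     lam0, root) = _init_state(nuclear, popmap, cfg)

    L = len(nuclear)
    pats = [compress_patterns(a) for a in nuclear]
    Pmax = max(p.shape[1] for p, _ in pats)
    n = len(nuclear[0].labels)
    N = 2 * n - 1
    tipdata = np.zeros((L, n, Pmax), np.int8)
    weights = np.zeros((L, Pmax), np.float64)
    for l, (p, w) in enumerate(pats):
        tipdata[l, :, :p.shape[1]] = p
        weights[l, :w.shape[0]] = w
    gparent = np.stack([g[0] for g in gtrees])
    gchild0 = np.stack([g[1] for g in gtrees])
    gchild1 = np.stack([g[2] for g in gtrees])
    gage = np.stack([g[3] for g in gtrees])

    if lambda_fixed is not None:
        lam0 = float(lambda_fixed)
    samp_c0, samp_c1, samp_age, acc, trials = _kernels.run_sptree_mcmc(
        seed, cfg.n_iterations, cfg.sample_interval,
        tipdata, weights, tip_sp,
        sparent, schild0, schild1, sage, stheta,
        gparent, gchild0, gchild1, gage,
        lam0, likelihood_on, lambda_fixed is not None,
        cfg.theta_min, cfg.theta_max)

    samples = []
    M = sparent.shape[0]
    for k in range(samp_c0.shape[0]):
        par = np.full(M, -1, np.int64)
        for v in range(M):
            if samp_c0[k, v] >= 0:
                par[samp_c0[k, v]] = v
                par[samp_c1[k, v]] = v
        samples.append(arrays_to_tree(par, samp_c0[k], samp_c1[k],
                                      samp_age[k], pops))
    return samples


def map_guide_tree(samples: list[RootedTree], keep_last: int) -> RootedTree:
    """MAP (modal) topology among the last ``keep_last`` sampled trees."""
    if not samples:
        raise ValueError("no samples")
    if keep_last > len(samples):
        raise ValueError("keep_last exceeds the number of samples")
    return modal_topology(samples[-keep_last:], burn_in_fraction=0.0)
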