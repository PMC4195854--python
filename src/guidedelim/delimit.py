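"""Bayesian species delimitation on a fixed guide tree by rjMCMC.

Delimitation models are generated by collapsing internal nodes of a rooted
guide tree over populations: a model is an ancestor-closed set of "split"
(speciation) nodes — a node can be split only if its parent is split.  A
split node carries a divergence time tau; every population lineage present
in the current model carries its own theta.  The reversible-jump sampler
adds or removes one split at a time: a split draws the new tau uniformly
below both the parent's tau and the youngest gene coalescence joining the
two daughter sides (any larger value has zero density), and draws the two
newly distinguished thetas from their gamma prior, which makes the
dimension-matching terms cancel against the prior.

Following the study protocol, an analysis consists of two independent runs
whose samples are pooled after per-run burn-in; disagreement between runs
beyond a tolerance is flagged in the diagnostics.  The rjMCMC algorithm tags
of the original protocol (algorithm 0 with epsilon = 2, algorithm 1 with
alpha = 2, m = 1) parameterise kernels of another implementation; they are
recorded as provenance only — the stationary distribution does not depend
on the kernel, and this module uses its own jump construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._arrays import tree_to_arrays
from .likelihood import PriorConfig
from .mlsearch import _upgma_subtree, jc_distance_matrix
from .seqio import Alignment, compress_patterns
from .trees import RootedTree

__all__ = ["RjmcmcConfig", "SplitPosterior", "enumerate_models", "rjmcmc_delimit",
           "count_models"]


@dataclass(frozen=True)
class RjmcmcConfig:
    """Chain settings for the delimitation sampler.

    Defaults are the study protocol: burn-in 5000, 20,000 samples taken every
    2 sweeps, two independent runs combined.  ``algorithm_tags`` is
    provenance metadata only.
    """

    burn_in: int = 5_000
    n_samples: int = 20_000
    sample_interval: int = 2
    n_runs: int = 2
    algorithm_tags: tuple = ("rj0(eps=2)", "rj1(alpha=2,m=1)")
    run_agreement_tol: float = 0.1
    eps_mix: float = 0.5
    autotune: bool = True

    def __post_init__(self):
        if min(self.burn_in, self.n_samples, self.sample_interval, self.n_runs) < 1:
            raise ValueError("chain settings must be positive")

    @classmethod
    def scaled(cls, burn_in: int = 2_000, n_samples: int = 5_000, **kw) -> "RjmcmcConfig":
        return cls(burn_in=burn_in, n_samples=n_samples, **kw)


@dataclass
class SplitPosterior:
    """Posterior summaries of a delimitation analysis.

    Split probabilities are keyed by the clade (frozenset of population
    labels) under each internal guide-tree node, which is robust to node
    renumbering.  ``model_probs`` keys are the sorted tuple of split clades.
    """

    split_prob: dict
    model_probs: dict
    tau0_mean: float
    theta_mean: float
    n_samples: int
    per_run_split_prob: list
    diagnostics: dict = field(default_factory=dict)
    raw_split_samples: "np.ndarray | None" = None  # (n_samples, n_nodes) uint8
    node_clades: list | None = None                # clade per column

    def prob(self, clade) -> float:
        return self.split_prob[frozenset(clade)]


# ----------------------------------------------------------------------


def enumerate_models(guide: RootedTree) -> list[frozenset]:
    """All delimitation models of a guide tree.

    Each model is returned as a frozenset of split clades (tip-label sets of
    the split nodes); the empty frozenset is the one-species model.  The
    count obeys N(tip) = 1, N(node) = 1 + N(left) * N(right).
    """
    guide.validate()

    def rec(node) -> list[frozenset]:
        if node.is_tip:
            return [frozenset()]
        left, right = (rec(c) for c in node.children)
        out = [frozenset()]  # this node collapsed (entire subtree one species)
        me = frozenset([guide.clade(node)])
        for lm in left:
            for rm in right:
                out.append(me | lm | rm)
        return out

    return rec(guide.root)


def count_models(guide: RootedTree) -> int:
    return len(enumerate_models(guide))


# ----------------------------------------------------------------------


def _init_gene_trees(loci: list[Alignment], labels: list[str]):
    gtrees = []
    for aln in loci:
        D = jc_distance_matrix(aln)
        t = RootedTree(_upgma_subtree(labels, D))
        t.ages_from_lengths()
        for node in t.postorder():
            if not node.is_tip:
                node.age = max(node.age, max(c.age for c in node.children) + 1e-9,
                               1e-9)
        gtrees.append(tree_to_arrays(t, labels))
    return gtrees


def rjmcmc_delimit(loci: list[Alignment], guide: RootedTree,
                   popmap: dict[str, str], prior: PriorConfig,
                   cfg: RjmcmcConfig, seed: int,
                   likelihood_on: bool = True) -> SplitPosterior:
    """Posterior split probabilities by reversible-jump MCMC.

    ``popmap`` maps sequence labels to guide-tree tip (population) labels.
    Runs ``cfg.n_runs`` independent chains from seeds derived from ``seed``
    and pools their samples; per-run split probabilities are kept for the
    between-run agreement diagnostic.
    """
    if not loci:
        raise ValueError("need at least one locus")
    guide.validate()
    pops = sorted(guide.tip_labels())
    if set(popmap.values()) != set(pops):
        raise ValueError("population map does not match the guide-tree tips")
    labels = loci[0].labels
    for aln in loci[1:]:
        if aln.labels != labels:
            raise ValueError("all loci must share the same sequence labels")
    missing = set(labels) - set(popmap)
    if missing:
        raise ValueError(f"sequences missing from the population map: {sorted(missing)}")

    # guide-tree arrays; node ages are sampler state, so only topology is used
    gtopo = guide.copy()
    for node in gtopo.postorder():
        node.age = None
        node.length = None
    sparent, schild0, schild1, _ = tree_to_arrays_topology(gtopo, pops)
    M = sparent.shape[0]
    ns = len(pops)
    pop_idx = {p: i for i, p in enumerate(pops)}
    tip_sp = np.array([pop_idx[popmap[l]] for l in labels], np.int64)

    gtrees = _init_gene_trees(loci, labels)
    pats = [compress_patterns(a) for a in loci]
    Pmax = max(p.shape[1] for p, _ in pats)
    n = len(labels)
    L = len(loci)
    tipdata = np.zeros((L, n, Pmax), np.int8)
    weights = np.zeros((L, Pmax), np.float64)
    for l, (p, w) in enumerate(pats):
        tipdata[l, :, :p.shape[1]] = p
        weights[l, :w.shape[0]] = w

    # clade labels per node index (for keying output)
    clade_of = _clades_by_index(sparent, schild0, schild1, pops)
    root = int(np.where(sparent < 0)[0][0])

    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31 - 2)) + 1 for s in ss.spawn(cfg.n_runs)]
    pooled_split = []
    pooled_tau = []
    pooled_theta = []
    per_run = []
    diagnostics = {"algorithm_tags": list(cfg.algorithm_tags), "eps_mix_final": []}
    for run_seed in run_seeds:
        gparent = np.stack([g[0] for g in gtrees])
        gchild0 = np.stack([g[1] for g in gtrees])
        gchild1 = np.stack([g[2] for g in gtrees])
        gage = np.stack([g[3] for g in gtrees])
        sage, stheta, split = _init_model(sparent, schild0, schild1, root, prior,
                                          gparent, gchild0, gchild1, gage, tip_sp)
        samp_split, samp_tau, samp_theta, acc, trials, eps = _kernels.run_rjmcmc(
            run_seed, cfg.burn_in, cfg.n_samples * cfg.sample_interval,
            cfg.sample_interval,
            tipdata, weights, tip_sp,
            sparent, schild0, schild1, sage, stheta, split,
            gparent, gchild0, gchild1, gage,
            prior.tau0_shape, prior.tau0_rate, prior.theta_shape, prior.theta_rate,
            likelihood_on, cfg.eps_mix, cfg.autotune)
        pooled_split.append(samp_split)
        pooled_tau.append(samp_tau)
        pooled_theta.append(samp_theta)
        per_run.append({clade_of[v]: float(samp_split[:, v].mean())
                        for v in range(M) if schild0[v] >= 0})
        diagnostics["eps_mix_final"].append(float(eps))

    S = np.concatenate(pooled_split)
    T = np.concatenate(pooled_tau)
    TH = np.concatenate(pooled_theta)
    split_prob = {clade_of[v]: float(S[:, v].mean())
                  for v in range(M) if schild0[v] >= 0}
    # per-model posterior over visited models
    internal = [v for v in range(M) if schild0[v] >= 0]
    keys, counts = np.unique(S[:, internal], axis=0, return_counts=True)
    model_probs = {}
    for row, c in zip(keys, counts):
        model = frozenset(clade_of[v] for v, bit in zip(internal, row) if bit)
        model_probs[model] = model_probs.get(model, 0.0) + c / S.shape[0]

    max_dis = 0.0
    if len(per_run) > 1:
        for cl in per_run[0]:
            vals = [r[cl] for r in per_run]
            max_dis = max(max_dis, max(vals) - min(vals))
    diagnostics["max_between_run_disagreement"] = max_dis
    diagnostics["runs_agree"] = bool(max_dis <= cfg.run_agreement_tol)

    root_split = S[:, root].astype(bool)
    tau0_mean = float(T[root_split, root].mean()) if root_split.any() else 0.0
    theta_mean = float(TH[:, root].mean())
    return SplitPosterior(split_prob, model_probs, tau0_mean, theta_mean,
                          int(S.shape[0]), per_run, diagnostics,
                          raw_split_samples=S, node_clades=list(clade_of))


def tree_to_arrays_topology(tree: RootedTree, tip_order):
    """Like :func:`tree_to_arrays` but tolerating absent ages."""
    for node in tree.postorder():
        if node.age is None:
            node.age = 0.0
    return tree_to_arrays(tree, tip_order)


def _clades_by_index(sparent, schild0, schild1, pops):
    M = sparent.shape[0]
    ns = len(pops)
    clade = [frozenset([p]) for p in pops] + [frozenset()] * (M - ns)
    # postorder accumulation
    done = [v < ns for v in range(M)]
    while not all(done):
        for v in range(ns, M):
            if not done[v] and done[schild0[v]] and done[schild1[v]]:
                clade[v] = clade[schild0[v]] | clade[schild1[v]]
                done[v] = True
    return clade


def _init_model(sparent, schild0, schild1, root, prior,
                gparent, gchild0, gchild1, gage, tip_sp):
    """Fully split starting model with gene-tree-compatible taus."""
    M = sparent.shape[0]
    ns = (M + 1) // 2
    sage = np.zeros(M)
    stheta = np.full(M, prior.theta_mean)
    split = np.zeros(M, np.bool_)
    for v in range(M):
        if schild0[v] >= 0:
            split[v] = True
    pmask = _kernels._pop_masks(schild0, schild1, sparent)
    # preorder: parent bounds apply
    order = [root]
    i = 0
    while i < len(order):
        v = order[i]
        i += 1
        if schild0[v] >= 0:
            order.extend([int(schild0[v]), int(schild1[v])])
    for v in order:
        if schild0[v] < 0:
            continue
        bound = _kernels._cross_bound(v, schild0, schild1, pmask,
                                      gparent, gchild0, gchild1, gage, tip_sp)
        hi = bound * 0.9
        if sparent[v] >= 0:
            hi = min(hi, sage[sparent[v]] * 0.9)
        sage[v] = max(hi, 1e-10)
        if sparent[v] >= 0 and sage[v] >= sage[sparent[v]]:
            sage[v] = sage[sparent[v]] * 0.5
    return sage, stheta, split
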