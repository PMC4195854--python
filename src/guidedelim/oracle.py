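"""Independent verification oracle for small delimitation problems.

For guide trees of at most 3 populations with at most 2 sequences each and a
single locus, the posterior over delimitation models can be computed without
any MCMC: the marginal likelihood of each model is the prior-predictive
expectation of the sequence likelihood,

    m(X | model) = E[ f(X | G) ],   (tau, theta) ~ prior,  G ~ MSC(tau, theta),

estimated here by plain Monte Carlo with a large number of independent
draws (the integrand is bounded and the problems are small enough for the
estimator to be tight; the returned standard errors quantify it).  Combined
with the uniform model prior this yields per-model posterior probabilities
that are independent of the rjMCMC code path they are used to check.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from ._arrays import tree_to_arrays
from .delimit import enumerate_models, tree_to_arrays_topology, _clades_by_index
from .likelihood import PriorConfig
from .seqio import Alignment, compress_patterns
from .trees import RootedTree

__all__ = ["oracle_posterior"]


def oracle_posterior(loci: list[Alignment], guide: RootedTree,
                     popmap: dict[str, str], prior: PriorConfig,
                     n_draws: int = 200_000, seed: int = 1) -> dict:
    """Per-model posterior probabilities by enumeration + Monte Carlo.

    Returns a dict with ``probs`` (model -> probability, models keyed as
    frozensets of split clades), ``log_marginals`` and ``se`` (per-model
    Monte Carlo standard errors on the log marginal likelihood).  Refuses
    problems beyond its exhaustive-verification envelope.
    """
    if len(loci) != 1:
        raise ValueError("oracle handles exactly one locus")
    pops = sorted(guide.tip_labels())
    if len(pops) > 3:
        raise ValueError("oracle handles at most 3 populations")
    counts = {}
    for seq, pop in popmap.items():
        counts[pop] = counts.get(pop, 0) + 1
    if max(counts.values()) > 2:
        raise ValueError("oracle handles at most 2 sequences per population")
    aln = loci[0]
    labels = aln.labels

    gtopo = guide.copy()
    sparent, schild0, schild1, _ = tree_to_arrays_topology(gtopo, pops)
    M = sparent.shape[0]
    clade_of = _clades_by_index(sparent, schild0, schild1, pops)
    pop_idx = {p: i for i, p in enumerate(pops)}
    tip_sp = np.array([pop_idx[popmap[l]] for l in labels], np.int64)
    patterns, weights = compress_patterns(aln)

    models = enumerate_models(guide)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 2)) + 1
             for s in ss.spawn(len(models))]
    log_marg, ses = {}, {}
    for model, mseed in zip(models, seeds):
        split = np.zeros(M, np.bool_)
        for v in range(M):
            if schild0[v] >= 0 and clade_of[v] in model:
                split[v] = True
        lls = _kernels.oracle_model_logliks(
            mseed, n_draws, sparent, schild0, schild1, split, tip_sp,
            patterns, weights, prior.tau0_shape, prior.tau0_rate,
            prior.theta_shape, prior.theta_rate)
        m = lls.max()
        w = np.exp(lls - m)
        mean = w.mean()
        log_marg[model] = float(m + np.log(mean))
        ses[model] = float(w.std() / (mean * np.sqrt(len(w))))

    # uniform prior over models; "orderings" weighting optional
    logw = {}
    for model in models:
        lw = log_marg[model]
        if prior.model_prior == "orderings":
            lw += np.log(_n_orderings(model))
        logw[model] = lw
    top = max(logw.values())
    raw = {mdl: np.exp(lw - top) for mdl, lw in logw.items()}
    Z = sum(raw.values())
    probs = {mdl: v / Z for mdl, v in raw.items()}
    return {"probs": probs, "log_marginals": log_marg, "se": ses,
            "n_draws": n_draws}


def _n_orderings(model: frozenset) -> int:
    """Number of linear extensions of a model's split-clade poset.

    The poset is ordered by clade containment; the count is
    K! / prod(subtree sizes), the standard forest-heap formula.
    """
    import math

    clades_ = sorted(model, key=len)
    K = len(clades_)
    if K == 0:
        return 1
    sizes = {}
    for c in clades_:  # ascending size: children before parents
        sizes[c] = 1 + sum(sizes[d] for d in clades_ if d < c and
                           _is_child(d, c, clades_))
    out = math.factorial(K)
    for s in sizes.values():
        out //= s
    return out


def _is_child(d, c, all_clades) -> bool:
    """Is d an immediate sub-clade of c within the model's clade set?"""
    if not d < c:
        return False
    return not any(d < e < c for e in all_clades)
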