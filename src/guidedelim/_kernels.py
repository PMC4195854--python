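"""Numba kernels: JC69 pruning, MSC density, simulation, and MCMC engines.

Everything here operates on flat integer/float arrays so the samplers can run
millions of elementary moves per minute on one core.  Conventions:

* A gene tree over ``n`` tips has ``N = 2n - 1`` nodes; tips are ``0..n-1``.
  ``parent/child0/child1`` are index arrays (``-1`` for absent), ``age`` holds
  node ages in expected substitutions per site (tips at 0).
* A species (or guide) tree over ``ns`` tips has ``M = 2*ns - 1`` nodes in the
  same layout; ``sage`` holds divergence times tau and ``stheta`` the
  population-size parameters theta.  In the delimitation sampler, collapsed
  guide nodes simply carry ``tau = 0``: a zero-length species branch hosts no
  coalescent events and contributes nothing to the density, which reproduces
  the convention that the populations under a collapsed node form one species
  whose theta is the one of the subtree root.
* Site data are compressed patterns: ``tipdata`` of shape ``(n, P)`` with
  states 0..3 (T,C,A,G) and per-pattern ``weights``.
* All randomness goes through numba's ``np.random.*`` seeded once per kernel
  call, so runs are reproducible from an integer seed.
"""

import math

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's global RNG state (shared by the simulation kernels)."""
    np.random.seed(seed)


# ======================================================================
# tree traversal helpers


@njit(cache=True)
def _postorder(child0, child1, root, out):
    """Fill ``out`` with a postorder of the internal nodes below ``root``."""
    stack = np.empty(out.shape[0] * 2 + 2, np.int64)
    tmp = np.empty(out.shape[0] * 2 + 2, np.int64)
    ns = 0
    nt = 0
    stack[ns] = root
    ns += 1
    while ns > 0:
        ns -= 1
        v = stack[ns]
        if child0[v] >= 0:
            tmp[nt] = v
            nt += 1
            stack[ns] = child0[v]
            ns += 1
            stack[ns] = child1[v]
            ns += 1
    k = 0
    for i in range(nt - 1, -1, -1):
        out[k] = tmp[i]
        k += 1
    return k


@njit(cache=True)
def _find_root(parent):
    for v in range(parent.shape[0]):
        if parent[v] < 0:
            return v
    return -1


@njit(cache=True)
def _mrca_sp(sparent, a, b):
    """MRCA of two species-tree nodes (allocation-free two-pointer climb)."""
    da = 0
    x = a
    while sparent[x] >= 0:
        x = sparent[x]
        da += 1
    db = 0
    x = b
    while sparent[x] >= 0:
        x = sparent[x]
        db += 1
    while da > db:
        a = sparent[a]
        da -= 1
    while db > da:
        b = sparent[b]
        db -= 1
    while a != b:
        a = sparent[a]
        b = sparent[b]
    return a


# ======================================================================
# JC69 pruning likelihood


@njit(cache=True)
def _update_gene_node(v, child0, child1, age, tipdata, condL, logsc):
    """Recompute the conditional likelihoods at internal node ``v``.

    Returns False if a branch length would be negative (invalid state).
    """
    n = tipdata.shape[0]
    c0 = child0[v]
    c1 = child1[v]
    t0 = age[v] - age[c0]
    t1 = age[v] - age[c1]
    if t0 < 0.0 or t1 < 0.0:
        return False
    e0 = math.exp(-4.0 * t0 / 3.0)
    e1 = math.exp(-4.0 * t1 / 3.0)
    a0 = 0.25 * (1.0 - e0)
    a1 = 0.25 * (1.0 - e1)
    P = tipdata.shape[1]
    for p in range(P):
        sc = 0.0
        if c0 < n:
            s0 = tipdata[c0, p]
            f00 = a0
            f01 = a0
            f02 = a0
            f03 = a0
            if s0 == 0:
                f00 = a0 + e0
            elif s0 == 1:
                f01 = a0 + e0
            elif s0 == 2:
                f02 = a0 + e0
            else:
                f03 = a0 + e0
        else:
            S0 = condL[c0, p, 0] + condL[c0, p, 1] + condL[c0, p, 2] + condL[c0, p, 3]
            f00 = a0 * S0 + e0 * condL[c0, p, 0]
            f01 = a0 * S0 + e0 * condL[c0, p, 1]
            f02 = a0 * S0 + e0 * condL[c0, p, 2]
            f03 = a0 * S0 + e0 * condL[c0, p, 3]
            sc += logsc[c0, p]
        if c1 < n:
            s1 = tipdata[c1, p]
            f10 = a1
            f11 = a1
            f12 = a1
            f13 = a1
            if s1 == 0:
                f10 = a1 + e1
            elif s1 == 1:
                f11 = a1 + e1
            elif s1 == 2:
                f12 = a1 + e1
            else:
                f13 = a1 + e1
        else:
            S1 = condL[c1, p, 0] + condL[c1, p, 1] + condL[c1, p, 2] + condL[c1, p, 3]
            f10 = a1 * S1 + e1 * condL[c1, p, 0]
            f11 = a1 * S1 + e1 * condL[c1, p, 1]
            f12 = a1 * S1 + e1 * condL[c1, p, 2]
            f13 = a1 * S1 + e1 * condL[c1, p, 3]
            sc += logsc[c1, p]
        v0 = f00 * f10
        v1 = f01 * f11
        v2 = f02 * f12
        v3 = f03 * f13
        m = v0
        if v1 > m:
            m = v1
        if v2 > m:
            m = v2
        if v3 > m:
            m = v3
        if m <= 0.0:
            m = 1e-300
        condL[v, p, 0] = v0 / m
        condL[v, p, 1] = v1 / m
        condL[v, p, 2] = v2 / m
        condL[v, p, 3] = v3 / m
        logsc[v, p] = sc + math.log(m)
    return True


@njit(cache=True)
def _root_loglik(root, condL, logsc, weights):
    tot = 0.0
    P = weights.shape[0]
    for p in range(P):
        L = 0.25 * (condL[root, p, 0] + condL[root, p, 1]
                    + condL[root, p, 2] + condL[root, p, 3])
        if L <= 0.0:
            return NEG_INF
        tot += weights[p] * (math.log(L) + logsc[root, p])
    return tot


@njit(cache=True)
def gene_loglik_full(parent, child0, child1, age, tipdata, weights, condL, logsc):
    """Full postorder Felsenstein pruning under JC69; returns the log-likelihood."""
    N = parent.shape[0]
    root = _find_root(parent)
    order = np.empty((N - 1) // 2 + 1, np.int64)
    k = _postorder(child0, child1, root, order)
    for i in range(k):
        if not _update_gene_node(order[i], child0, child1, age, tipdata, condL, logsc):
            return NEG_INF
    return _root_loglik(root, condL, logsc, weights)


@njit(cache=True)
def gene_loglik_path(v, parent, child0, child1, age, tipdata, weights, condL, logsc):
    """Update conditionals from ``v`` up to the root; returns the log-likelihood."""
    x = v
    while x >= 0:
        if not _update_gene_node(x, child0, child1, age, tipdata, condL, logsc):
            return NEG_INF
        x = parent[x]
    return _root_loglik(_find_root(parent), condL, logsc, weights)


@njit(cache=True)
def gene_loglik_path2(va, vb, parent, child0, child1, age, tipdata, weights,
                      condL, logsc):
    """Update conditionals along two root paths (after a subtree exchange).

    The union of the two paths is refreshed in age order, so every child is
    updated before its parent (node ages are strictly increasing root-wards).
    """
    path = np.empty(128, np.int64)
    k = 0
    x = va
    while x >= 0:
        path[k] = x
        k += 1
        x = parent[x]
    x = vb
    while x >= 0:
        dup = False
        for i in range(k):
            if path[i] == x:
                dup = True
                break
        if not dup:
            path[k] = x
            k += 1
        x = parent[x]
    # insertion sort by age, ascending
    for i in range(1, k):
        key = path[i]
        a = age[key]
        j = i - 1
        while j >= 0 and age[path[j]] > a:
            path[j + 1] = path[j]
            j -= 1
        path[j + 1] = key
    for i in range(k):
        if not _update_gene_node(path[i], child0, child1, age, tipdata,
                                 condL, logsc):
            return NEG_INF
    return _root_loglik(_find_root(parent), condL, logsc, weights)


# ======================================================================
# multispecies-coalescent gene-tree density


@njit(cache=True)
def msc_logdensity(gparent, gchild0, gchild1, gage, tip_sp,
                   sparent, schild0, schild1, sage, stheta):
    """Log density of a gene tree under the MSC on a species tree.

    Returns ``-inf`` for gene trees incompatible with the species tree
    (a coalescence older than its children is also rejected).
    """
    N = gparent.shape[0]
    n = (N + 1) // 2
    M = sparent.shape[0]

    # one scratch buffer for all index arrays (allocation cost dominates the
    # samplers otherwise; this function runs tens of thousands of times per
    # second inside the MCMC kernels)
    ws = np.zeros((n - 1) + N + 5 * M + 2, np.int64)
    order = ws[0:n - 1]
    assign = ws[n - 1:n - 1 + N]
    ncoal = ws[n - 1 + N:n - 1 + N + M]
    n_in = ws[n - 1 + N + M:n - 1 + N + 2 * M]
    sorder = ws[n - 1 + N + 2 * M:n - 1 + N + 3 * M]
    sstack = ws[n - 1 + N + 3 * M:n - 1 + N + 5 * M + 2]

    # ascending-age order of internal gene nodes (children precede parents
    # because a parent is strictly older in any valid gene tree)
    for i in range(n - 1):
        key = n + i
        a = gage[key]
        j = i - 1
        while j >= 0 and gage[order[j]] > a:
            order[j + 1] = order[j]
            j -= 1
        order[j + 1] = key

    for i in range(n):
        assign[i] = tip_sp[i]
    for i in range(n - 1):
        v = order[i]
        c0 = gchild0[v]
        c1 = gchild1[v]
        if gage[v] < gage[c0] or gage[v] < gage[c1]:
            return NEG_INF
        s = _mrca_sp(sparent, assign[c0], assign[c1])
        if gage[v] < sage[s]:
            return NEG_INF
        while sparent[s] >= 0 and gage[v] >= sage[sparent[s]]:
            s = sparent[s]
        assign[v] = s

    for i in range(n - 1):
        ncoal[assign[order[i]]] += 1

    for i in range(n):
        n_in[tip_sp[i]] += 1
    # species postorder (internal nodes), allocation-free DFS
    sroot = _find_root(sparent)
    top = 0
    sstack[top] = sroot
    top += 1
    nint = 0
    while top > 0:
        top -= 1
        s = sstack[top]
        if schild0[s] >= 0:
            sorder[nint] = s
            nint += 1
            sstack[top] = schild0[s]
            top += 1
            sstack[top] = schild1[s]
            top += 1
    # reverse to children-first order
    for i in range(nint // 2):
        tmp = sorder[i]
        sorder[i] = sorder[nint - 1 - i]
        sorder[nint - 1 - i] = tmp
    for i in range(nint):
        s = sorder[i]
        c0 = schild0[s]
        c1 = schild1[s]
        n_in[s] += (n_in[c0] - ncoal[c0]) + (n_in[c1] - ncoal[c1])

    total = 0.0
    for s in range(M):
        k = n_in[s]
        th = stheta[s]
        t_prev = sage[s]
        for i in range(n - 1):
            v = order[i]
            if assign[v] == s:
                t = gage[v]
                if k < 2:
                    return NEG_INF
                total += math.log(2.0 / th) - k * (k - 1) * (t - t_prev) / th
                k -= 1
                t_prev = t
        if sparent[s] >= 0:
            total -= k * (k - 1) * (sage[sparent[s]] - t_prev) / th
    return total


# ======================================================================
# simulation


@njit(cache=True)
def sim_gene_tree(sparent, schild0, schild1, sage, stheta, tip_sp,
                  gparent, gchild0, gchild1, gage):
    """Simulate one gene tree under the MSC; fills the four output arrays.

    ``tip_sp`` maps each of the ``n`` gene tips to a species-tree tip node.
    Within a branch holding ``k`` lineages with parameter theta, the waiting
    time to the next coalescence is Exponential(rate k(k-1)/theta); the pair
    is chosen uniformly; survivors pass to the parent branch at its tau.
    """
    n = tip_sp.shape[0]
    M = sparent.shape[0]
    pool = np.full((M, n), -1, np.int64)
    cnt = np.zeros(M, np.int64)
    for i in range(n):
        s = tip_sp[i]
        pool[s, cnt[s]] = i
        cnt[s] += 1
        gparent[i] = -1
        gchild0[i] = -1
        gchild1[i] = -1
        gage[i] = 0.0

    sroot = _find_root(sparent)
    sorder = np.empty(M, np.int64)
    _postorder(schild0, schild1, sroot, sorder)
    # process every species branch in postorder (tips first)
    proc = np.empty(M, np.int64)
    np_ = 0
    # species postorder including tips: sort nodes by age with tips first
    done = np.zeros(M, np.uint8)
    # simple repeated scan (M is tiny): a node is ready when its children are done
    while np_ < M:
        for s in range(M):
            if done[s]:
                continue
            if schild0[s] < 0 or (done[schild0[s]] and done[schild1[s]]):
                proc[np_] = s
                np_ += 1
                done[s] = 1
    nxt = n  # next internal gene node id
    for ii in range(M):
        s = proc[ii]
        if schild0[s] >= 0:
            # inherit survivors from children
            for c in (schild0[s], schild1[s]):
                for j in range(cnt[c]):
                    pool[s, cnt[s]] = pool[c, j]
                    cnt[s] += 1
        k = cnt[s]
        t = sage[s]
        is_root = sparent[s] < 0
        upper = 1e308 if is_root else sage[sparent[s]]
        th = stheta[s]
        while k > 1:
            rate = k * (k - 1) / th
            t_next = t + np.random.exponential(1.0 / rate)
            if t_next >= upper:
                break
            t = t_next
            i = np.random.randint(k)
            j = np.random.randint(k - 1)
            if j >= i:
                j += 1
            a = pool[s, i]
            b = pool[s, j]
            v = nxt
            nxt += 1
            gchild0[v] = a
            gchild1[v] = b
            gparent[a] = v
            gparent[b] = v
            gage[v] = t
            gparent[v] = -1
            # replace a by v, remove b
            pool[s, i] = v
            pool[s, j] = pool[s, k - 1]
            pool[s, k - 1] = -1
            k -= 1
        cnt[s] = k
    return nxt - 1  # root index (== 2n-2 when fully coalesced)


@njit(cache=True)
def sim_sequences(gparent, gage, length, out):
    """Simulate JC69 sequences down a gene tree; ``out`` is (N, length) int8.

    The root state is uniform on the four bases per site; along a branch of
    length t a site keeps its state with probability e^(-4t/3) and otherwise
    lands on a uniformly drawn base.
    """
    N = gparent.shape[0]
    order = np.argsort(-gage)  # parents strictly older -> visited first
    for oi in range(N):
        v = order[oi]
        if gparent[v] < 0:
            for s in range(length):
                out[v, s] = np.random.randint(4)
        else:
            t = gage[gparent[v]] - gage[v]
            e = math.exp(-4.0 * t / 3.0)
            u = gparent[v]
            for s in range(length):
                if np.random.random() < e:
                    out[v, s] = out[u, s]
                else:
                    out[v, s] = np.random.randint(4)


# ======================================================================
# prior-predictive Monte Carlo (delimitation-model oracle)


@njit(cache=True)
def oracle_model_logliks(seed, ndraw, sparent, schild0, schild1, split, tip_sp,
                         tipdata, weights, tau0_shape, tau0_rate,
                         theta_shape, theta_rate):
    """Sequence log-likelihoods under draws from one delimitation model's prior.

    For each draw: sample tau0 from its gamma prior, the other split-node
    ages uniformly given tau0 (rejection against the order constraints),
    thetas of active lineages from their gamma prior, a gene tree from the
    MSC, and score the alignment by pruning.  The log-mean-exp of the result
    estimates the model's marginal likelihood.
    """
    np.random.seed(seed)
    M = sparent.shape[0]
    root = _find_root(sparent)
    n = tip_sp.shape[0]
    N = 2 * n - 1
    out = np.empty(ndraw)
    sage = np.zeros(M)
    stheta = np.ones(M)
    gparent = np.empty(N, np.int64)
    gchild0 = np.empty(N, np.int64)
    gchild1 = np.empty(N, np.int64)
    gage = np.zeros(N)
    condL = np.zeros((N, tipdata.shape[1], 4))
    logsc = np.zeros((N, tipdata.shape[1]))
    for it in range(ndraw):
        for v in range(M):
            sage[v] = 0.0
        if split[root]:
            tau0 = np.random.gamma(tau0_shape, 1.0 / tau0_rate)
            sage[root] = tau0
            ok = False
            while not ok:
                ok = True
                for v in range(M):
                    if v != root and schild0[v] >= 0 and split[v]:
                        sage[v] = tau0 * np.random.random()
                for v in range(M):
                    if v != root and schild0[v] >= 0 and split[v]:
                        if sage[v] >= sage[sparent[v]]:
                            ok = False
        for v in range(M):
            if v == root or split[sparent[v]]:
                stheta[v] = np.random.gamma(theta_shape, 1.0 / theta_rate)
            else:
                stheta[v] = 1.0  # inactive: zero-length branch, never used
        sim_gene_tree(sparent, schild0, schild1, sage, stheta, tip_sp,
                      gparent, gchild0, gchild1, gage)
        out[it] = gene_loglik_full(gparent, gchild0, gchild1, gage,
                                   tipdata, weights, condL, logsc)
    return out


# ======================================================================
# shared gene-tree MCMC moves
#
# The acceptance target for every gene-tree move is
#   loglik(locus) + msc(locus)
# (priors and the Yule/age terms involve no gene-tree quantities), so the
# species-tree sampler and the rjMCMC delimitation sampler share these.


@njit(cache=True)
def _gene_age_slide(l, gparent, gchild0, gchild1, gage, tipdata, weights,
                    condL, logsc, tip_sp, sparent, schild0, schild1, sage, stheta,
                    cur_ll, cur_msc, likelihood_on):
    """Uniform slide of one internal node age within its local bracket."""
    N = gparent[l].shape[0]
    n = (N + 1) // 2
    v = n + np.random.randint(n - 1)
    if gparent[l][v] < 0:
        # root: multiplier on the root stem above the older child
        c0 = gchild0[l][v]
        c1 = gchild1[l][v]
        lo = gage[l][c0] if gage[l][c0] > gage[l][c1] else gage[l][c1]
        x = gage[l][v] - lo
        m = math.exp(0.5 * (np.random.random() - 0.5))
        new_age = lo + x * m
        log_hast = math.log(m)
    else:
        c0 = gchild0[l][v]
        c1 = gchild1[l][v]
        lo = gage[l][c0] if gage[l][c0] > gage[l][c1] else gage[l][c1]
        hi = gage[l][gparent[l][v]]
        if hi <= lo:
            return False, cur_ll, cur_msc
        new_age = lo + (hi - lo) * np.random.random()
        log_hast = 0.0
    old_age = gage[l][v]
    gage[l][v] = new_age
    new_msc = msc_logdensity(gparent[l], gchild0[l], gchild1[l], gage[l], tip_sp,
                             sparent, schild0, schild1, sage, stheta)
    if new_msc == NEG_INF:
        gage[l][v] = old_age
        return False, cur_ll, cur_msc
    if likelihood_on:
        new_ll = gene_loglik_path(v, gparent[l], gchild0[l], gchild1[l], gage[l],
                                  tipdata[l], weights[l], condL[l], logsc[l])
    else:
        new_ll = 0.0
    dlog = (new_ll - cur_ll) + (new_msc - cur_msc) + log_hast
    if math.log(np.random.random() + 1e-320) < dlog:
        return True, new_ll, new_msc
    gage[l][v] = old_age
    if likelihood_on:
        gene_loglik_path(v, gparent[l], gchild0[l], gchild1[l], gage[l],
                         tipdata[l], weights[l], condL[l], logsc[l])
    return False, cur_ll, cur_msc


@njit(cache=True)
def _gene_exchange(l, wide, gparent, gchild0, gchild1, gage, tipdata, weights,
                   condL, logsc, tip_sp, sparent, schild0, schild1, sage, stheta,
                   cur_ll, cur_msc, likelihood_on):
    """Narrow (NNI) or wide exchange of two gene-tree subtrees."""
    N = gparent[l].shape[0]
    n = (N + 1) // 2
    if wide:
        a = np.random.randint(N)
        b = np.random.randint(N)
        if a == b or gparent[l][a] < 0 or gparent[l][b] < 0:
            return False, cur_ll, cur_msc
        # reject if one is an ancestor of the other
        x = gparent[l][a]
        while x >= 0:
            if x == b:
                return False, cur_ll, cur_msc
            x = gparent[l][x]
        x = gparent[l][b]
        while x >= 0:
            if x == a:
                return False, cur_ll, cur_msc
            x = gparent[l][x]
        pa = gparent[l][a]
        pb = gparent[l][b]
        if gage[l][pa] <= gage[l][b] or gage[l][pb] <= gage[l][a]:
            return False, cur_ll, cur_msc
    else:
        # narrow exchange with node-age redraw: swap a child of v with v's
        # sibling and draw a fresh age for v within its new bracket, which
        # keeps the move feasible regardless of the current age ordering
        v = n + np.random.randint(n - 1)
        if gparent[l][v] < 0:
            return False, cur_ll, cur_msc
        u = gparent[l][v]
        s = gchild1[l][u] if gchild0[l][u] == v else gchild0[l][u]
        c = gchild0[l][v] if np.random.random() < 0.5 else gchild1[l][v]
        oth = gchild1[l][v] if gchild0[l][v] == c else gchild0[l][v]
        hi = gage[l][u]
        lo_new = gage[l][oth] if gage[l][oth] > gage[l][s] else gage[l][s]
        if lo_new >= hi:
            return False, cur_ll, cur_msc
        lo_old = gage[l][oth] if gage[l][oth] > gage[l][c] else gage[l][c]
        old_age_v = gage[l][v]
        # swap
        if gchild0[l][v] == c:
            gchild0[l][v] = s
        else:
            gchild1[l][v] = s
        if gchild0[l][u] == s:
            gchild0[l][u] = c
        else:
            gchild1[l][u] = c
        gparent[l][c] = u
        gparent[l][s] = v
        gage[l][v] = lo_new + (hi - lo_new) * np.random.random()
        log_hast = math.log((hi - lo_new) / (hi - lo_old))
        new_msc = msc_logdensity(gparent[l], gchild0[l], gchild1[l], gage[l],
                                 tip_sp, sparent, schild0, schild1, sage, stheta)
        accept = False
        new_ll = cur_ll
        if new_msc > NEG_INF:
            if likelihood_on:
                new_ll = gene_loglik_path2(v, u, gparent[l], gchild0[l],
                                           gchild1[l], gage[l], tipdata[l],
                                           weights[l], condL[l], logsc[l])
            else:
                new_ll = 0.0
            if new_ll > NEG_INF:
                dlog = (new_ll - cur_ll) + (new_msc - cur_msc) + log_hast
                accept = math.log(np.random.random() + 1e-320) < dlog
        if accept:
            return True, new_ll, new_msc
        # undo
        if gchild0[l][v] == s:
            gchild0[l][v] = c
        else:
            gchild1[l][v] = c
        if gchild0[l][u] == c:
            gchild0[l][u] = s
        else:
            gchild1[l][u] = s
        gparent[l][c] = v
        gparent[l][s] = u
        gage[l][v] = old_age_v
        if likelihood_on:
            gene_loglik_path2(v, u, gparent[l], gchild0[l], gchild1[l], gage[l],
                              tipdata[l], weights[l], condL[l], logsc[l])
        return False, cur_ll, cur_msc
    # swap: a (child of pa) <-> b (child of pb)
    if gchild0[l][pa] == a:
        gchild0[l][pa] = b
    else:
        gchild1[l][pa] = b
    if gchild0[l][pb] == b:
        gchild0[l][pb] = a
    else:
        gchild1[l][pb] = a
    gparent[l][a] = pb
    gparent[l][b] = pa

    new_msc = msc_logdensity(gparent[l], gchild0[l], gchild1[l], gage[l], tip_sp,
                             sparent, schild0, schild1, sage, stheta)
    accept = False
    new_ll = cur_ll
    if new_msc > NEG_INF:
        if likelihood_on:
            new_ll = gene_loglik_path2(pa, pb, gparent[l], gchild0[l], gchild1[l],
                                       gage[l], tipdata[l], weights[l],
                                       condL[l], logsc[l])
        else:
            new_ll = 0.0
        dlog = (new_ll - cur_ll) + (new_msc - cur_msc)
        accept = math.log(np.random.random() + 1e-320) < dlog
    if accept:
        return True, new_ll, new_msc
    # undo
    if gchild0[l][pa] == b:
        gchild0[l][pa] = a
    else:
        gchild1[l][pa] = a
    if gchild0[l][pb] == a:
        gchild0[l][pb] = b
    else:
        gchild1[l][pb] = b
    gparent[l][a] = pa
    gparent[l][b] = pb
    if likelihood_on:
        gene_loglik_path2(pa, pb, gparent[l], gchild0[l], gchild1[l], gage[l],
                          tipdata[l], weights[l], condL[l], logsc[l])
    return False, cur_ll, cur_msc


@njit(cache=True)
def _all_msc(gparent, gchild0, gchild1, gage, tip_sp,
             sparent, schild0, schild1, sage, stheta, out):
    L = len(gparent)
    tot = 0.0
    for l in range(L):
        d = msc_logdensity(gparent[l], gchild0[l], gchild1[l], gage[l], tip_sp,
                           sparent, schild0, schild1, sage, stheta)
        out[l] = d
        if d == NEG_INF:
            return NEG_INF
        tot += d
    return tot


# ======================================================================
# species-tree MCMC (the Bayesian guide-tree arm)


@njit(cache=True)
def _yule_logdensity(sparent, sage, lam):
    """Yule prior density of the species-tree node ages, log scale.

    The Yule process conditioned on the number of extant tips (the
    reconstructed pure-birth process with complete sampling): node heights
    behave as sorted iid Exponential(lambda) draws assigned to a uniformly
    chosen labeled history, giving log f = (n-1) log lambda
    - lambda * sum(internal node heights) up to a topology-independent
    constant.
    """
    M = sparent.shape[0]
    ns = (M + 1) // 2
    H = 0.0
    for v in range(ns, M):  # internal nodes occupy indices ns..M-1
        H += sage[v]
    return (ns - 1) * math.log(lam) - lam * H


@njit(cache=True)
def _yule_exposure(sparent, sage):
    """Sum of internal node heights (the lambda-Gibbs rate term)."""
    M = sparent.shape[0]
    ns = (M + 1) // 2
    H = 0.0
    for v in range(ns, M):
        H += sage[v]
    return H


@njit(cache=True)
def run_sptree_mcmc(seed, n_iter, thin,
                    tipdata, weights, tip_sp,
                    sparent, schild0, schild1, sage, stheta,
                    gparent, gchild0, gchild1, gage,
                    lam0, likelihood_on, lambda_fixed,
                    theta_min, theta_max):
    """MCMC over (species tree, tau, theta, lambda, gene trees).

    The target is the posterior under the conditioned Yule prior with
    f(lambda) = 1/lambda and the hierarchical population-size prior of the
    multispecies-coalescent species-tree tools: theta_v | psi ~
    Gamma(2, 2/psi) per branch with the improper f(psi) = 1/psi on the mean
    (both lambda and 1/psi admit Gibbs draws).  theta stays truncated to
    [theta_min, theta_max] as a numerical guard.  One iteration is one
    elementary proposal.  Returns sampled species-tree child arrays and ages
    plus acceptance counters per move family.
    """
    np.random.seed(seed)
    L = tipdata.shape[0]
    M = sparent.shape[0]
    ns = (M + 1) // 2
    NG = gparent.shape[1]
    n_gene = (NG + 1) // 2
    lam = lam0
    psi = 0.0
    for v in range(M):
        psi += stheta[v] / M

    cur_ll = np.zeros(L, np.float64)
    cur_msc = np.zeros(L, np.float64)
    condL = np.zeros((L, gparent.shape[1], tipdata.shape[2], 4), np.float64)
    logsc = np.zeros((L, gparent.shape[1], tipdata.shape[2]), np.float64)
    for l in range(L):
        if likelihood_on:
            cur_ll[l] = gene_loglik_full(gparent[l], gchild0[l], gchild1[l], gage[l],
                                         tipdata[l], weights[l], condL[l], logsc[l])
        cur_msc[l] = msc_logdensity(gparent[l], gchild0[l], gchild1[l], gage[l],
                                    tip_sp, sparent, schild0, schild1, sage, stheta)

    n_samples = n_iter // thin
    samp_c0 = np.zeros((n_samples, M), np.int64)
    samp_c1 = np.zeros((n_samples, M), np.int64)
    samp_age = np.zeros((n_samples, M), np.float64)
    acc = np.zeros(16, np.int64)
    trials = np.zeros(16, np.int64)
    scratch_msc = np.zeros(L, np.float64)

    isamp = 0
    for it in range(n_iter):
        u = np.random.random()
        if u < 0.45:
            # gene node age slide
            kind = 0
            l = np.random.randint(L)
            ok, nll, nmsc = _gene_age_slide(l, gparent, gchild0, gchild1, gage,
                                            tipdata, weights, condL, logsc, tip_sp,
                                            sparent, schild0, schild1, sage, stheta,
                                            cur_ll[l], cur_msc[l], likelihood_on)
            if ok:
                cur_ll[l] = nll
                cur_msc[l] = nmsc
                acc[kind] += 1
            trials[kind] += 1
        elif u < 0.62:
            # gene narrow exchange
            kind = 1
            l = np.random.randint(L)
            ok, nll, nmsc = _gene_exchange(l, False, gparent, gchild0, gchild1, gage,
                                           tipdata, weights, condL, logsc, tip_sp,
                                           sparent, schild0, schild1, sage, stheta,
                                           cur_ll[l], cur_msc[l], likelihood_on)
            if ok:
                cur_ll[l] = nll
                cur_msc[l] = nmsc
                acc[kind] += 1
            trials[kind] += 1
        elif u < 0.72:
            # gene wide exchange
            kind = 2
            l = np.random.randint(L)
            ok, nll, nmsc = _gene_exchange(l, True, gparent, gchild0, gchild1, gage,
                                           tipdata, weights, condL, logsc, tip_sp,
                                           sparent, schild0, schild1, sage, stheta,
                                           cur_ll[l], cur_msc[l], likelihood_on)
            if ok:
                cur_ll[l] = nll
                cur_msc[l] = nmsc
                acc[kind] += 1
            trials[kind] += 1
        elif u < 0.84:
            # species node age move (slide for non-root, stem multiplier for root)
            kind = 3
            trials[kind] += 1
            v = ns + np.random.randint(ns - 1)
            c0 = schild0[v]
            c1 = schild1[v]
            lo = sage[c0] if sage[c0] > sage[c1] else sage[c1]
            old = sage[v]
            feasible = True
            log_hast = 0.0
            new = old
            if sparent[v] < 0:
                x = old - lo
                m = math.exp(0.7 * (np.random.random() - 0.5))
                new = lo + x * m
                log_hast = math.log(m)
            else:
                hi = sage[sparent[v]]
                if hi <= lo:
                    feasible = False
                else:
                    new = lo + (hi - lo) * np.random.random()
            if feasible:
                old_y = _yule_logdensity(sparent, sage, lam)
                sage[v] = new
                new_y = _yule_logdensity(sparent, sage, lam)
                tot = _all_msc(gparent, gchild0, gchild1, gage, tip_sp,
                               sparent, schild0, schild1, sage, stheta, scratch_msc)
                accepted = False
                if tot > NEG_INF:
                    dlog = (tot - cur_msc.sum()) + (new_y - old_y) + log_hast
                    if math.log(np.random.random() + 1e-320) < dlog:
                        for l in range(L):
                            cur_msc[l] = scratch_msc[l]
                        acc[kind] += 1
                        accepted = True
                if not accepted:
                    sage[v] = old
        elif u < 0.91:
            # theta update under theta | psi ~ Gamma(2, 2/psi): either a
            # local multiplier (prior ratio enters the acceptance) or an
            # independence draw from the conditional prior (prior and
            # proposal cancel).  The independence draw keeps likelihood-flat
            # thetas (branches hosting no coalescences) from parking at an
            # extreme and vetoing topology moves through that branch.
            kind = 4
            v = np.random.randint(M)
            old = stheta[v]
            if np.random.random() < 0.5:
                m = math.exp(0.8 * (np.random.random() - 0.5))
                new = old * m
                dprior = (math.log(new / old) - (2.0 / psi) * (new - old)
                          + math.log(m))
            else:
                new = np.random.gamma(2.0, 0.5 * psi)
                dprior = 0.0
            trials[kind] += 1
            if theta_min <= new <= theta_max:
                stheta[v] = new
                tot = _all_msc(gparent, gchild0, gchild1, gage, tip_sp,
                               sparent, schild0, schild1, sage, stheta, scratch_msc)
                if tot > NEG_INF and math.log(np.random.random() + 1e-320) < \
                        (tot - cur_msc.sum()) + dprior:
                    for l in range(L):
                        cur_msc[l] = scratch_msc[l]
                    acc[kind] += 1
                else:
                    stheta[v] = old
        elif u < 0.97:
            # species-tree NNI with node-age redraw
            kind = 5
            trials[kind] += 1
            v = ns + np.random.randint(ns - 1)
            feasible = sparent[v] >= 0
            if feasible:
                uu = sparent[v]
                s = schild1[uu] if schild0[uu] == v else schild0[uu]
                c = schild0[v] if np.random.random() < 0.5 else schild1[v]
                oth = schild1[v] if schild0[v] == c else schild0[v]
                lo_new = sage[oth] if sage[oth] > sage[s] else sage[s]
                hi = sage[uu]
                if lo_new >= hi:
                    feasible = False
            if feasible:
                lo_old = sage[oth] if sage[oth] > sage[c] else sage[c]
                old_age_v = sage[v]
                old_y = _yule_logdensity(sparent, sage, lam)
                # reverse-proposal age window, bounded by the youngest gene
                # coalescence joining the current daughter sides of v
                pmask = _pop_masks(schild0, schild1, sparent)
                hi_r = _cross_bound(v, schild0, schild1, pmask,
                                    gparent, gchild0, gchild1, gage, tip_sp)
                if hi > hi_r:
                    hi_r_eff = hi_r
                else:
                    hi_r_eff = hi
                # swap c <-> s
                if schild0[v] == c:
                    schild0[v] = s
                else:
                    schild1[v] = s
                if schild0[uu] == s:
                    schild0[uu] = c
                else:
                    schild1[uu] = c
                sparent[s] = v
                sparent[c] = uu
                pmask = _pop_masks(schild0, schild1, sparent)
                hi_f = _cross_bound(v, schild0, schild1, pmask,
                                    gparent, gchild0, gchild1, gage, tip_sp)
                if hi < hi_f:
                    hi_f = hi
                accepted = False
                if hi_f > lo_new:
                    sage[v] = lo_new + (hi_f - lo_new) * np.random.random()
                    new_y = _yule_logdensity(sparent, sage, lam)
                    tot = _all_msc(gparent, gchild0, gchild1, gage, tip_sp,
                                   sparent, schild0, schild1, sage, stheta,
                                   scratch_msc)
                    if tot > NEG_INF:
                        log_hast = math.log((hi_f - lo_new) / (hi_r_eff - lo_old))
                        dlog = (tot - cur_msc.sum()) + (new_y - old_y) + log_hast
                        if math.log(np.random.random() + 1e-320) < dlog:
                            for l in range(L):
                                cur_msc[l] = scratch_msc[l]
                            acc[kind] += 1
                            accepted = True
                if not accepted:
                    # undo
                    if schild0[v] == s:
                        schild0[v] = c
                    else:
                        schild1[v] = c
                    if schild0[uu] == c:
                        schild0[uu] = s
                    else:
                        schild1[uu] = s
                    sparent[c] = v
                    sparent[s] = uu
                    sage[v] = old_age_v
        elif u < 0.99:
            # whole-state scale ("mixing") move: all ages and thetas together.
            # Without it the joint scale of (tau, gene ages, theta) only
            # diffuses through many small coupled steps.
            kind = 7
            trials[kind] += 1
            m = math.exp(0.6 * (np.random.random() - 0.5))
            d = L * (n_gene - 1) + (ns - 1) + M
            ok_scale = True
            for v in range(M):
                if (stheta[v] * m < theta_min) or (stheta[v] * m > theta_max):
                    ok_scale = False
            if ok_scale:
                old_y = _yule_logdensity(sparent, sage, lam)
                for l in range(L):
                    for v in range(n_gene, NG):
                        gage[l][v] *= m
                for v in range(ns, M):
                    sage[v] *= m
                for v in range(M):
                    stheta[v] *= m
                psi *= m  # theta prior is scale-equivariant given psi; the
                # psi dimension's Jacobian cancels its 1/psi prior ratio
                new_y = _yule_logdensity(sparent, sage, lam)
                tot = _all_msc(gparent, gchild0, gchild1, gage, tip_sp,
                               sparent, schild0, schild1, sage, stheta, scratch_msc)
                new_ll_tot = 0.0
                ll_new = np.zeros(L, np.float64)
                if tot > NEG_INF and likelihood_on:
                    for l in range(L):
                        ll_new[l] = gene_loglik_full(gparent[l], gchild0[l],
                                                     gchild1[l], gage[l],
                                                     tipdata[l], weights[l],
                                                     condL[l], logsc[l])
                        new_ll_tot += ll_new[l]
                accepted = False
                if tot > NEG_INF:
                    # theta prior 1/theta: ratio = m^-M, cancelling the M theta
                    # dimensions in the Jacobian term m^d
                    dlog = ((new_ll_tot - cur_ll.sum()) + (tot - cur_msc.sum())
                            + (new_y - old_y) + (d - M) * math.log(m))
                    if math.log(np.random.random() + 1e-320) < dlog:
                        for l in range(L):
                            cur_msc[l] = scratch_msc[l]
                            if likelihood_on:
                                cur_ll[l] = ll_new[l]
                        acc[kind] += 1
                        accepted = True
                if not accepted:
                    inv = 1.0 / m
                    for l in range(L):
                        for v in range(n_gene, NG):
                            gage[l][v] *= inv
                    for v in range(ns, M):
                        sage[v] *= inv
                    for v in range(M):
                        stheta[v] *= inv
                    psi *= inv
                    if likelihood_on:
                        for l in range(L):
                            gene_loglik_full(gparent[l], gchild0[l], gchild1[l],
                                             gage[l], tipdata[l], weights[l],
                                             condL[l], logsc[l])
        else:
            # Gibbs draws for the two hyperparameters: lambda (gamma
            # conditional under f(lambda) = 1/lambda) and the population-size
            # mean psi (1/psi is gamma-conditional under f(psi) = 1/psi with
            # the Gamma(2, 2/psi) branch sizes)
            kind = 6
            trials[kind] += 1
            if not lambda_fixed:
                B = _yule_exposure(sparent, sage)
                lam = np.random.gamma(ns - 1.0, 1.0 / B)
                acc[kind] += 1
            th_sum = 0.0
            for v in range(M):
                th_sum += stheta[v]
            psi = 1.0 / np.random.gamma(2.0 * M, 1.0 / (2.0 * th_sum))

        if (it + 1) % thin == 0 and isamp < n_samples:
            for v in range(M):
                samp_c0[isamp, v] = schild0[v]
                samp_c1[isamp, v] = schild1[v]
                samp_age[isamp, v] = sage[v]
            isamp += 1
    return samp_c0, samp_c1, samp_age, acc, trials


# ======================================================================
# rjMCMC species delimitation on a fixed guide tree


@njit(cache=True)
def _log_age_prior(sparent, schild0, schild1, sage, split,
                   tau0_shape, tau0_rate):
    """Log prior of the split-node ages.

    tau0 (the root age, present when the root is split) has a gamma prior;
    the non-root split ages given tau0 are uniform on the order-constrained
    region, i.e. density prod(s_v) / tau0^K where s_v is the number of split
    nodes in the split-poset subtree of v (the linear-extension count of the
    constraint forest).
    """
    M = sparent.shape[0]
    root = _find_root(sparent)
    if not split[root]:
        return 0.0
    tau0 = sage[root]
    lp = (tau0_shape * math.log(tau0_rate) - math.lgamma(tau0_shape)
          + (tau0_shape - 1.0) * math.log(tau0) - tau0_rate * tau0)
    order = np.empty((M + 1) // 2, np.int64)
    k = _postorder(schild0, schild1, root, order)
    sizes = np.zeros(M, np.int64)
    K = 0
    for i in range(k):
        v = order[i]
        if not split[v]:
            continue
        sz = 1
        c0 = schild0[v]
        c1 = schild1[v]
        if c0 >= 0 and split[c0]:
            sz += sizes[c0]
        if c1 >= 0 and split[c1]:
            sz += sizes[c1]
        sizes[v] = sz
        if v != root:
            K += 1
            lp += math.log(sz)
    lp -= K * math.log(tau0)
    return lp


@njit(cache=True)
def _log_theta_prior(sparent, stheta, split, theta_shape, theta_rate):
    M = sparent.shape[0]
    root = _find_root(sparent)
    lp = 0.0
    for v in range(M):
        if v == root or split[sparent[v]]:
            th = stheta[v]
            lp += (theta_shape * math.log(theta_rate) - math.lgamma(theta_shape)
                   + (theta_shape - 1.0) * math.log(th) - theta_rate * th)
    return lp


@njit(cache=True)
def _pop_masks(schild0, schild1, sparent):
    """Bitmask of guide-tree tip populations below each guide node."""
    M = sparent.shape[0]
    ns = (M + 1) // 2
    mask = np.zeros(M, np.int64)
    for v in range(ns):
        mask[v] = 1 << v
    root = _find_root(sparent)
    order = np.empty((M + 1) // 2, np.int64)
    k = _postorder(schild0, schild1, root, order)
    for i in range(k):
        v = order[i]
        mask[v] = mask[schild0[v]] | mask[schild1[v]]
    return mask


@njit(cache=True)
def _cross_bound(v, schild0, schild1, pmask,
                 gparent, gchild0, gchild1, gage, tip_sp):
    """Smallest gene coalescent age joining the two daughter sides of ``v``.

    This is the hard upper bound for a proposed tau_v: any younger age would
    postdate an observed cross-coalescence and have zero density.
    """
    L = len(gparent)
    maskA = pmask[schild0[v]]
    maskB = pmask[schild1[v]]
    best = 1e308
    for l in range(L):
        N = gparent[l].shape[0]
        n = (N + 1) // 2
        tmask = np.zeros(N, np.int64)
        for i in range(n):
            tmask[i] = 1 << tip_sp[i]
        order = np.empty(N, np.int64)
        root = _find_root(gparent[l])
        k = _postorder(gchild0[l], gchild1[l], root, order)
        for i in range(k):
            w = order[i]
            tmask[w] = tmask[gchild0[l][w]] | tmask[gchild1[l][w]]
        for i in range(k):
            w = order[i]
            mL = tmask[gchild0[l][w]]
            mR = tmask[gchild1[l][w]]
            cross = ((mL & maskA) != 0 and (mR & maskB) != 0) or \
                    ((mL & maskB) != 0 and (mR & maskA) != 0)
            if cross:
                if gage[l][w] < best:
                    best = gage[l][w]
    return best


@njit(cache=True)
def _count_split_candidates(sparent, schild0, split, out):
    """Collapsed internal nodes whose parent is split (or the root)."""
    M = sparent.shape[0]
    root = _find_root(sparent)
    k = 0
    for v in range(M):
        if schild0[v] < 0 or split[v]:
            continue
        if v == root or split[sparent[v]]:
            out[k] = v
            k += 1
    return k


@njit(cache=True)
def _count_merge_candidates(sparent, schild0, schild1, split, out):
    """Split nodes whose children are both unsplit (leaves of the split set)."""
    M = sparent.shape[0]
    k = 0
    for v in range(M):
        if schild0[v] < 0 or not split[v]:
            continue
        c0 = schild0[v]
        c1 = schild1[v]
        ok0 = schild0[c0] < 0 or not split[c0]
        ok1 = schild0[c1] < 0 or not split[c1]
        if ok0 and ok1:
            out[k] = v
            k += 1
    return k


@njit(cache=True)
def run_rjmcmc(seed, n_burn, n_iter, thin,
               tipdata, weights, tip_sp,
               sparent, schild0, schild1, sage, stheta, split,
               gparent, gchild0, gchild1, gage,
               tau0_shape, tau0_rate, theta_shape, theta_rate,
               likelihood_on, eps_mix0, autotune):
    """Reversible-jump MCMC over species-delimitation models on a guide tree.

    One iteration is a sweep: age slides over every gene-tree node, a handful
    of topology exchanges per locus, tau/theta updates, one whole-state scale
    ("mixing") move, and two split/merge jump attempts.  Samples the split
    indicators, tau and theta every ``thin`` sweeps after ``n_burn`` sweeps of
    burn-in (during which the mixing step size can auto-tune).
    """
    np.random.seed(seed)
    L = tipdata.shape[0]
    M = sparent.shape[0]
    ns = (M + 1) // 2
    root = _find_root(sparent)

    cur_ll = np.zeros(L, np.float64)
    cur_msc = np.zeros(L, np.float64)
    condL = np.zeros((L, gparent.shape[1], tipdata.shape[2], 4), np.float64)
    logsc = np.zeros((L, gparent.shape[1], tipdata.shape[2]), np.float64)
    for l in range(L):
        if likelihood_on:
            cur_ll[l] = gene_loglik_full(gparent[l], gchild0[l], gchild1[l], gage[l],
                                         tipdata[l], weights[l], condL[l], logsc[l])
        cur_msc[l] = msc_logdensity(gparent[l], gchild0[l], gchild1[l], gage[l],
                                    tip_sp, sparent, schild0, schild1, sage, stheta)

    pmask = _pop_masks(schild0, schild1, sparent)
    cand = np.empty(M, np.int64)
    scratch_msc = np.zeros(L, np.float64)
    n_int = ns - 1
    N = gparent.shape[1]
    n = (N + 1) // 2

    n_samples = n_iter // thin
    samp_split = np.zeros((n_samples, M), np.uint8)
    samp_tau = np.zeros((n_samples, M), np.float64)
    samp_theta = np.zeros((n_samples, M), np.float64)
    acc = np.zeros(8, np.int64)
    trials = np.zeros(8, np.int64)
    eps_mix = eps_mix0
    mix_acc = 0
    mix_try = 0

    isamp = 0
    total_sweeps = n_burn + n_iter
    for sweep in range(total_sweeps):
        # ---- gene-tree updates
        for l in range(L):
            for _ in range(n - 1):
                ok, nll, nmsc = _gene_age_slide(l, gparent, gchild0, gchild1, gage,
                                                tipdata, weights, condL, logsc, tip_sp,
                                                sparent, schild0, schild1, sage, stheta,
                                                cur_ll[l], cur_msc[l], likelihood_on)
                if ok:
                    cur_ll[l] = nll
                    cur_msc[l] = nmsc
                    acc[0] += 1
                trials[0] += 1
            for _ in range(4):
                wide = np.random.random() < 0.4
                ok, nll, nmsc = _gene_exchange(l, wide, gparent, gchild0, gchild1, gage,
                                               tipdata, weights, condL, logsc, tip_sp,
                                               sparent, schild0, schild1, sage, stheta,
                                               cur_ll[l], cur_msc[l], likelihood_on)
                if ok:
                    cur_ll[l] = nll
                    cur_msc[l] = nmsc
                    acc[1] += 1
                trials[1] += 1

        # ---- tau updates
        for v in range(ns, M):
            if not split[v]:
                continue
            trials[2] += 1
            old = sage[v]
            if v == root:
                if np.random.random() < 0.5:
                    m = math.exp(0.6 * (np.random.random() - 0.5))
                    new = old * m
                    log_hast = math.log(m)
                else:
                    # independence draw from the gamma prior; the prior's
                    # gamma factor cancels the proposal density
                    new = np.random.gamma(tau0_shape, 1.0 / tau0_rate)
                    log_hast = (tau0_shape - 1.0) * math.log(old / new) \
                        - tau0_rate * (old - new)
                c0 = schild0[v]
                c1 = schild1[v]
                lo = sage[c0] if sage[c0] > sage[c1] else sage[c1]
                if new <= lo:
                    continue
                dprior = -_log_age_prior(sparent, schild0, schild1, sage, split,
                                         tau0_shape, tau0_rate)
                sage[v] = new
                dprior += _log_age_prior(sparent, schild0, schild1, sage, split,
                                         tau0_shape, tau0_rate)
            else:
                c0 = schild0[v]
                c1 = schild1[v]
                lo0 = sage[c0] if split[c0] or schild0[c0] < 0 else 0.0
                lo1 = sage[c1] if split[c1] or schild0[c1] < 0 else 0.0
                lo = lo0 if lo0 > lo1 else lo1
                hi = sage[sparent[v]]
                if hi <= lo:
                    continue
                sage[v] = lo + (hi - lo) * np.random.random()
                dprior = 0.0
                log_hast = 0.0
            tot = _all_msc(gparent, gchild0, gchild1, gage, tip_sp,
                           sparent, schild0, schild1, sage, stheta, scratch_msc)
            if tot > NEG_INF and math.log(np.random.random() + 1e-320) < \
                    (tot - cur_msc.sum()) + dprior + log_hast:
                for l in range(L):
                    cur_msc[l] = scratch_msc[l]
                acc[2] += 1
            else:
                sage[v] = old

        # ---- theta multiplier updates (a random half of the active lineages
        # per sweep; each theta is still visited every couple of sweeps)
        for v in range(M):
            if not (v == root or split[sparent[v]]):
                continue
            if np.random.random() < 0.5:
                continue
            trials[3] += 1
            old = stheta[v]
            if np.random.random() < 0.5:
                # multiplier: gamma prior ratio + Hastings
                m = math.exp(0.8 * (np.random.random() - 0.5))
                new = old * m
                dlog = ((theta_shape - 1.0) * math.log(new / old)
                        - theta_rate * (new - old) + math.log(m))
            else:
                # independence draw from the gamma prior: the prior and the
                # proposal density cancel, leaving the MSC change alone
                new = np.random.gamma(theta_shape, 1.0 / theta_rate)
                dlog = 0.0
            stheta[v] = new
            tot = _all_msc(gparent, gchild0, gchild1, gage, tip_sp,
                           sparent, schild0, schild1, sage, stheta, scratch_msc)
            if tot > NEG_INF and math.log(np.random.random() + 1e-320) < \
                    (tot - cur_msc.sum()) + dlog:
                for l in range(L):
                    cur_msc[l] = scratch_msc[l]
                acc[3] += 1
            else:
                stheta[v] = old

        # ---- whole-state mixing (scale) move
        trials[4] += 1
        mix_try += 1
        m = math.exp(eps_mix * (np.random.random() - 0.5))
        d = 0
        for l in range(L):
            d += n - 1
        for v in range(ns, M):
            if split[v]:
                d += 1
        for v in range(M):
            if v == root or split[sparent[v]]:
                d += 1
        old_prior = (_log_age_prior(sparent, schild0, schild1, sage, split,
                                    tau0_shape, tau0_rate)
                     + _log_theta_prior(sparent, stheta, split,
                                        theta_shape, theta_rate))
        for l in range(L):
            for v in range(n, N):
                gage[l][v] *= m
        for v in range(ns, M):
            if split[v]:
                sage[v] *= m
        for v in range(M):
            if v == root or split[sparent[v]]:
                stheta[v] *= m
        new_prior = (_log_age_prior(sparent, schild0, schild1, sage, split,
                                    tau0_shape, tau0_rate)
                     + _log_theta_prior(sparent, stheta, split,
                                        theta_shape, theta_rate))
        tot = _all_msc(gparent, gchild0, gchild1, gage, tip_sp,
                       sparent, schild0, schild1, sage, stheta, scratch_msc)
        new_ll_tot = 0.0
        old_ll_tot = cur_ll.sum()
        ll_new = np.zeros(L, np.float64)
        if tot > NEG_INF and likelihood_on:
            for l in range(L):
                ll_new[l] = gene_loglik_full(gparent[l], gchild0[l], gchild1[l],
                                             gage[l], tipdata[l], weights[l],
                                             condL[l], logsc[l])
                new_ll_tot += ll_new[l]
        ok = False
        if tot > NEG_INF:
            dlog = ((new_ll_tot - old_ll_tot) + (tot - cur_msc.sum())
                    + (new_prior - old_prior) + d * math.log(m))
            ok = math.log(np.random.random() + 1e-320) < dlog
        if ok:
            for l in range(L):
                cur_msc[l] = scratch_msc[l]
                cur_ll[l] = ll_new[l]
            acc[4] += 1
            mix_acc += 1
        else:
            inv = 1.0 / m
            for l in range(L):
                for v in range(n, N):
                    gage[l][v] *= inv
            for v in range(ns, M):
                if split[v]:
                    sage[v] *= inv
            for v in range(M):
                if v == root or split[sparent[v]]:
                    stheta[v] *= inv
            if likelihood_on:
                for l in range(L):
                    gene_loglik_full(gparent[l], gchild0[l], gchild1[l], gage[l],
                                     tipdata[l], weights[l], condL[l], logsc[l])
        if autotune and sweep < n_burn and mix_try >= 50:
            rate = mix_acc / mix_try
            if rate > 0.6:
                eps_mix = min(eps_mix * 1.4, 5.0)
            elif rate < 0.15:
                eps_mix = max(eps_mix / 1.4, 0.01)
            mix_acc = 0
            mix_try = 0

        # ---- reversible-jump split/merge attempts
        for _ in range(2):
            trials[5] += 1
            go_split = np.random.random() < 0.5
            if go_split:
                ncand = _count_split_candidates(sparent, schild0, split, cand)
                if ncand == 0:
                    continue
                v = cand[np.random.randint(ncand)]
                U = _cross_bound(v, schild0, schild1, pmask,
                                 gparent, gchild0, gchild1, gage, tip_sp)
                if v != root and sage[sparent[v]] < U:
                    U = sage[sparent[v]]
                if U <= 0.0:
                    continue
                old_prior = _log_age_prior(sparent, schild0, schild1, sage, split,
                                           tau0_shape, tau0_rate)
                tau_new = U * np.random.random()
                th0 = np.random.gamma(theta_shape, 1.0 / theta_rate)
                th1 = np.random.gamma(theta_shape, 1.0 / theta_rate)
                c0 = schild0[v]
                c1 = schild1[v]
                old_th0 = stheta[c0]
                old_th1 = stheta[c1]
                split[v] = True
                sage[v] = tau_new
                stheta[c0] = th0
                stheta[c1] = th1
                new_prior = _log_age_prior(sparent, schild0, schild1, sage, split,
                                           tau0_shape, tau0_rate)
                nmerge = _count_merge_candidates(sparent, schild0, schild1, split, cand)
                tot = _all_msc(gparent, gchild0, gchild1, gage, tip_sp,
                               sparent, schild0, schild1, sage, stheta, scratch_msc)
                ok = False
                if tot > NEG_INF:
                    dlog = ((tot - cur_msc.sum()) + (new_prior - old_prior)
                            + math.log(U) + math.log(ncand) - math.log(nmerge))
                    ok = math.log(np.random.random() + 1e-320) < dlog
                if ok:
                    for l in range(L):
                        cur_msc[l] = scratch_msc[l]
                    acc[5] += 1
                else:
                    split[v] = False
                    sage[v] = 0.0
                    stheta[c0] = old_th0
                    stheta[c1] = old_th1
            else:
                nmerge = _count_merge_candidates(sparent, schild0, schild1, split, cand)
                if nmerge == 0:
                    continue
                v = cand[np.random.randint(nmerge)]
                old_prior = _log_age_prior(sparent, schild0, schild1, sage, split,
                                           tau0_shape, tau0_rate)
                c0 = schild0[v]
                c1 = schild1[v]
                old_tau = sage[v]
                old_th0 = stheta[c0]
                old_th1 = stheta[c1]
                split[v] = False
                sage[v] = 0.0
                new_prior = _log_age_prior(sparent, schild0, schild1, sage, split,
                                           tau0_shape, tau0_rate)
                U = _cross_bound(v, schild0, schild1, pmask,
                                 gparent, gchild0, gchild1, gage, tip_sp)
                if v != root and sage[sparent[v]] < U:
                    U = sage[sparent[v]]
                nsplitc = _count_split_candidates(sparent, schild0, split, cand)
                tot = _all_msc(gparent, gchild0, gchild1, gage, tip_sp,
                               sparent, schild0, schild1, sage, stheta, scratch_msc)
                ok = False
                if tot > NEG_INF and U > 0.0:
                    dlog = ((tot - cur_msc.sum()) + (new_prior - old_prior)
                            - math.log(U) + math.log(nmerge) - math.log(nsplitc))
                    ok = math.log(np.random.random() + 1e-320) < dlog
                if ok:
                    for l in range(L):
                        cur_msc[l] = scratch_msc[l]
                    acc[5] += 1
                else:
                    split[v] = True
                    sage[v] = old_tau
                    stheta[c0] = old_th0
                    stheta[c1] = old_th1

        # ---- sampling
        if sweep >= n_burn and (sweep - n_burn + 1) % thin == 0 and isamp < n_samples:
            for v in range(M):
                samp_split[isamp, v] = 1 if split[v] else 0
                samp_tau[isamp, v] = sage[v]
                samp_theta[isamp, v] = stheta[v]
            isamp += 1
    return samp_split, samp_tau, samp_theta, acc, trials, eps_mix
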