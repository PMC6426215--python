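"""Numba kernels for the computationally heavy learners.

Two samplers live here:

* a BayesB Gibbs sampler (point mass at zero + t-slab via the standard
  normal / scaled-inverse-chi-square augmentation);
* CART regression-tree growth for the random forest, using per-feature
  presorted orders that are stably partitioned down the tree.

Both seed numba's internal RNG explicitly, so a fixed seed gives a
bit-identical chain / forest.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# BayesB


@njit(cache=True)
def bayesb_gibbs(X, y, pi, nu, s2, n_iter, burnin, thin, seed,
                 nu_e, S_e):
    """Gibbs sampler for y = mu + X beta + e with BayesB prior on beta.

    beta_j = delta_j * b_j with P(delta_j = 0) = pi, b_j | sig2_j ~
    N(0, sig2_j), sig2_j ~ nu * s2 / chi2_nu (scaled-inv-chi2), and
    sigma_e^2 ~ nu_e * S_e / chi2_nu_e.  X should be standardized and y
    centered by the caller.

    Returns (mu_mean, beta_mean, pip, sigma_e2_chain).
    """
    np.random.seed(seed)
    n, p = X.shape
    x2 = np.empty(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += X[i, j] * X[i, j]
        x2[j] = acc

    beta = np.zeros(p)
    sig2 = np.full(p, nu * s2 / max(nu - 2.0, 0.5))
    vy = np.var(y) + 1e-12
    sigma_e2 = 0.5 * vy
    mu = 0.0
    e = y.copy()

    include_all = pi <= 0.0
    exclude_all = pi >= 1.0
    log_prior_odds = 0.0
    if not include_all and not exclude_all:
        log_prior_odds = np.log(1.0 - pi) - np.log(pi)

    n_keep = (n_iter - burnin + thin - 1) // thin
    mu_sum = 0.0
    beta_sum = np.zeros(p)
    pip_sum = np.zeros(p)
    sig_e_chain = np.empty(n_iter)
    kept = 0

    for it in range(n_iter):
        # intercept
        mean_mu = mu + np.sum(e) / n
        mu_new = np.random.normal(mean_mu, np.sqrt(sigma_e2 / n))
        shift = mu_new - mu
        for i in range(n):
            e[i] -= shift
        mu = mu_new

        for j in range(p):
            if x2[j] <= 0.0:
                beta[j] = 0.0
                continue
            bj = beta[j]
            rj = 0.0
            for i in range(n):
                rj += X[i, j] * e[i]
            rj += x2[j] * bj
            c = x2[j] + sigma_e2 / sig2[j]
            if exclude_all:
                new_b = 0.0
            else:
                if include_all:
                    take = True
                else:
                    log_bf = 0.5 * (np.log(sigma_e2 / (sig2[j] * c))
                                    + rj * rj / (sigma_e2 * c))
                    z = log_prior_odds + log_bf
                    if z > 35.0:
                        take = True
                    elif z < -35.0:
                        take = False
                    else:
                        p1 = 1.0 / (1.0 + np.exp(-z))
                        take = np.random.random() < p1
                if take:
                    new_b = np.random.normal(rj / c, np.sqrt(sigma_e2 / c))
                else:
                    new_b = 0.0
            if new_b != bj:
                diff = bj - new_b
                for i in range(n):
                    e[i] += X[i, j] * diff
                beta[j] = new_b
            # marker variance: posterior when in, prior when out
            if beta[j] != 0.0:
                sig2[j] = (nu * s2 + beta[j] * beta[j]) / \
                    np.random.chisquare(nu + 1.0)
            else:
                sig2[j] = nu * s2 / np.random.chisquare(nu)

        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma_e2 = (sse + nu_e * S_e) / np.random.chisquare(n + nu_e)
        sig_e_chain[it] = sigma_e2

        if it >= burnin and (it - burnin) % thin == 0:
            kept += 1
            mu_sum += mu
            for j in range(p):
                beta_sum[j] += beta[j]
                if beta[j] != 0.0:
                    pip_sum[j] += 1.0

    if kept == 0:
        kept = 1
    return mu_sum / kept, beta_sum / kept, pip_sum / kept, sig_e_chain


# ---------------------------------------------------------------------------
# random forest


@njit(cache=True)
def _grow_tree(X, boot, yb, samples, mtry, min_node, feat_out, thr_out,
               left_out, right_out, value_out, feat_perm, stack, vals, order,
               tmp):
    """Grow one unpruned CART regression tree in place.

    ``samples`` holds bootstrap slots; a node owns the segment
    [start, end).  Candidate features are sorted node-locally (the node
    subsets are small), and the winning split partitions the segment.
    Returns the number of nodes.
    """
    n = boot.shape[0]
    p = X.shape[1]
    n_nodes = 1
    stack[0, 0] = 0
    stack[0, 1] = n
    stack[0, 2] = 0  # node id
    top = 1
    while top > 0:
        top -= 1
        start = stack[top, 0]
        end = stack[top, 1]
        node = stack[top, 2]
        nn = end - start
        ysum = 0.0
        ysq = 0.0
        for k in range(start, end):
            v = yb[samples[k]]
            ysum += v
            ysq += v * v
        value_out[node] = ysum / nn
        feat_out[node] = -1
        sse = ysq - ysum * ysum / nn
        if nn <= min_node or sse <= 1e-12 * nn:
            continue

        best_gain = 0.0
        best_f = -1
        best_thr = 0.0
        for m in range(mtry):
            j = m + np.random.randint(p - m)
            f = feat_perm[j]
            feat_perm[j] = feat_perm[m]
            feat_perm[m] = f
            for k in range(nn):
                vals[k] = X[boot[samples[start + k]], f]
            ord_loc = order[:nn]
            ord_loc[:] = np.argsort(vals[:nn], kind="mergesort")
            sl = 0.0
            prev_val = vals[ord_loc[0]]
            for k in range(nn - 1):
                sl += yb[samples[start + ord_loc[k]]]
                cur_val = vals[ord_loc[k + 1]]
                if cur_val > prev_val:
                    nl = k + 1
                    nr = nn - nl
                    gain = (sl * sl / nl
                            + (ysum - sl) * (ysum - sl) / nr
                            - ysum * ysum / nn)
                    if gain > best_gain + 1e-12:
                        best_gain = gain
                        best_f = f
                        best_thr = 0.5 * (prev_val + cur_val)
                    prev_val = cur_val
        if best_f < 0:
            continue

        # partition the segment on the winning split
        a = 0
        b = 0
        for k in range(start, end):
            s = samples[k]
            if X[boot[s], best_f] <= best_thr:
                samples[start + a] = s
                a += 1
            else:
                tmp[b] = s
                b += 1
        for k in range(b):
            samples[start + a + k] = tmp[k]

        left_id = n_nodes
        right_id = n_nodes + 1
        n_nodes += 2
        feat_out[node] = best_f
        thr_out[node] = best_thr
        left_out[node] = left_id
        right_out[node] = right_id
        stack[top, 0] = start
        stack[top, 1] = start + a
        stack[top, 2] = left_id
        top += 1
        stack[top, 0] = start + a
        stack[top, 1] = end
        stack[top, 2] = right_id
        top += 1
    return n_nodes


@njit(cache=True)
def grow_forest(X, y, ntree, mtry, min_node, seed):
    """Grow a regression forest; returns node arrays plus in-bag counts."""
    np.random.seed(seed)
    n, p = X.shape
    max_nodes = 2 * n + 1
    feat = np.full((ntree, max_nodes), -1, dtype=np.int32)
    thr = np.zeros((ntree, max_nodes))
    left = np.full((ntree, max_nodes), -1, dtype=np.int32)
    right = np.full((ntree, max_nodes), -1, dtype=np.int32)
    value = np.zeros((ntree, max_nodes))
    inbag = np.zeros((ntree, n), dtype=np.int32)

    boot = np.empty(n, dtype=np.int32)
    yb = np.empty(n)
    samples = np.empty(n, dtype=np.int32)
    feat_perm = np.empty(p, dtype=np.int32)
    stack = np.empty((2 * n + 2, 3), dtype=np.int32)
    vals = np.empty(n)
    order = np.empty(n, dtype=np.int64)
    tmp = np.empty(n, dtype=np.int32)

    for t in range(ntree):
        for i in range(n):
            b = np.random.randint(n)
            boot[i] = b
            inbag[t, b] += 1
            yb[i] = y[b]
            samples[i] = i
        for f in range(p):
            feat_perm[f] = f
        _grow_tree(X, boot, yb, samples, mtry, min_node, feat[t], thr[t],
                   left[t], right[t], value[t], feat_perm, stack, vals,
                   order, tmp)
    return feat, thr, left, right, value, inbag


@njit(cache=True)
def forest_predict(X, feat, thr, left, right, value):
    """Ensemble-mean prediction for each row of X."""
    n = X.shape[0]
    ntree = feat.shape[0]
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for t in range(ntree):
            node = 0
            while feat[t, node] >= 0:
                if X[i, feat[t, node]] <= thr[t, node]:
                    node = left[t, node]
                else:
                    node = right[t, node]
            acc += value[t, node]
        out[i] = acc / ntree
    return out


@njit(cache=True)
def forest_oob_predict(X, feat, thr, left, right, value, inbag):
    """Out-of-bag prediction per training row (NaN if never out of bag)."""
    n = X.shape[0]
    ntree = feat.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        acc = 0.0
        cnt = 0
        for t in range(ntree):
            if inbag[t, i] > 0:
                continue
            node = 0
            while feat[t, node] >= 0:
                if X[i, feat[t, node]] <= thr[t, node]:
                    node = left[t, node]
                else:
                    node = right[t, node]
            acc += value[t, node]
            cnt += 1
        if cnt > 0:
            out[i] = acc / cnt
    return out
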