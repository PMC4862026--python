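"""Low-level decision-tree kernels for the missing-value-aware random forest.

Trees are binary CART-style classifiers grown on Gini impurity.  Missing
feature values are never imputed: every internal node stores, in addition
to (feature, threshold), a *missing direction* chosen during training by
evaluating both "missing goes left" and "missing goes right" variants of
each candidate split and keeping the one with the larger impurity decrease
(missingness incorporated in attribute, MIA).  At prediction time an
instance with a missing value at a node simply follows the stored
direction, so an all-missing feature vector still reaches a leaf.

The kernels are numba-compiled; trees are returned as flat parallel
arrays (feature, threshold, missing_left, left, right, leaf) indexed by
node id, with node 0 the root and leaf[i] == -1 marking internal nodes.

Determinism: each tree receives one 32-bit seed that drives both the
bootstrap draw and the per-node feature subsampling; identical inputs and
seed reproduce the tree bit for bit.

Tie-breaking is fixed: among splits of equal gain the lowest feature
index wins, then the lowest threshold, then missing-left over
missing-right; leaves with tied class counts vote the negative class.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: gains below this are treated as zero (no admissible split)
MIN_GAIN = 1e-12


@njit(cache=True)
def _grow_tree(X, y, sample_idx, mtry, max_depth, seed, do_bootstrap):
    """Grow one tree; returns flat node arrays plus the in-bag count vector.

    X : (n_total, p) float64 with NaN for missing
    y : (n_total,) int64 in {0, 1}
    sample_idx : row indices of X forming the training set of this tree
                 (before bootstrap)
    """
    np.random.seed(seed)
    n = sample_idx.shape[0]
    p = X.shape[1]

    inbag = np.zeros(n, np.int64)  # per training position, times drawn
    idx = np.empty(n, np.int64)    # rows of X owned by the tree, partitioned in place
    if do_bootstrap:
        for i in range(n):
            j = np.random.randint(0, n)
            inbag[j] += 1
            idx[i] = sample_idx[j]
    else:
        for i in range(n):
            inbag[i] = 1
            idx[i] = sample_idx[i]

    max_nodes = 2 * n + 1
    feat = np.full(max_nodes, -1, np.int64)
    thr = np.zeros(max_nodes, np.float64)
    miss_left = np.zeros(max_nodes, np.uint8)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    leaf = np.full(max_nodes, -1, np.int64)

    stack_node = np.empty(max_nodes, np.int64)
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)
    stack_depth = np.empty(max_nodes, np.int64)
    top = 0
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n
    stack_depth[0] = 0
    n_nodes = 1

    feat_pool = np.arange(p)
    vals = np.empty(n, np.float64)
    labs = np.empty(n, np.int64)

    while top >= 0:
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        depth = stack_depth[top]
        top -= 1

        m = hi - lo
        npos = 0
        for i in range(lo, hi):
            npos += y[idx[i]]

        if npos == 0 or npos == m or depth >= max_depth:
            # majority vote; exact tie -> negative class
            leaf[node] = 1 if 2 * npos > m else 0
            continue

        fp = npos / m
        parent_imp = 1.0 - fp * fp - (1.0 - fp) * (1.0 - fp)

        # sample mtry distinct features (partial Fisher-Yates), then visit
        # them in ascending index order so ties resolve to the lowest index
        for j in range(mtry):
            k = j + np.random.randint(0, p - j)
            tmp = feat_pool[j]
            feat_pool[j] = feat_pool[k]
            feat_pool[k] = tmp
        cand = np.sort(feat_pool[:mtry].copy())

        best_gain = MIN_GAIN
        best_f = -1
        best_t = 0.0
        best_ml = 1

        for ci in range(mtry):
            f = cand[ci]
            nobs = 0
            mtot = 0
            mpos = 0
            for i in range(lo, hi):
                v = X[idx[i], f]
                if np.isnan(v):
                    mtot += 1
                    mpos += y[idx[i]]
                else:
                    vals[nobs] = v
                    labs[nobs] = y[idx[i]]
                    nobs += 1
            if nobs < 2:
                continue
            order = np.argsort(vals[:nobs], kind="mergesort")

            cpos = 0
            for b in range(nobs - 1):
                cpos += labs[order[b]]
                vlo = vals[order[b]]
                vhi = vals[order[b + 1]]
                if vhi <= vlo:
                    continue
                t = 0.5 * (vlo + vhi)
                if t <= vlo or t >= vhi:
                    # adjacent floats: midpoint collapses onto a value
                    t = vlo
                nl_obs = b + 1
                lp_obs = cpos
                # evaluate missing->left first so an exact tie keeps left
                for mdir in range(2):
                    if mdir == 0:
                        nl = nl_obs + mtot
                        lp = lp_obs + mpos
                    else:
                        if mtot == 0:
                            break  # identical to mdir 0
                        nl = nl_obs
                        lp = lp_obs
                    nr = m - nl
                    rp = npos - lp
                    if nl == 0 or nr == 0:
                        continue
                    plf = lp / nl
                    prf = rp / nr
                    child_imp = (
                        nl * (1.0 - plf * plf - (1.0 - plf) * (1.0 - plf))
                        + nr * (1.0 - prf * prf - (1.0 - prf) * (1.0 - prf))
                    ) / m
                    gain = parent_imp - child_imp
                    if gain > best_gain:
                        best_gain = gain
                        best_f = f
                        best_t = t
                        best_ml = 1 - mdir

        if best_f < 0:
            leaf[node] = 1 if 2 * npos > m else 0
            continue

        # stable in-place partition of idx[lo:hi]
        buf = np.empty(m, np.int64)
        nl = 0
        nr = 0
        for i in range(lo, hi):
            v = X[idx[i], best_f]
            if np.isnan(v):
                go_left = best_ml == 1
            else:
                go_left = v <= best_t
            if go_left:
                buf[nl] = idx[i]
                nl += 1
            else:
                buf[m - 1 - nr] = idx[i]
                nr += 1
        for i in range(nl):
            idx[lo + i] = buf[i]
        for i in range(nr):
            idx[lo + nl + i] = buf[m - 1 - i]

        if nl == 0 or nr == 0:
            leaf[node] = 1 if 2 * npos > m else 0
            continue

        lc = n_nodes
        rc = n_nodes + 1
        n_nodes += 2
        feat[node] = best_f
        thr[node] = best_t
        miss_left[node] = best_ml
        left[node] = lc
        right[node] = rc

        top += 1
        stack_node[top] = lc
        stack_lo[top] = lo
        stack_hi[top] = lo + nl
        stack_depth[top] = depth + 1
        top += 1
        stack_node[top] = rc
        stack_lo[top] = lo + nl
        stack_hi[top] = hi
        stack_depth[top] = depth + 1

    return (
        feat[:n_nodes],
        thr[:n_nodes],
        miss_left[:n_nodes],
        left[:n_nodes],
        right[:n_nodes],
        leaf[:n_nodes],
        inbag,
    )


@njit(cache=True)
def _predict_tree(feat, thr, miss_left, left, right, leaf, X, out):
    """Route every row of X to a leaf; writes the leaf class into out."""
    for i in range(X.shape[0]):
        node = 0
        while leaf[node] == -1:
            v = X[i, feat[node]]
            if np.isnan(v):
                node = left[node] if miss_left[node] == 1 else right[node]
            elif v <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = leaf[node]
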