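"""Compiled kernels: CART forest growth, prediction, and OOB permutation VIMP.

The forest lives in flat node arrays (feature, threshold, children, leaf
value, per-tree offsets), which keeps the hot loops free of Python objects:
a shadowVIMP analysis fits hundreds of thousands of small forests.

Tree growth is exact best-split CART on the in-bag rows only, with bootstrap
multiplicity entering as integer sample weights: split criteria, leaf values
and node sizes are all multiplicity-weighted, i.e. genuine
bootstrap-with-replacement semantics.  At every node exactly ``mtry``
candidate columns are drawn without replacement; a node becomes a leaf when
its weighted size falls below the minimum split size, it is pure, or no
candidate admits a valid split.  Thresholds are midpoints between adjacent
distinct values.

All randomness (per-node column draws, per-tree VIMP permutations) is seeded
per tree, so results are reproducible and independent of execution order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["grow_forest", "predict_forest", "per_tree_vimp_kernel"]

NO_FEATURE = -2  # leaf marker in the feature array


@njit(cache=True)
def _argsort_insertion(vals, order, nv):
    """Insertion-sort argsort into the preallocated ``order`` buffer.

    Node sizes here are tens of samples, where insertion sort beats
    allocating general-purpose sorts."""
    for a in range(nv):
        order[a] = a
    for a in range(1, nv):
        idx = order[a]
        v = vals[idx]
        b = a - 1
        while b >= 0 and vals[order[b]] > v:
            order[b + 1] = order[b]
            b -= 1
        order[b + 1] = idx


@njit(cache=True)
def grow_forest(X, y, counts, seeds, mtry, min_split_weight, classification):
    """Grow q weighted CART trees; returns flat node arrays + offsets.

    X : (n, p) float32; y : (n,) float64 (class codes 0/1 for
    classification); counts : (q, n) bootstrap multiplicities;
    seeds : (q,) per-tree RNG seeds.

    Returns (feature, threshold, left, right, value, node_off) where value
    is (total_nodes, 1) weighted means for regression or (total_nodes, 2)
    weighted class counts for classification, and children indices are
    global (already offset into the concatenated node table).
    """
    q, n = counts.shape
    p = X.shape[1]
    per_tree_cap = 2 * n + 1
    cap = q * per_tree_cap
    C = 2 if classification else 1

    feature = np.full(cap, NO_FEATURE, dtype=np.int64)
    threshold = np.zeros(cap)
    left = np.full(cap, -1, dtype=np.int64)
    right = np.full(cap, -1, dtype=np.int64)
    value = np.zeros((cap, C))
    node_off = np.zeros(q + 1, dtype=np.int64)

    samples = np.empty(n, dtype=np.int64)
    buf = np.empty(n, dtype=np.int64)
    features = np.empty(p, dtype=np.int64)
    vals = np.empty(n)
    order = np.empty(n, dtype=np.int64)
    stack_node = np.empty(per_tree_cap, dtype=np.int64)
    stack_start = np.empty(per_tree_cap, dtype=np.int64)
    stack_end = np.empty(per_tree_cap, dtype=np.int64)

    for l in range(q):
        np.random.seed(seeds[l])
        base = node_off[l]
        ns = 0
        for i in range(n):
            if counts[l, i] > 0:
                samples[ns] = i
                ns += 1
        for f in range(p):
            features[f] = f

        next_local = 1
        top = 0
        stack_node[0] = 0
        stack_start[0] = 0
        stack_end[0] = ns

        while top >= 0:
            node = base + stack_node[top]
            start = stack_start[top]
            end = stack_end[top]
            top -= 1
            nv = end - start

            # weighted node statistics
            W = 0.0
            S = 0.0
            SS = 0.0
            c1 = 0.0
            for a in range(start, end):
                i = samples[a]
                wi = counts[l, i]
                yi = y[i]
                W += wi
                S += wi * yi
                if classification:
                    c1 += wi * yi  # yi is the 0/1 class code
                else:
                    SS += wi * yi * yi
            if classification:
                value[node, 0] = W - c1
                value[node, 1] = c1
                pure = c1 == 0.0 or c1 == W
            else:
                value[node, 0] = S / W
                pure = SS - S * S / W <= 1e-12 * W
            if nv < 2 or W < min_split_weight or pure:
                continue

            # exactly mtry candidate columns, drawn without replacement
            best_proxy = -np.inf
            best_f = -1
            best_thr = 0.0
            for t in range(mtry):
                r = t + np.random.randint(0, p - t)
                tmp = features[t]
                features[t] = features[r]
                features[r] = tmp
                f = features[t]
                for a in range(nv):
                    vals[a] = X[samples[start + a], f]
                _argsort_insertion(vals, order, nv)
                if vals[order[nv - 1]] <= vals[order[0]]:
                    continue  # constant within the node
                wL = 0.0
                SL = 0.0
                c1L = 0.0
                for a in range(nv - 1):
                    i = samples[start + order[a]]
                    wi = counts[l, i]
                    wL += wi
                    if classification:
                        c1L += wi * y[i]
                    else:
                        SL += wi * y[i]
                    va = vals[order[a]]
                    vb = vals[order[a + 1]]
                    if vb <= va:
                        continue
                    wR = W - wL
                    if classification:
                        c0L = wL - c1L
                        c0R = (W - c1) - c0L
                        c1R = c1 - c1L
                        proxy = (c0L * c0L + c1L * c1L) / wL + (c0R * c0R + c1R * c1R) / wR
                    else:
                        SR = S - SL
                        proxy = SL * SL / wL + SR * SR / wR
                    if proxy > best_proxy:
                        best_proxy = proxy
                        best_f = f
                        best_thr = 0.5 * (va + vb)
            if best_f < 0:
                continue  # no candidate admitted a valid split

            # stable partition of the node's samples by the chosen split
            nl = 0
            nr = 0
            for a in range(start, end):
                i = samples[a]
                if X[i, best_f] <= best_thr:
                    samples[start + nl] = i
                    nl += 1
                else:
                    buf[nr] = i
                    nr += 1
            for a in range(nr):
                samples[start + nl + a] = buf[a]

            feature[node] = best_f
            threshold[node] = best_thr
            lid = next_local
            rid = next_local + 1
            next_local += 2
            left[node] = base + lid
            right[node] = base + rid
            top += 1
            stack_node[top] = rid
            stack_start[top] = start + nl
            stack_end[top] = end
            top += 1
            stack_node[top] = lid
            stack_start[top] = start
            stack_end[top] = start + nl

        node_off[l + 1] = base + next_local

    total = node_off[q]
    return (
        feature[:total],
        threshold[:total],
        left[:total],
        right[:total],
        value[:total],
        node_off,
    )


@njit(cache=True)
def _leaf(feat, thresh, left, right, base, Xo, row, override_col, override_val):
    node = base
    while feat[node] >= 0:
        f = feat[node]
        v = override_val[row] if f == override_col else Xo[row, f]
        node = left[node] if v <= thresh[node] else right[node]
    return node


@njit(cache=True)
def predict_forest(X, feat, thresh, left, right, value, node_off, classification):
    """Forest prediction: per-tree means averaged (regression) or majority
    of per-tree majority votes (classification, returns vote fractions)."""
    q = node_off.shape[0] - 1
    nr = X.shape[0]
    out = np.zeros(nr)
    no_override = np.empty(1, dtype=np.float32)
    for l in range(q):
        base = node_off[l]
        for r in range(nr):
            node = _leaf(feat, thresh, left, right, base, X, r, -1, no_override)
            if classification:
                out[r] += 1.0 if value[node, 1] > value[node, 0] else 0.0
            else:
                out[r] += value[node, 0]
    return out / q


@njit(cache=True)
def per_tree_vimp_kernel(
    X, y, oob_flat, oob_off, feat, thresh, left, right, value, node_off,
    seeds, classification,
):
    """(q, p) per-tree permutation importances plus validity flags.

    For every tree: baseline OOB error, then for each column the tree
    splits on, the OOB error after a fresh Fisher-Yates permutation of that
    column within the OOB set (seeded per tree).  Unused columns score 0
    exactly; rows whose root-to-leaf path never reads the permuted column
    keep their baseline contribution.  Trees with an empty OOB set are
    flagged invalid; a single-element OOB set admits only the identity
    permutation and scores 0.
    """
    q = node_off.shape[0] - 1
    n, p = X.shape
    C = value.shape[1]
    per_tree = np.zeros((q, p))
    valid = np.ones(q, dtype=np.bool_)
    used_mark = np.zeros(p, dtype=np.bool_)
    no_override = np.empty(1, dtype=np.float32)
    used = np.empty(p, dtype=np.int64)
    Xo = np.empty((n, p), dtype=np.float32)
    yo = np.empty(n)
    row_err = np.empty(n)
    perm = np.empty(n, dtype=np.int64)
    shuffled = np.empty(n, dtype=np.float32)

    for l in range(q):
        m = oob_off[l + 1] - oob_off[l]
        if m == 0:
            valid[l] = False
            continue
        base = node_off[l]
        n_used = 0
        for node in range(base, node_off[l + 1]):
            f = feat[node]
            if f >= 0 and not used_mark[f]:
                used_mark[f] = True
                used[n_used] = f
                n_used += 1
        for a in range(n_used):
            used_mark[used[a]] = False
        if n_used == 0 or m == 1:
            continue

        for r in range(m):
            i = oob_flat[oob_off[l] + r]
            for c in range(p):
                Xo[r, c] = X[i, c]
            yo[r] = y[i]

        # baseline error and per-row contributions
        base_err = 0.0
        for r in range(m):
            node = _leaf(feat, thresh, left, right, base, Xo, r, -1, no_override)
            if classification:
                best = 0
                for c in range(1, C):
                    if value[node, c] > value[node, best]:
                        best = c
                row_err[r] = 1.0 if best != int(yo[r]) else 0.0
            else:
                d = value[node, 0] - yo[r]
                row_err[r] = d * d
            base_err += row_err[r]
        base_err /= m

        np.random.seed(seeds[l])
        for a in range(n_used):
            u = used[a]
            for r in range(m):
                perm[r] = r
            for r in range(m - 1, 0, -1):
                s = np.random.randint(0, r + 1)
                tmp = perm[r]
                perm[r] = perm[s]
                perm[s] = tmp
            for r in range(m):
                shuffled[r] = Xo[perm[r], u]
            err = 0.0
            for r in range(m):
                node = _leaf(feat, thresh, left, right, base, Xo, r, u, shuffled)
                if classification:
                    best = 0
                    for c in range(1, C):
                        if value[node, c] > value[node, best]:
                            best = c
                    if best != int(yo[r]):
                        err += 1.0
                else:
                    d = value[node, 0] - yo[r]
                    err += d * d
            per_tree[l, u] = err / m - base_err
    return per_tree, valid
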