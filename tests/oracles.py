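"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive (exhaustive enumeration, recursive
simulation, dense matrix algebra) and shares no code with the package's
algorithmic paths.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import scipy.linalg


def mk_transition_expm(rates, model, t, k=3):
    """Generic matrix-exponential transition matrix (scipy expm)."""
    Q = np.zeros((k, k))
    rates = np.asarray(rates, float)
    if model == "ER":
        Q[:] = rates[0]
    else:
        iu = np.triu_indices(k, 1)
        Q[iu] = rates
        Q.T[iu] = rates
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return scipy.linalg.expm(Q * t)


def _edges_and_nodes(tree):
    """(parent_index, child_index, length) triples plus tip/internal ids."""
    nodes = list(tree.d.preorder_node_iter())
    index = {nd: i for i, nd in enumerate(nodes)}
    edges = [
        (index[nd.parent_node], index[nd], nd.edge.length or 0.0)
        for nd in nodes
        if nd.parent_node is not None
    ]
    tips = {
        index[nd]: (nd.taxon.label if nd.taxon else nd.label)
        for nd in nodes
        if nd.is_leaf()
    }
    internals = [i for i, nd in enumerate(nodes) if not nd.is_leaf()]
    labels = {
        index[nd]: (
            nd.taxon.label if nd.is_leaf() else nd.label
        )
        for nd in nodes
    }
    return edges, tips, internals, labels


def mk_lik_enumeration(tree, char, model, rates, states):
    """Likelihood by exhaustive sum over all internal-node state assignments."""
    k = len(states)
    sidx = {s: j for j, s in enumerate(states)}
    edges, tips, internals, _ = _edges_and_nodes(tree)
    P = {e: mk_transition_expm(rates, model, e[2], k) for e in edges}
    total = 0.0
    for assign in product(range(k), repeat=len(internals)):
        state = {i: s for i, s in zip(internals, assign)}
        for i, lbl in tips.items():
            state[i] = sidx[char[lbl]]
        prob = 1.0 / k  # uniform root prior; node 0 is the root in preorder
        for e in edges:
            pi, ci, _ = e
            prob *= P[e][state[pi], state[ci]]
        total += prob
    return total


def mk_marginals_enumeration(tree, char, model, rates, states):
    """P(node = s | tips) for every internal node, by joint enumeration."""
    k = len(states)
    sidx = {s: j for j, s in enumerate(states)}
    edges, tips, internals, labels = _edges_and_nodes(tree)
    P = {e: mk_transition_expm(rates, model, e[2], k) for e in edges}
    post = {labels[i]: np.zeros(k) for i in internals}
    for assign in product(range(k), repeat=len(internals)):
        state = {i: s for i, s in zip(internals, assign)}
        for i, lbl in tips.items():
            state[i] = sidx[char[lbl]]
        prob = 1.0 / k
        for e in edges:
            pi, ci, _ = e
            prob *= P[e][state[pi], state[ci]]
        for i in internals:
            post[labels[i]][state[i]] += prob
    return {lbl: v / v.sum() for lbl, v in post.items()}


def bm_tips_recursive(tree, sigma2, rng):
    """Single-trait BM by drawing a normal increment on every branch."""
    vals = {}
    out = {}
    for nd in tree.d.preorder_node_iter():
        if nd.parent_node is None:
            vals[nd] = 0.0
        else:
            t = nd.edge.length or 0.0
            vals[nd] = vals[nd.parent_node] + rng.normal(
                0.0, np.sqrt(sigma2 * t)
            )
        if nd.is_leaf():
            out[nd.taxon.label] = vals[nd]
    return out


def gls_bm_rate(tree, x):
    """BM rate from dense matrix algebra: (x-a1)' C^-1 (x-a1) / (n-1).

    Independent check of the contrast-variance estimator.
    """
    order, C = tree.phylo_covariance()
    v = np.asarray([x[t] for t in order], float)
    Ci = np.linalg.inv(C)
    ones = np.ones(len(order))
    a = (ones @ Ci @ v) / (ones @ Ci @ ones)
    d = v - a
    return float(d @ Ci @ d / (len(order) - 1))


def standard_pca(X):
    """Ordinary covariance PCA of centered data; returns (eigvals, scores)."""
    Xc = X - X.mean(axis=0, keepdims=True)
    S = Xc.T @ Xc / (X.shape[0] - 1)
    w, V = np.linalg.eigh(S)
    idx = np.argsort(w)[::-1]
    return w[idx], Xc @ V[:, idx]


def cr_brute(S, idx1, idx2):
    """Covariance ratio by explicit element-wise sums."""
    num = 0.0
    for i in idx1:
        for j in idx2:
            num += S[i, j] ** 2
    d1 = sum(
        S[i, j] ** 2 for i in idx1 for j in idx1 if i != j
    )
    d2 = sum(
        S[i, j] ** 2 for i in idx2 for j in idx2 if i != j
    )
    return np.sqrt(num / np.sqrt(d1 * d2))


def yule_depth_oracle(n, birth, rng):
    """Depth of the conditioned pure-birth process, simulated directly."""
    depth = 0.0
    for k in range(2, n):
        depth += rng.exponential(1.0 / (k * birth))
    depth += rng.exponential(1.0 / (n * birth))
    return depth
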