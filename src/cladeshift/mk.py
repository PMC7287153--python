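"""Continuous-time Mk models for a discrete habitat character.

Implements the likelihood of K-state Markov models on a rooted tree via
Felsenstein's pruning algorithm, maximum-likelihood fitting of the
equal-rates (ER) and symmetric (SYM) models, likelihood-ratio comparison,
marginal ancestral state reconstruction by re-rooting the tree at each
internal node, and counting of state transitions along the reconstructed
history.

States are identified by an ordered tuple of labels (default
``("CS", "HF", "WA")``: cold steppe, humid forest, warm arid shrubland).
The root prior is uniform, matching the flat prior customary for the
re-rooting reconstruction method; it is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .tree import PhyloTree

__all__ = [
    "DEFAULT_STATES",
    "MkFit",
    "rate_matrix",
    "transition_matrix",
    "mk_loglik",
    "fit_mk",
    "lrt",
    "marginal_ancestral_states",
    "most_probable_states",
    "count_transitions",
]

DEFAULT_STATES: tuple[str, ...] = ("CS", "HF", "WA")

_LOG_Q_LO, _LOG_Q_HI = np.log(1e-8), np.log(1e3)


@dataclass
class MkFit:
    model: str                     # "ER" or "SYM"
    rates: np.ndarray              # ER: (1,), SYM: (K(K-1)/2,)
    log_likelihood: float          # nats
    aic: float                     # 2k - 2 lnL
    converged: bool
    boundary: bool = False         # rate(s) stuck at the lower bound
    n_params: int = 0
    states: tuple[str, ...] = DEFAULT_STATES


def _n_rates(model: str, k: int) -> int:
    if model == "ER":
        return 1
    if model == "SYM":
        return k * (k - 1) // 2
    raise ValueError(f"unknown Mk model {model!r} (expected 'ER' or 'SYM')")


def rate_matrix(rates: Sequence[float], model: str, k: int) -> np.ndarray:
    """Instantaneous generator Q: off-diagonal exchange rates, rows sum to 0."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("Mk rates must be >= 0")
    if rates.size != _n_rates(model, k):
        raise ValueError(
            f"{model} with {k} states needs {_n_rates(model, k)} rate(s), "
            f"got {rates.size}"
        )
    Q = np.zeros((k, k))
    if model == "ER":
        Q[:] = rates[0]
    else:
        iu = np.triu_indices(k, 1)
        Q[iu] = rates
        Q.T[iu] = rates
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_matrix(
    rates: Sequence[float], model: str, t: float, k: int = 3
) -> np.ndarray:
    """P(t) = expm(Q t), computed from the symmetric eigendecomposition of Q.

    For ER the result coincides with the closed form
    ``P_ii = 1/K + (1 - 1/K) e^{-Kqt}``, ``P_ij = 1/K - (1/K) e^{-Kqt}``.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if model == "ER":
        q = float(np.asarray(rates, dtype=float).ravel()[0])
        if q < 0:
            raise ValueError("Mk rates must be >= 0")
        e = np.exp(-k * q * t)
        P = np.full((k, k), (1.0 - e) / k)
        np.fill_diagonal(P, 1.0 / k + (1.0 - 1.0 / k) * e)
        return P
    Q = rate_matrix(rates, model, k)
    # Q is symmetric for ER and SYM, so the spectral route is exact and stable.
    w, U = np.linalg.eigh(Q)
    P = (U * np.exp(w * t)) @ U.T
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _tip_state_vector(
    char: Mapping[str, str], label: str, states: Sequence[str]
) -> np.ndarray:
    if label not in char:
        raise KeyError(f"tip {label!r} has no scored state")
    s = char[label]
    try:
        j = list(states).index(s)
    except ValueError:
        raise ValueError(
            f"state {s!r} of taxon {label!r} not in declared states {tuple(states)}"
        ) from None
    v = np.zeros(len(states))
    v[j] = 1.0
    return v


def _pruning_partials(
    tree: PhyloTree,
    char: Mapping[str, str],
    model: str,
    rates: Sequence[float],
    states: Sequence[str],
) -> tuple[np.ndarray, float]:
    """Conditional likelihoods at the root and the accumulated log-scaler."""
    k = len(states)
    partial: dict = {}
    log_scale = 0.0
    for nd in tree.d.postorder_node_iter():
        if nd.is_leaf():
            lbl = nd.taxon.label if nd.taxon else nd.label
            partial[nd] = _tip_state_vector(char, lbl, states)
            continue
        v = np.ones(k)
        for child in nd.child_nodes():
            P = transition_matrix(rates, model, child.edge.length or 0.0, k)
            v = v * (P @ partial[child])
        m = v.max()
        if m <= 0:
            return np.zeros(k), -np.inf
        v = v / m
        log_scale += np.log(m)
        partial[nd] = v
    return partial[tree.d.seed_node], log_scale


def mk_loglik(
    tree: PhyloTree,
    char: Mapping[str, str],
    model: str,
    rates: Sequence[float],
    states: Sequence[str] = DEFAULT_STATES,
    root_prior: Sequence[float] | None = None,
) -> float:
    """Pruning log-likelihood (nats) with a uniform root prior by default."""
    k = len(states)
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior, float)
    root_partial, log_scale = _pruning_partials(tree, char, model, rates, states)
    lik = float(prior @ root_partial)
    if lik <= 0:
        return -np.inf
    return np.log(lik) + log_scale


def fit_mk(
    tree: PhyloTree,
    char: Mapping[str, str],
    model: str = "ER",
    states: Sequence[str] = DEFAULT_STATES,
    n_starts: int = 10,
    seed: int = 0,
) -> MkFit:
    """Maximize the Mk likelihood over log-parameterized rates.

    Rates are bounded to [1e-8, 1e3] per unit branch length and optimized
    from ``n_starts`` log-uniform multi-starts (seeded, deterministic).
    """
    k = len(states)
    p = _n_rates(model, k)
    observed = {char[t] for t in tree.tip_labels}
    rng = np.random.default_rng(seed)

    def nll(log_rates: np.ndarray) -> float:
        ll = mk_loglik(tree, char, model, np.exp(log_rates), states)
        return -ll if np.isfinite(ll) else 1e12

    starts = [np.full(p, np.log(0.5))]
    starts += [
        rng.uniform(np.log(1e-3), np.log(50.0), size=p) for _ in range(n_starts - 1)
    ]
    best = None
    for x0 in starts:
        res = minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=[(_LOG_Q_LO, _LOG_Q_HI)] * p,
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"Mk {model} fit failed to converge from {n_starts} starts"
        )
    rates = np.exp(best.x)
    lnl = -best.fun
    boundary = bool(np.any(best.x <= _LOG_Q_LO + 1e-6)) or len(observed) < 2
    return MkFit(
        model=model,
        rates=rates,
        log_likelihood=lnl,
        aic=2 * p - 2 * lnl,
        converged=bool(best.success),
        boundary=boundary,
        n_params=p,
        states=tuple(states),
    )


def lrt(fit_restricted: MkFit, fit_general: MkFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested Mk fits: (statistic, df, p).

    The statistic is 2(lnL_general - lnL_restricted); small negative values
    (within 1e-8) from optimizer noise are clipped to zero.
    """
    stat = 2.0 * (fit_general.log_likelihood - fit_restricted.log_likelihood)
    if stat < -1e-8:
        raise ValueError(
            f"general model fits worse than restricted (2dlnL = {stat:.3g}); "
            "optimizer failure"
        )
    stat = max(stat, 0.0)
    df = fit_general.n_params - fit_restricted.n_params
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    if stat == 0.0:
        p = 1.0
    return stat, df, p


def marginal_ancestral_states(
    tree: PhyloTree,
    char: Mapping[str, str],
    model: str,
    rates: Sequence[float],
    states: Sequence[str] = DEFAULT_STATES,
    root_prior: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Marginal state probabilities at every node via the re-rooting method.

    For each internal node the tree is re-rooted there, pruning conditional
    likelihoods are computed, and the node's marginal distribution is the
    normalized product of its subtree partials with the (uniform) prior.
    Rates are held fixed at the supplied (ML) estimates.  Tip rows are the
    observed indicator vectors.  Rows sum to 1.
    """
    k = len(states)
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior, float)
    tree = tree.copy()
    tree.ensure_node_ids()
    rows: dict[str, np.ndarray] = {}

    for nd in tree.d.preorder_node_iter():
        if nd.is_leaf():
            lbl = nd.taxon.label if nd.taxon else nd.label
            rows[lbl] = _tip_state_vector(char, lbl, states)

    for nd in list(tree.d.preorder_internal_node_iter()):
        nid = nd.label
        if nd is tree.d.seed_node:
            work = tree
        else:
            work = tree.copy()
            target = next(
                n for n in work.d.preorder_internal_node_iter() if n.label == nid
            )
            work.d.reroot_at_node(target, update_bipartitions=False)
        partial, _ = _pruning_partials(work, char, model, rates, states)
        post = prior * partial
        tot = post.sum()
        if tot <= 0:
            raise RuntimeError(f"zero marginal likelihood at node {nid!r}")
        rows[nid] = post / tot

    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(states))
    table.index.name = "node"
    return table


def most_probable_states(table: pd.DataFrame) -> pd.Series:
    """Argmax state per node; ties broken by state-column order with a warning."""
    vals = table.to_numpy()
    best = vals.max(axis=1)
    ties = (np.isclose(vals, best[:, None])).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"argmax ties at nodes {list(table.index[ties])}; "
            "broken by state order",
            stacklevel=2,
        )
    return pd.Series(
        [table.columns[j] for j in vals.argmax(axis=1)], index=table.index,
        name="state",
    )


def count_transitions(
    tree: PhyloTree, node_states: Mapping[str, str]
) -> pd.DataFrame:
    """Count parent -> child state changes along every edge.

    ``node_states`` maps node ids (tips by label, internals by their
    ``ensure_node_ids`` label) to their assigned state.  Returns a table
    keyed by (from, to) ordered state pairs.
    """
    tree = tree.copy()
    tree.ensure_node_ids()
    counts: dict[tuple[str, str], int] = {}
    for nd in tree.d.preorder_node_iter():
        if nd.parent_node is None:
            continue
        pid = (
            nd.parent_node.label
            if not nd.parent_node.is_leaf()
            else nd.parent_node.taxon.label
        )
        cid = nd.taxon.label if nd.is_leaf() else nd.label
        a, b = node_states[pid], node_states[cid]
        if a != b:
            counts[(a, b)] = counts.get((a, b), 0) + 1
    out = pd.DataFrame(
        [(a, b, n) for (a, b), n in sorted(counts.items())],
        columns=["from", "to", "count"],
    )
    return out
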