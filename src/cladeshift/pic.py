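"""Phylogenetically independent contrasts and Brownian-motion rate tests.

Traits are log-transformed and z-standardized once, across the full taxon
set, so that per-clade rates remain on one common scale.  The evolutionary
rate of a trait is estimated from the variance of its standardized
contrasts, beta = sum(c_i^2) / (n - 1), and rates are compared between
clades or among traits with variance-ratio F tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .tree import PhyloTree, TreeValidationError

__all__ = [
    "ContrastSet",
    "RateEstimate",
    "preprocess_traits",
    "pic",
    "bm_rate",
    "rate_ratio_test",
    "rates_table",
]


@dataclass
class ContrastSet:
    trait: str
    contrasts: np.ndarray          # n-1 standardized contrasts, postorder
    node_values: dict[str, float]  # internal-node trait estimates
    adjusted_lengths: dict[str, float]
    n_tips: int


@dataclass
class RateEstimate:
    trait: str
    scope: str                     # "all" or a clade name
    beta: float                    # trait-units^2 per unit branch length
    n: int                         # taxa in the scope tree


def preprocess_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """Natural log then per-column z-score (mean 0, sample SD 1).

    Raises on non-positive entries (naming taxon and trait) and on
    zero-variance columns.
    """
    bad = (raw <= 0) | ~np.isfinite(raw)
    if bad.to_numpy().any():
        taxon = raw.index[bad.any(axis=1)][0]
        trait = raw.columns[bad.loc[taxon]][0]
        raise ValueError(
            f"trait {trait!r} of taxon {taxon!r} is not strictly positive; "
            "log transform impossible"
        )
    logged = np.log(raw)
    sd = logged.std(axis=0, ddof=1)
    if (sd < 1e-300).any():
        cols = list(sd.index[sd < 1e-300])
        raise ValueError(f"constant trait column(s) {cols}: zero SD")
    out = (logged - logged.mean(axis=0)) / sd
    out.attrs["scale"] = "log-z"
    return out


def pic(tree: PhyloTree, trait: pd.Series) -> ContrastSet:
    """Felsenstein's independent contrasts for one trait.

    At each internal node with children carrying values (x_i, x_j) and
    working branch lengths (b_i, b_j):

    * contrast        c = (x_i - x_j) / sqrt(b_i + b_j)
    * node value      (x_i/b_i + x_j/b_j) / (1/b_i + 1/b_j)
    * parent branch   lengthened by b_i b_j / (b_i + b_j)

    The tree must be strictly bifurcating (a pruning knuckle at the root is
    tolerated and skipped).
    """
    name = trait.name if trait.name is not None else "trait"
    missing = [t for t in tree.tip_labels if t not in trait.index]
    if missing:
        raise KeyError(f"tips without trait values: {missing}")
    work = tree.copy()
    work.ensure_node_ids()

    values: dict = {}
    blens: dict = {}
    contrasts: list[float] = []
    node_values: dict[str, float] = {}
    adjusted: dict[str, float] = {}

    root = work.d.seed_node
    for nd in work.d.postorder_node_iter():
        if nd.is_leaf():
            values[nd] = float(trait[nd.taxon.label])
            blens[nd] = nd.edge.length or 0.0
            continue
        kids = nd.child_nodes()
        if len(kids) == 1 and nd is root:
            # root knuckle from pruning: pass the single child through
            values[nd] = values[kids[0]]
            blens[nd] = blens[kids[0]]
            continue
        if len(kids) != 2:
            raise TreeValidationError(
                f"node {nd.label!r} has {len(kids)} children; resolve "
                "polytomies before computing contrasts"
            )
        ci, cj = kids
        bi, bj = blens[ci], blens[cj]
        tot = bi + bj
        if tot <= 0:
            raise TreeValidationError(
                f"zero summed branch length below node {nd.label!r}"
            )
        contrasts.append((values[ci] - values[cj]) / np.sqrt(tot))
        values[nd] = (values[ci] / bi + values[cj] / bj) / (1.0 / bi + 1.0 / bj) \
            if bi > 0 and bj > 0 else (
                values[cj] if bi == 0 else values[ci]
            )
        node_values[nd.label] = values[nd]
        extra = (bi * bj / tot) if bi > 0 and bj > 0 else 0.0
        blens[nd] = (nd.edge.length or 0.0) + extra
        adjusted[nd.label] = blens[nd]

    return ContrastSet(
        trait=name,
        contrasts=np.asarray(contrasts),
        node_values=node_values,
        adjusted_lengths=adjusted,
        n_tips=tree.n_tips,
    )


def bm_rate(contrasts: ContrastSet) -> RateEstimate:
    """Brownian-motion rate beta = sum(c_i^2) / (n - 1)."""
    c = contrasts.contrasts
    if c.size < 2:
        raise ValueError("need at least 2 contrasts to estimate a rate")
    beta = float(np.sum(c * c) / (contrasts.n_tips - 1))
    return RateEstimate(
        trait=contrasts.trait, scope="all", beta=beta, n=contrasts.n_tips
    )


def rate_ratio_test(
    a: ContrastSet, b: ContrastSet
) -> tuple[float, tuple[int, int], float]:
    """Two-tailed variance-ratio F test of two contrast sets.

    F = beta_a / beta_b with df (n_a - 1, n_b - 1);
    p = 2 * min(P(F <= f), P(F >= f)), capped at 1.
    """
    ra, rb = bm_rate(a), bm_rate(b)
    if rb.beta == 0:
        raise ZeroDivisionError("denominator rate is zero; F undefined")
    F = ra.beta / rb.beta
    df = (ra.n - 1, rb.n - 1)
    p = 2.0 * min(f_dist.cdf(F, *df), f_dist.sf(F, *df))
    return F, df, min(p, 1.0)


def _letter_groups(
    names: Sequence[str],
    values: Mapping[str, float],
    sig: Mapping[tuple[str, str], bool],
    letters: str,
) -> dict[str, str]:
    """Compact letter display: maximal cliques of the 'not significantly
    different' graph, lettered in order of increasing group value."""
    names = sorted(names, key=lambda k: values[k])
    compatible = {
        frozenset(sub)
        for r in range(1, len(names) + 1)
        for sub in combinations(names, r)
        if not any(sig[(x, y)] for x, y in combinations(sorted(sub), 2))
    }
    maximal = [
        s for s in compatible
        if not any(s < t for t in compatible)
    ]
    maximal.sort(key=lambda s: min(values[x] for x in s))
    out: dict[str, list[str]] = {n: [] for n in names}
    for i, group in enumerate(maximal):
        for n in group:
            out[n].append(letters[i % len(letters)])
    return {n: "".join(sorted(ls)) for n, ls in out.items()}


def rates_table(
    tree: PhyloTree,
    traits: pd.DataFrame,
    clades: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-trait BM rates on the full tree and within each clade.

    Clade columns carry compact letters from pairwise between-clade F tests
    (within a trait row); the full-tree column carries letters from pairwise
    among-trait F tests.  Pairwise tests are uncorrected, at ``alpha``.
    Clades with fewer than 4 taxa are reported as NA.
    """
    subtree: dict[str, PhyloTree | None] = {}
    for cname, taxa in clades.items():
        subtree[cname] = (
            tree.extract_clade(taxa) if len(list(taxa)) >= 4 else None
        )

    all_cs = {tr: pic(tree, traits[tr]) for tr in traits.columns}
    clade_cs: dict[str, dict[str, ContrastSet]] = {}
    for cname, st in subtree.items():
        if st is None:
            continue
        sub_traits = traits.loc[st.tip_labels]
        clade_cs[cname] = {tr: pic(st, sub_traits[tr]) for tr in traits.columns}

    # among-trait letters on the full tree
    beta_all = {tr: bm_rate(all_cs[tr]).beta for tr in traits.columns}
    sig_tr = {}
    for x, y in combinations(sorted(traits.columns), 2):
        _, _, p = rate_ratio_test(all_cs[x], all_cs[y])
        sig_tr[(x, y)] = sig_tr[(y, x)] = p < alpha
    trait_letters = _letter_groups(
        list(traits.columns), beta_all, sig_tr, "abcdefghij"
    )

    rows = []
    for tr in traits.columns:
        row: dict[str, object] = {
            "trait": tr,
            "beta_total": beta_all[tr],
            "letters_total": trait_letters[tr],
        }
        avail = [c for c in clades if c in clade_cs]
        sig_cl = {}
        for x, y in combinations(sorted(avail), 2):
            _, _, p = rate_ratio_test(clade_cs[x][tr], clade_cs[y][tr])
            sig_cl[(x, y)] = sig_cl[(y, x)] = p < alpha
        cl_beta = {c: bm_rate(clade_cs[c][tr]).beta for c in avail}
        cl_letters = (
            _letter_groups(avail, cl_beta, sig_cl, "ABCDEFGHIJ")
            if len(avail) >= 2 else {c: "A" for c in avail}
        )
        for cname in clades:
            if cname in clade_cs:
                row[f"beta_{cname}"] = cl_beta[cname]
                row[f"letters_{cname}"] = cl_letters[cname]
            else:
                row[f"beta_{cname}"] = np.nan
                row[f"letters_{cname}"] = "NA (clade < 4 taxa)"
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")
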