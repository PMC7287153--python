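"""Rooted phylogenies: Newick I/O and the tree surgery done before comparative analyses.

The tree is the substrate of every downstream computation (Mk likelihoods,
independent contrasts, GLS).  This module wraps :mod:`dendropy` trees in a
thin, validated container and adds the preparation steps a comparative study
needs: pruning to the sampled taxa, random resolution of polytomies,
ultrametricization, clade extraction, and the Brownian-motion phylogenetic
covariance matrix.
"""

from __future__ import annotations

import random
import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "NewickError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
]


class NewickError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """A tree violating the container's invariants."""


def _check_balanced(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickError(
                    f"unbalanced ')' at character offset {offset}"
                )
    if depth != 0:
        raise NewickError(
            f"unbalanced '(' (still {depth} open at character offset {len(text)})"
        )
    if not text.rstrip().endswith(";"):
        raise NewickError(
            f"Newick statement must end with ';' (character offset {len(text.rstrip())})"
        )


class PhyloTree:
    """A rooted tree with branch lengths and uniquely labelled tips.

    Branch lengths are in relative-time units.  A length on the root edge is
    permitted (it arises when pruning removes everything on one side of the
    root) and is treated as shared history of all tips.
    """

    def __init__(self, tree: dendropy.Tree, validate: bool = True):
        self._tree = tree
        if validate:
            self.validate()

    # -- internal access for sibling modules -------------------------------
    @property
    def d(self) -> dendropy.Tree:
        """The underlying dendropy tree (read-only by convention)."""
        return self._tree

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        _check_balanced(text)
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises assorted error classes
            if "duplicate" in str(exc).lower():
                raise TreeValidationError(str(exc)) from exc
            raise NewickError(f"could not parse Newick string: {exc}") from exc
        return cls(dt)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        )
        return s.strip()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1), validate=False)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        labels = self.tip_labels
        if len(labels) < 2:
            raise TreeValidationError(
                "trees with fewer than 2 tips are rejected: no comparative "
                "method applies"
            )
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeValidationError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for nd in self._tree.preorder_node_iter():
            if nd is self._tree.seed_node:
                continue
            bl = nd.edge.length
            if bl is None or not np.isfinite(bl) or bl < 0:
                raise TreeValidationError(
                    f"branch above {self._node_id(nd)!r} has invalid length {bl!r}"
                )

    @staticmethod
    def _node_id(nd: dendropy.Node) -> str:
        if nd.taxon is not None:
            return nd.taxon.label
        return nd.label or "<internal>"

    # -- basic queries -----------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in left-to-right preorder (the canonical taxon order)."""
        out = []
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf():
                out.append(nd.taxon.label if nd.taxon else nd.label)
        return out

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def is_bifurcating(self) -> bool:
        for nd in self._tree.preorder_internal_node_iter():
            k = len(nd.child_nodes())
            if nd is self._tree.seed_node and k == 1:
                continue  # root knuckle from pruning is tolerated
            if k != 2:
                return False
        return True

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Distance from the top of the root edge to each node (preorder walk)."""
        depths: dict[dendropy.Node, float] = {}
        for nd in self._tree.preorder_node_iter():
            parent = nd.parent_node
            base = 0.0 if parent is None else depths[parent]
            depths[nd] = base + (nd.edge.length or 0.0)
        return depths

    def tip_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {
            self._node_id(nd): depths[nd]
            for nd in self._tree.leaf_node_iter()
        }

    def total_length(self) -> float:
        tot = 0.0
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length:
                tot += nd.edge.length
        return tot

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        dep = list(self.tip_depths().values())
        span = max(dep) - min(dep)
        return span <= rel_tol * max(max(dep), 1e-300)

    def ensure_node_ids(self) -> None:
        """Label unlabelled internal nodes ``nd0, nd1, ...`` in preorder.

        Stable identifiers let ancestral-state tables refer to nodes across
        tree copies and reroots.
        """
        i = 0
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            if not nd.label:
                while True:
                    cand = f"nd{i}"
                    i += 1
                    if not any(
                        (o.label == cand) for o in self._tree.preorder_internal_node_iter()
                    ):
                        break
                nd.label = cand

    # -- tree surgery ------------------------------------------------------
    def resolve_polytomies(self, epsilon: float = 1e-4, seed: int = 0) -> "PhyloTree":
        """Randomly resolve every multifurcation into bifurcations.

        Each new internal branch receives length ``epsilon``; the grouping
        sequence is randomized by ``seed``.  Root-to-tip distances change by
        at most ``(k - 2) * epsilon`` for a ``k``-way polytomy.
        """
        if epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        rng = random.Random(seed)
        out = self.copy()
        for nd in list(out._tree.preorder_internal_node_iter()):
            children = nd.child_nodes()
            while len(children) > 2:
                i, j = sorted(rng.sample(range(len(children)), 2))
                c2 = children.pop(j)
                c1 = children.pop(i)
                nd.remove_child(c1)
                nd.remove_child(c2)
                merged = dendropy.Node()
                merged.edge.length = epsilon
                merged.add_child(c1)
                merged.add_child(c2)
                nd.add_child(merged)
                children.append(merged)
        out.validate()
        return out

    def force_ultrametric(self, method: str = "extend") -> "PhyloTree":
        """Equalize all root-to-tip path lengths.

        ``extend`` lengthens terminal branches only (internal structure is
        untouched); ``scale_paths`` rescales node heights so every root-to-tip
        path is stretched roughly proportionally.
        """
        out = self.copy()
        depths = out.node_depths()
        leaves = list(out._tree.leaf_node_iter())
        target = max(depths[lf] for lf in leaves)
        if method == "extend":
            for lf in leaves:
                gap = target - depths[lf]
                lf.edge.length = (lf.edge.length or 0.0) + gap
                if lf.edge.length < 0:
                    raise AssertionError("negative terminal branch under extend")
        elif method == "scale_paths":
            # New depth of a node = target * mean over its descendant tips of
            # depth(node)/depth(tip); tips land exactly on `target`, so every
            # root-to-tip path is stretched (approximately) proportionally.
            newdep: dict[dendropy.Node, float] = {}
            for nd in out._tree.preorder_node_iter():
                if any(depths[t] <= 0 for t in nd.leaf_iter()):
                    raise TreeValidationError("zero-depth tip cannot be scaled")
                ratios = [depths[nd] / depths[t] for t in nd.leaf_iter()]
                newdep[nd] = target * float(np.mean(ratios))
            for nd in out._tree.preorder_node_iter():
                if nd.parent_node is None:
                    if nd.edge.length:
                        nd.edge.length = newdep[nd]
                    continue
                bl = newdep[nd] - newdep[nd.parent_node]
                if bl < -1e-12:
                    raise TreeValidationError(
                        "scale_paths produced a negative branch; use method='extend'"
                    )
                nd.edge.length = max(bl, 0.0)
        else:
            raise ValueError(f"unknown ultrametricization method {method!r}")
        out.validate()
        return out

    def prune_to(self, keep: Iterable[str]) -> "PhyloTree":
        """Restrict the tree to ``keep``, preserving root-to-tip distances.

        Degree-2 internal nodes created by the pruning are suppressed with
        their branch lengths summed; shared history removed on one side of
        the root survives as a root edge length.
        """
        keep = set(keep)
        tips = set(self.tip_labels)
        missing = sorted(keep - tips)
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        if len(keep) < 2:
            raise TreeValidationError("cannot prune to fewer than 2 taxa")
        out = self.copy()
        out._tree.retain_taxa_with_labels(sorted(keep))
        out.validate()
        return out

    def extract_clade(self, taxa: Iterable[str]) -> "PhyloTree":
        """Subtree rooted at the MRCA of ``taxa`` (with all its descendants)."""
        taxa = set(taxa)
        tips = set(self.tip_labels)
        missing = sorted(taxa - tips)
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        if len(taxa) < 3:
            raise TreeValidationError("a clade needs at least 3 taxa for rate work")
        work = self.copy()
        mrca = work._tree.mrca(taxon_labels=sorted(taxa))
        if mrca is work._tree.seed_node:
            warnings.warn(
                "requested taxa span the root; returning the whole tree",
                stacklevel=2,
            )
            return work
        parent = mrca.parent_node
        parent.remove_child(mrca)
        mrca.edge.length = None
        sub = dendropy.Tree(
            seed_node=mrca, taxon_namespace=work._tree.taxon_namespace
        )
        sub.is_rooted = True
        return PhyloTree(sub)

    # -- covariance --------------------------------------------------------
    def phylo_covariance(self) -> tuple[list[str], np.ndarray]:
        """Brownian-motion covariance: C[i, j] = depth of MRCA(i, j).

        Returns the taxon order (tree tip preorder) together with the matrix;
        consumers must align data by these names, never by position alone.
        """
        order = self.tip_labels
        idx = {lbl: k for k, lbl in enumerate(order)}
        n = len(order)
        C = np.zeros((n, n))
        root = self._tree.seed_node
        for nd in self._tree.preorder_node_iter():
            bl = nd.edge.length or 0.0
            if nd is root and not nd.edge.length:
                continue
            if bl == 0.0 and nd is not root:
                continue
            below = [
                idx[t.taxon.label if t.taxon else t.label]
                for t in nd.leaf_iter()
            ]
            ix = np.ix_(below, below)
            C[ix] += bl
        return order, C


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick statement."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree; round-trips topology and lengths (>= 10 sig. digits)."""
    return tree.to_newick()
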