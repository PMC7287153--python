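"""Phylogenetic principal components analysis.

Components are extracted from the evolutionary trait covariance matrix,
i.e. the GLS estimate R = (X - 1a)' C^-1 (X - 1a) / (n - 1) where C is the
Brownian-motion phylogenetic covariance and a the GLS phylogenetic mean.
Scores are the centered (unwhitened) data projected onto the eigenvectors,
as in the standard phylogenetic-PCA formulation.  Component signs follow a
deterministic convention: the largest-magnitude loading of each component
is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .tree import PhyloTree

__all__ = [
    "PCAResult",
    "phylo_mean",
    "evolutionary_vcv",
    "phylo_pca",
    "plot_scores",
]


@dataclass
class PCAResult:
    loadings: pd.DataFrame       # trait x component, orthonormal columns
    eigenvalues: np.ndarray      # non-increasing
    proportions: np.ndarray      # eigenvalue_k / sum(eigenvalues)
    scores: pd.DataFrame         # taxon x component
    mean: pd.Series              # GLS phylogenetic mean per trait


def _chol(C: np.ndarray):
    try:
        return cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"phylogenetic covariance is singular: {exc}"
        ) from exc


def phylo_mean(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """GLS ancestral mean a = (1' C^-1 1)^-1 1' C^-1 X (row vector)."""
    X = np.atleast_2d(np.asarray(X, float))
    cf = _chol(C)
    ones = np.ones(X.shape[0])
    Ci1 = cho_solve(cf, ones)
    return (Ci1 @ X) / (ones @ Ci1)


def evolutionary_vcv(X: np.ndarray, C: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Evolutionary covariance R = (X - 1a)' C^-1 (X - 1a) / (n - 1)."""
    X = np.atleast_2d(np.asarray(X, float))
    cf = _chol(C)
    D = X - a[None, :]
    R = D.T @ cho_solve(cf, D) / (X.shape[0] - 1)
    return (R + R.T) / 2.0


def phylo_pca(tree: PhyloTree, X: pd.DataFrame) -> PCAResult:
    """Phylogenetic PCA of a complete taxon x trait table."""
    if X.isna().to_numpy().any():
        raise ValueError("trait table has missing values")
    order = tree.tip_labels
    if X.shape[1] < 2 or len(order) < 3:
        raise ValueError("need >= 3 taxa and >= 2 traits")
    Xv = X.loc[order].to_numpy(float)
    _, C = tree.phylo_covariance()

    a = phylo_mean(Xv, C)
    R = evolutionary_vcv(Xv, C, a)
    eigval, eigvec = np.linalg.eigh(R)
    idx = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[idx], eigvec[:, idx]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] *= -1.0
    comp = [f"PC{j + 1}" for j in range(eigvec.shape[1])]
    scores = (Xv - a[None, :]) @ eigvec
    total = eigval.sum()
    return PCAResult(
        loadings=pd.DataFrame(eigvec, index=X.columns, columns=comp),
        eigenvalues=eigval,
        proportions=eigval / total if total > 0 else eigval * 0.0,
        scores=pd.DataFrame(scores, index=order, columns=comp),
        mean=pd.Series(a, index=X.columns, name="phylo_mean"),
    )


def plot_scores(result: PCAResult, habitat: pd.Series, path: str) -> None:
    """Scatter of PC1/PC2 scores colored by habitat, with loading arrows."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    palette = {"CS": "#3b6fb6", "HF": "#2e8b57", "WA": "#d2691e"}
    fig, ax = plt.subplots(figsize=(6, 5))
    for state in sorted(habitat.unique()):
        sel = habitat.index[habitat == state]
        ax.scatter(
            result.scores.loc[sel, "PC1"],
            result.scores.loc[sel, "PC2"],
            label=state,
            color=palette.get(state, "gray"),
            s=35,
            edgecolor="k",
            linewidth=0.4,
        )
    scale = 0.8 * np.abs(result.scores[["PC1", "PC2"]].to_numpy()).max()
    for trait in result.loadings.index:
        dx, dy = result.loadings.loc[trait, ["PC1", "PC2"]] * scale
        ax.annotate(
            "", xy=(dx, dy), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="0.4", lw=1.0),
        )
        ax.text(dx * 1.08, dy * 1.08, trait, fontsize=8, color="0.25")
    p1, p2 = 100 * result.proportions[0], 100 * result.proportions[1]
    ax.set_xlabel(f"PC1 ({p1:.1f}% of variance)")
    ax.set_ylabel(f"PC2 ({p2:.1f}% of variance)")
    ax.axhline(0, color="0.85", lw=0.8, zorder=0)
    ax.axvline(0, color="0.85", lw=0.8, zorder=0)
    ax.legend(title="habitat", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
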