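"""Synthetic datasets with the statistical structure the analyses assume.

The generator emulates a comparative study of ~34 herbaceous species in
three clades: an ultrametric phylogeny, a 3-state habitat character evolving
under an equal-rates Mk process, seven log-scale traits evolving under
multivariate Brownian motion with a two-block modular covariance structure
and per-trait Pagel's lambda, additive habitat effects shifting the
"slow-strategy" traits in cold-steppe lineages, and habitat-linked climate
covariates.  Everything is seeded and bit-reproducible.

Default conditions (documented in the methods note):

* 34 taxa in clades of 10/12/12, total tree depth 1;
* trait blocks {LMA, LT, LD, RSR} and {PH, LA, AR}, within-block
  correlation 0.6, between-block correlation 0, unit rates;
* lambda = 0 for AR, 1 for all other traits;
* habitat effect: +2 (log-z units) on LMA, LT, LD, RSR for CS taxa;
* Mk rate chosen so the true history has 5-9 state changes (resampled,
  bounded retries).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .mk import DEFAULT_STATES, transition_matrix
from .tree import PhyloTree

__all__ = [
    "TRAIT_NAMES",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_yule",
    "simulate_mk",
    "simulate_traits",
    "default_trait_covariance",
    "make_fixture",
    "write_dataset",
]

TRAIT_NAMES: tuple[str, ...] = ("PH", "LA", "LMA", "LT", "LD", "AR", "RSR")
SLOW_BLOCK: tuple[str, ...] = ("LMA", "LT", "LD", "RSR")
FAST_BLOCK: tuple[str, ...] = ("PH", "LA", "AR")


def default_trait_covariance(
    within: float = 0.6,
    between: float = 0.0,
    trait_names: Sequence[str] = TRAIT_NAMES,
    block1: Sequence[str] = SLOW_BLOCK,
    block2: Sequence[str] = FAST_BLOCK,
) -> pd.DataFrame:
    """Two-block trait rate matrix (unit variances, block correlations)."""
    p = len(trait_names)
    R = np.full((p, p), between)
    pos = {t: i for i, t in enumerate(trait_names)}
    for block in (block1, block2):
        for a in block:
            for b in block:
                R[pos[a], pos[b]] = within
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=trait_names, columns=trait_names)


@dataclass
class SimulationConfig:
    n_taxa: int = 34
    clade_sizes: tuple[int, int, int] = (10, 12, 12)
    birth_rate: float = 1.0
    depth: float = 1.0
    q: float | None = None          # Mk exchange rate; None -> auto from tree length
    states: tuple[str, ...] = DEFAULT_STATES
    trait_names: tuple[str, ...] = TRAIT_NAMES
    R: pd.DataFrame | None = None   # trait rate matrix; None -> two-block default
    lambda_per_trait: Mapping[str, float] | None = None  # None -> AR=0, rest 1
    habitat_effects: Mapping[str, Mapping[str, float]] | None = None
    clade_R: Mapping[str, pd.DataFrame] | None = None    # per-clade rate matrices
    tip_stretch: float = 0.5        # terminal-branch stretch within clades
    root_state: str | None = "CS"   # the study system's inferred origin
    target_switches: tuple[int, int] = (5, 9)
    max_retries: int = 500
    seed: int = 0

    def resolve(self) -> "SimulationConfig":
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.R is None:
            self.R = default_trait_covariance(trait_names=self.trait_names)
        w = np.linalg.eigvalsh(self.R.to_numpy())
        if w.min() <= 0:
            raise ValueError("trait rate matrix R must be positive definite")
        if self.lambda_per_trait is None:
            self.lambda_per_trait = {
                t: (0.0 if t == "AR" else 1.0) for t in self.trait_names
            }
        if any(not 0 <= v <= 1 for v in self.lambda_per_trait.values()):
            raise ValueError("lambda values must lie in [0, 1]")
        if self.habitat_effects is None:
            self.habitat_effects = {
                "CS": {t: 2.0 for t in SLOW_BLOCK if t in self.trait_names}
            }
        return self


@dataclass
class SyntheticDataset:
    tree: PhyloTree
    habitat: pd.Series              # taxon -> state
    traits: pd.DataFrame            # taxon x trait, log scale
    climate: pd.DataFrame           # taxon x (wMAT, wMAP)
    truth: dict                     # generating parameters and true node states

    def validate(self) -> None:
        taxa = set(self.tree.tip_labels)
        for name, obj in (
            ("habitat", self.habitat),
            ("traits", self.traits),
            ("climate", self.climate),
        ):
            if set(obj.index) != taxa:
                raise ValueError(f"{name} taxa differ from tree tips")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_yule(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    prefix: str = "t",
) -> PhyloTree:
    """Pure-birth (Yule) tree conditioned on ``n_taxa`` tips.

    Starting from the root split (2 lineages), the waiting time between
    successive birth events with k extant lineages is Exponential(k * birth);
    after the (n-1)-th split the process runs for one further
    Exponential(n * birth) stretch to the present.  The result is ultrametric
    and bifurcating.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    active: list[dendropy.Node] = []
    for _ in range(2):
        c = dendropy.Node()
        c.edge.length = 0.0
        root.add_child(c)
        active.append(c)
    k = 2
    while k < n_taxa:
        wait = rng.exponential(1.0 / (k * birth_rate))
        for nd in active:
            nd.edge.length += wait
        split = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            c = dendropy.Node()
            c.edge.length = 0.0
            split.add_child(c)
            active.append(c)
        k += 1
    final = rng.exponential(1.0 / (n_taxa * birth_rate))
    for nd in active:
        nd.edge.length += final
    width = len(str(n_taxa))
    for i, nd in enumerate(active):
        nd.taxon = taxa.new_taxon(f"{prefix}{i + 1:0{width}d}")
    return PhyloTree(tree)


def simulate_mk(
    tree: PhyloTree,
    q: float,
    states: Sequence[str] = DEFAULT_STATES,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    root_state: str | None = None,
) -> tuple[pd.Series, dict[str, str]]:
    """Simulate an equal-rates Mk character by exact branch-end sampling.

    The root state is uniform (or fixed to ``root_state``); along each branch
    of length t the child state is drawn from the analytic ER transition
    matrix P(t).  Returns the tip character and the true state of every node
    (tips and internals).
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    k = len(states)
    work = tree.copy()
    work.ensure_node_ids()
    node_states: dict[str, str] = {}
    state_of: dict = {}
    for nd in work.d.preorder_node_iter():
        nid = nd.taxon.label if nd.is_leaf() else nd.label
        if nd.parent_node is None:
            j = (
                list(states).index(root_state)
                if root_state is not None
                else int(rng.integers(k))
            )
        else:
            pi = state_of[nd.parent_node]
            P = transition_matrix([q], "ER", nd.edge.length or 0.0, k)
            j = int(rng.choice(k, p=P[pi]))
        state_of[nd] = j
        node_states[nid] = states[j]
    tips = pd.Series(
        {t: node_states[t] for t in tree.tip_labels}, name="habitat"
    )
    return tips, node_states


def _true_switches(tree: PhyloTree, node_states: Mapping[str, str]) -> int:
    work = tree.copy()
    work.ensure_node_ids()
    n = 0
    for nd in work.d.preorder_node_iter():
        if nd.parent_node is None:
            continue
        pid = nd.parent_node.label
        cid = nd.taxon.label if nd.is_leaf() else nd.label
        if node_states[pid] != node_states[cid]:
            n += 1
    return n


def simulate_traits(
    tree: PhyloTree,
    R: pd.DataFrame,
    lambda_per_trait: Mapping[str, float] | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Multivariate trait values at the tips under lambda-damped BM.

    Tip values follow a matrix normal whose among-trait covariance is R and
    whose among-taxa covariance for trait j is the lambda_j-transform of the
    phylogenetic covariance C.  Construction: X = L_C Z1 L_R' diag(sqrt(l))
    + D^{1/2} Z2 L_R' diag(sqrt(1-l)) with D = diag(C), which reproduces the
    per-trait lambda transform exactly and shrinks cross-trait, cross-taxon
    covariance for traits with lambda < 1.
    """
    w = np.linalg.eigvalsh(R.to_numpy())
    if w.min() <= 0:
        raise ValueError("R must be positive definite")
    rng = rng if rng is not None else np.random.default_rng(seed)
    traits = list(R.columns)
    lam = np.array(
        [1.0 if lambda_per_trait is None else lambda_per_trait[t] for t in traits]
    )
    order, C = tree.phylo_covariance()
    n, p = len(order), len(traits)
    L_C = np.linalg.cholesky(C)
    L_R = np.linalg.cholesky(R.to_numpy())
    D = np.sqrt(np.diag(C))
    Z1 = rng.standard_normal((n, p))
    Z2 = rng.standard_normal((n, p))
    X = (L_C @ Z1 @ L_R.T) * np.sqrt(lam)[None, :] + (
        D[:, None] * (Z2 @ L_R.T)
    ) * np.sqrt(1.0 - lam)[None, :]
    return pd.DataFrame(X, index=order, columns=traits)


def _simulate_traits_by_clade(
    tree: PhyloTree,
    R_default: pd.DataFrame,
    clade_R: Mapping[str, pd.DataFrame],
    clades: Mapping[str, Sequence[str]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Branch-wise BM with a clade-specific trait rate matrix (lambda = 1).

    A branch uses clade X's matrix when all tips below it belong to clade X;
    backbone branches use the default matrix.
    """
    traits = list(R_default.columns)
    chol = {name: np.linalg.cholesky(Rc.loc[traits, traits].to_numpy())
            for name, Rc in clade_R.items()}
    chol_default = np.linalg.cholesky(R_default.to_numpy())
    member = {t: name for name, taxa in clades.items() for t in taxa}

    work = tree.copy()
    work.ensure_node_ids()
    vals: dict = {}
    rows: dict[str, np.ndarray] = {}
    for nd in work.d.preorder_node_iter():
        if nd.parent_node is None:
            vals[nd] = np.zeros(len(traits))
        else:
            owners = {member.get(t.taxon.label) for t in nd.leaf_iter()}
            if len(owners) == 1 and (owner := owners.pop()) in chol:
                L = chol[owner]
            else:
                L = chol_default
            t_len = nd.edge.length or 0.0
            step = L @ rng.standard_normal(len(traits)) * np.sqrt(t_len)
            vals[nd] = vals[nd.parent_node] + step
        if nd.is_leaf():
            rows[nd.taxon.label] = vals[nd]
    return pd.DataFrame.from_dict(rows, orient="index", columns=traits).loc[
        tree.tip_labels
    ]


def _build_clade_tree(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[PhyloTree, dict[str, list[str]]]:
    """Ultrametric tree of three labelled clades on a fixed backbone.

    Root (depth 0) splits into clade I's stem and the ancestor of clades
    II and III (depth 0.2 * depth); clade crown groups sit at 0.4 * depth
    and each clade subtree is a Yule tree rescaled to 0.6 * depth.
    """
    sizes = config.clade_sizes
    if sum(sizes) != config.n_taxa:
        raise ValueError("clade sizes must sum to n_taxa")
    depth = config.depth
    crown, inner = 0.6 * depth, 0.2 * depth
    width = len(str(config.n_taxa))
    subtrees = []
    clades: dict[str, list[str]] = {}
    start = 1
    for name, size in zip(("CladeI", "CladeII", "CladeIII"), sizes):
        sub = simulate_yule(size, birth_rate=config.birth_rate, rng=rng)
        d = max(sub.tip_depths().values())
        # Stretch every terminal branch by a fixed share of the crown depth
        # (keeping the subtree ultrametric), emulating consensus trees made
        # ultrametric by lengthening terminals; raw Yule realizations have
        # near-zero terminal branches that give no-signal traits pathological
        # weight in inverse-covariance analyses.
        s = config.tip_stretch * d
        for nd in sub.d.leaf_node_iter():
            nd.edge.length = (nd.edge.length or 0.0) + s
        d += s
        for nd in sub.d.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = (nd.edge.length or 0.0) * crown / d
        labels = [f"sp{j:0{width}d}" for j in range(start, start + size)]
        for tip, lbl in zip(sub.d.leaf_node_iter(), labels):
            tip.taxon.label = lbl
        clades[name] = labels
        start += size
        subtrees.append(sub)
    nwk = [t.to_newick().rstrip(";").lstrip("[&R] ").strip() for t in subtrees]
    stem_i = depth - crown               # clade I stem: root -> crown
    stem_inner = depth - crown - inner   # clade II/III stems from inner node
    text = (
        f"({nwk[0]}:{stem_i:.10g},"
        f"({nwk[1]}:{stem_inner:.10g},{nwk[2]}:{stem_inner:.10g}):{inner:.10g});"
    )
    return PhyloTree.from_newick(text), clades


def make_fixture(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic dataset under the default study design."""
    config = (config or SimulationConfig()).resolve()
    rng = np.random.default_rng(config.seed)
    tree, clades = _build_clade_tree(config, rng)

    # habitat: ER Mk, resampled until the true history has 5-9 switches.
    # Expected switches ~= 2q * total length (leaving rate 2q for K = 3),
    # so default q targets the middle of the accepted range.
    q = config.q
    if q is None:
        q = (sum(config.target_switches) / 2.0) / (2.0 * tree.total_length())
    lo, hi = config.target_switches
    habitat = node_states = None
    for attempt in range(config.max_retries):
        hab, ns = simulate_mk(
            tree, q, config.states, rng=rng, root_state=config.root_state
        )
        n_sw = _true_switches(tree, ns)
        if lo <= n_sw <= hi and set(hab) == set(config.states):
            habitat, node_states, n_switches = hab, ns, n_sw
            break
    if habitat is None:
        raise RuntimeError(
            f"no habitat history with {lo}-{hi} switches in "
            f"{config.max_retries} draws; try a different q (used {q:.3g})"
        )

    # traits
    if config.clade_R:
        if any(
            v != 1.0 for v in config.lambda_per_trait.values()
        ):
            raise ValueError("clade-specific R requires lambda = 1 for all traits")
        traits = _simulate_traits_by_clade(
            tree, config.R, config.clade_R, clades, rng
        )
    else:
        traits = simulate_traits(
            tree, config.R, config.lambda_per_trait, rng=rng
        )
    for state, effects in config.habitat_effects.items():
        sel = habitat == state
        for tr, delta in effects.items():
            traits.loc[sel, tr] += delta

    # climate covariates: habitat-linked means plus BM noise
    base_mat = {"CS": 4.0, "HF": 10.0, "WA": 13.0}
    base_map = {"CS": 450.0, "HF": 900.0, "WA": 250.0}
    noise = simulate_traits(
        tree,
        pd.DataFrame(np.eye(2), index=["wMAT", "wMAP"], columns=["wMAT", "wMAP"]),
        {"wMAT": 1.0, "wMAP": 1.0},
        rng=rng,
    )
    climate = pd.DataFrame(
        {
            "wMAT": [base_mat[habitat[t]] for t in tree.tip_labels],
            "wMAP": [base_map[habitat[t]] for t in tree.tip_labels],
        },
        index=tree.tip_labels,
    )
    climate["wMAT"] += 1.5 * noise["wMAT"].loc[climate.index]
    climate["wMAP"] += 120.0 * noise["wMAP"].loc[climate.index]

    ds = SyntheticDataset(
        tree=tree,
        habitat=habitat,
        traits=traits,
        climate=climate,
        truth={
            "seed": config.seed,
            "q": q,
            "n_switches": n_switches,
            "node_states": node_states,
            "clades": clades,
            "lambda_per_trait": dict(config.lambda_per_trait),
            "habitat_effects": {
                s: dict(e) for s, e in config.habitat_effects.items()
            },
            "R": config.R.to_numpy().tolist(),
            "trait_names": list(config.trait_names),
        },
    )
    ds.validate()
    return ds


def modularity_scenario_config(
    seed: int,
    delta: float = 3.0,
    within_modular: float = 0.9,
    within_integrated: float = 0.6,
) -> SimulationConfig:
    """Scenario: one integrated clade, two leaf/life-form-modular clades.

    Clade I evolves with a fully integrated trait covariance (all
    correlations equal); Clades II and III evolve with zero covariance
    between the leaf module (LA, LMA, LT, LD, AR) and the life-form module
    (PH, RSR) and high correlation within each.  Cold-steppe lineages are
    shifted by ``delta`` on the slow-strategy traits, lowering their scores
    on the leading PC axis.  All traits evolve with lambda = 1 (required by
    the per-clade branchwise simulation).
    """
    R_mod = default_trait_covariance(
        within=within_modular, between=0.0,
        block1=("PH", "RSR"), block2=("LA", "LMA", "LT", "LD", "AR"),
    )
    R_int = default_trait_covariance(
        within=within_integrated, between=within_integrated
    )
    return SimulationConfig(
        seed=seed,
        R=R_mod,
        lambda_per_trait={t: 1.0 for t in TRAIT_NAMES},
        clade_R={"CladeI": R_int, "CladeII": R_mod, "CladeIII": R_mod},
        habitat_effects={"CS": {t: delta for t in SLOW_BLOCK}},
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write tree.nwk, traits.tsv, habitat.tsv, climate.tsv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    (outdir / "tree.nwk").write_text(ds.tree.to_newick() + "\n")
    files["tree"] = str(outdir / "tree.nwk")
    # traits are simulated on the log scale; files carry raw-scale values so
    # a pipeline run applies the same log + z preprocessing as on real data
    np.exp(ds.traits).rename_axis("taxon").to_csv(
        outdir / "traits.tsv", sep="\t", float_format="%.10g"
    )
    files["traits"] = str(outdir / "traits.tsv")
    ds.habitat.rename_axis("taxon").to_frame().to_csv(
        outdir / "habitat.tsv", sep="\t"
    )
    files["habitat"] = str(outdir / "habitat.tsv")
    ds.climate.rename_axis("taxon").to_csv(
        outdir / "climate.tsv", sep="\t", float_format="%.10g"
    )
    files["climate"] = str(outdir / "climate.tsv")
    (outdir / "truth.json").write_text(json.dumps(ds.truth, indent=1))
    files["truth"] = str(outdir / "truth.json")
    return files
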