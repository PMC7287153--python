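"""End-to-end orchestration: from data files to the full set of result tables.

Stages, in order: tree preparation (prune / resolve polytomies /
ultrametricize), Mk fits with LRT and marginal ancestral states plus
transition counts, trait preprocessing, phylogenetic PCA, PGLS of PC axes
on habitat and climate (with OLS comparison), per-trait lambda signal
table, evolutionary-rates table, and covariance-ratio modularity on all
taxa and per clade.  Every table is written as TSV with fixed float
formatting so that reruns under the same seeds are byte-identical; fits
and the run manifest are JSON.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, gls, mk, modularity, pca, pic
from .tree import PhyloTree, parse_newick

__all__ = ["PipelineConfig", "RunManifest", "auto_clades", "run_pipeline"]

_FLOAT = "%.10g"


@dataclass
class PipelineConfig:
    tree_path: str
    traits_path: str
    habitat_path: str
    climate_path: str | None = None
    out_dir: str = "results"
    habitat_reference: str = "CS"
    clades: dict[str, list[str]] | str = "auto:3-deepest"
    n_permutations: int = 999
    seed: int = 0
    ultrametric_method: str = "extend"
    polytomy_epsilon: float = 1e-4
    mk_model: str = "ER"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, status: str, outputs: list[str], wall: float):
        self.stages.append(
            {"stage": name, "status": status, "outputs": outputs,
             "wall_seconds": round(wall, 3)}
        )

    def write(self, path: Path):
        path.write_text(json.dumps(
            {"config": self.config, "version": self.version,
             "stages": self.stages}, indent=1))


def auto_clades(tree: PhyloTree) -> dict[str, list[str]]:
    """Three clades from the two deepest splits of the tree.

    The smaller root child is Clade I; the larger root child's two children
    are Clades II and III (ordered by their first tip label).  Errors if any
    resulting clade has fewer than 3 taxa.
    """
    if tree.n_tips < 9:
        raise ValueError("auto clade detection needs >= 9 taxa")
    root_kids = tree.d.seed_node.child_nodes()
    if len(root_kids) != 2:
        raise ValueError("root must be bifurcating for auto clade detection")

    def tipset(nd):
        return [t.taxon.label for t in nd.leaf_iter()]

    a, b = root_kids
    ta, tb = tipset(a), tipset(b)
    small, large = (ta, b) if len(ta) <= len(tb) else (tb, a)
    large_kids = large.child_nodes()
    if len(large_kids) != 2:
        raise ValueError("larger root child is not bifurcating")
    t1, t2 = tipset(large_kids[0]), tipset(large_kids[1])
    if min(t1) > min(t2):
        t1, t2 = t2, t1
    clades = {"CladeI": small, "CladeII": t1, "CladeIII": t2}
    for name, taxa in clades.items():
        if len(taxa) < 3:
            raise ValueError(
                f"{name} would have {len(taxa)} taxa; supply explicit clade lists"
            )
    return clades


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", float_format=_FLOAT)


def _pgls_row(fit: gls.GLSFit) -> dict:
    row = {
        "response": fit.response, "design": fit.design, "kind": fit.kind,
        "n": fit.n, "F": fit.fvalue, "df1": fit.f_df[0], "df2": fit.f_df[1],
        "F_p": fit.f_p, "R2": fit.r2,
        "lambda": fit.lam if fit.lam is not None else "",
        "AIC": fit.aic, "logLik": fit.loglik,
    }
    for name, r in fit.params.iterrows():
        tag = name.replace(" ", "_")
        row[f"coef_{tag}"] = r["coef"]
        row[f"t_{tag}"] = r["t"]
        row[f"p_{tag}"] = r["p"]
    return row


def run_pipeline(config: PipelineConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.__dict__.copy(), version=__version__)

    for p in (config.tree_path, config.traits_path, config.habitat_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    if config.climate_path and not Path(config.climate_path).exists():
        raise FileNotFoundError(config.climate_path)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                outputs = fn() or []
            except Exception:
                manifest.record(name, "failed", [], time.perf_counter() - t0)
                manifest.write(out / "manifest.json")
                raise
            manifest.record(name, "ok", outputs, time.perf_counter() - t0)
            return outputs
        return wrap

    state: dict = {}

    @stage("tree_prep")
    def _tree_prep():
        tree = parse_newick(Path(config.tree_path).read_text())
        raw_traits = pd.read_csv(config.traits_path, sep="\t", index_col=0)
        habitat = pd.read_csv(config.habitat_path, sep="\t", index_col=0).iloc[:, 0]
        climate = (
            pd.read_csv(config.climate_path, sep="\t", index_col=0)
            if config.climate_path else None
        )
        shared = [t for t in tree.tip_labels
                  if t in raw_traits.index and t in habitat.index]
        if len(shared) < 10:
            raise ValueError(
                f"only {len(shared)} taxa shared between tree and tables"
            )
        if len(shared) < tree.n_tips:
            tree = tree.prune_to(shared)
        if not tree.is_bifurcating():
            tree = tree.resolve_polytomies(config.polytomy_epsilon, config.seed)
        if not tree.is_ultrametric():
            tree = tree.force_ultrametric(config.ultrametric_method)
        tree.ensure_node_ids()
        state["tree"] = tree
        state["raw_traits"] = raw_traits.loc[tree.tip_labels]
        state["habitat"] = habitat.loc[tree.tip_labels]
        state["climate"] = (
            climate.loc[tree.tip_labels] if climate is not None else None
        )
        if isinstance(config.clades, str):
            if config.clades != "auto:3-deepest":
                raise ValueError(f"unknown clade rule {config.clades!r}")
            state["clades"] = auto_clades(tree)
        else:
            state["clades"] = {
                k: [t for t in v if t in set(tree.tip_labels)]
                for k, v in config.clades.items()
            }
        path = out / "prepared_tree.nwk"
        path.write_text(tree.to_newick() + "\n")
        (out / "clades.json").write_text(json.dumps(state["clades"], indent=1))
        return [str(path), str(out / "clades.json")]

    @stage("mk_ancestral")
    def _mk():
        tree, habitat = state["tree"], state["habitat"]
        char = habitat.to_dict()
        fit_er = mk.fit_mk(tree, char, "ER", seed=config.seed)
        fit_sym = mk.fit_mk(tree, char, "SYM", seed=config.seed)
        stat, df, p = mk.lrt(fit_er, fit_sym)
        chosen = fit_er if config.mk_model.upper() == "ER" else fit_sym
        marg = mk.marginal_ancestral_states(
            tree, char, chosen.model, chosen.rates
        )
        states_map = mk.most_probable_states(marg).to_dict()
        trans = mk.count_transitions(tree, states_map)
        fits = {
            "ER": {"q": fit_er.rates.tolist(),
                   "logLik": fit_er.log_likelihood, "AIC": fit_er.aic},
            "SYM": {"rates": fit_sym.rates.tolist(),
                    "logLik": fit_sym.log_likelihood, "AIC": fit_sym.aic},
            "LRT": {"statistic": stat, "df": df, "p": p},
            "model_used": chosen.model,
        }
        (out / "mk_fits.json").write_text(json.dumps(fits, indent=1))
        _write_tsv(marg, out / "ancestral_states.tsv")
        _write_tsv(trans.set_index("from"), out / "transitions.tsv")
        # annotated tree: internal labels replaced by most probable state
        ann = tree.copy()
        ann.ensure_node_ids()
        for nd in ann.d.preorder_internal_node_iter():
            nd.label = f"{nd.label}={states_map[nd.label]}"
        (out / "ancestral_tree.nwk").write_text(ann.to_newick() + "\n")
        state["mk"] = fits
        return [str(out / f) for f in
                ("mk_fits.json", "ancestral_states.tsv",
                 "transitions.tsv", "ancestral_tree.nwk")]

    @stage("preprocess_traits")
    def _traits():
        logz = pic.preprocess_traits(state["raw_traits"])
        state["traits"] = logz
        _write_tsv(logz, out / "traits_logz.tsv")
        return [str(out / "traits_logz.tsv")]

    @stage("phylo_pca")
    def _pca():
        res = pca.phylo_pca(state["tree"], state["traits"])
        state["pca"] = res
        _write_tsv(res.loadings, out / "pca_loadings.tsv")
        _write_tsv(res.scores, out / "pca_scores.tsv")
        eig = pd.DataFrame(
            {"eigenvalue": res.eigenvalues, "proportion": res.proportions},
            index=res.loadings.columns,
        )
        _write_tsv(eig, out / "pca_eigenvalues.tsv")
        return [str(out / f) for f in
                ("pca_loadings.tsv", "pca_scores.tsv", "pca_eigenvalues.tsv")]

    @stage("pgls")
    def _pgls():
        tree = state["tree"]
        scores = state["pca"].scores
        rows = []
        designs = {"habitat": gls.habitat_design(
            state["habitat"], config.habitat_reference
        )}
        if state["climate"] is not None:
            designs["climate"] = state["climate"][["wMAT", "wMAP"]]
        for resp in ("PC1", "PC2"):
            y = scores[resp]
            for dname, X in designs.items():
                for mode in ("pgls_ml_lambda", "ols"):
                    fit = gls.pgls(tree, y, X, mode=mode)
                    rows.append(_pgls_row(fit))
        table = pd.DataFrame(rows).set_index(["response", "design", "kind"])
        _write_tsv(table, out / "pgls.tsv")
        state["pgls"] = table
        return [str(out / "pgls.tsv")]

    @stage("signal_lambda")
    def _signal():
        tree = state["tree"]
        cols = dict(state["traits"].items())
        if state["climate"] is not None:
            for c in state["climate"].columns:
                cols[c] = state["climate"][c]
        rows = []
        for name, series in cols.items():
            lf = gls.fit_lambda(tree, series)
            rows.append({
                "trait": name, "lambda": lf.lambda_hat,
                "logLik": lf.loglik, "AIC_hat": lf.aic_hat,
                "AIC_lambda0": lf.aic0, "AIC_lambda1": lf.aic1,
            })
        table = pd.DataFrame(rows).set_index("trait")
        _write_tsv(table, out / "signal_lambda.tsv")
        state["signal"] = table
        return [str(out / "signal_lambda.tsv")]

    @stage("rates")
    def _rates():
        table = pic.rates_table(
            state["tree"], state["traits"], state["clades"]
        )
        _write_tsv(table, out / "rates.tsv")
        state["rates"] = table
        return [str(out / "rates.tsv")]

    @stage("modularity")
    def _modularity():
        results = modularity.modularity_by_clade(
            state["tree"], state["traits"], state["clades"],
            n_permutations=config.n_permutations, seed=config.seed,
        )
        rows = [{
            "scope": r.scope,
            "CR": r.cr_observed if r.cr_observed is not None else "",
            "p": r.p_value if r.p_value is not None else "",
            "n_taxa": r.n_taxa,
            "n_permutations": r.n_permutations,
            "note": r.note,
        } for r in results]
        table = pd.DataFrame(rows).set_index("scope")
        _write_tsv(table, out / "modularity.tsv")
        state["modularity"] = table
        return [str(out / "modularity.tsv")]

    manifest.write(out / "manifest.json")
    return manifest
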