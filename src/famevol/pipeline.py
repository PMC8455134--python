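"""Run configuration and the end-to-end workflow.

A :class:`RunConfig` carries every threshold of the analysis with its
standard default (per-branch shift level 0.05, copy cap 100, minimum two
species, 100 permutations, 500 bootstrap replicates, six focal branches,
truncation 100, 75%/75% annotation fractions) plus input paths and stage
toggles; :func:`run_pipeline` wires the stages together
(simulate → dollo → enrichment → birth-death fit → shifts → giant-branch
analyses) and writes one TSV per stage plus a JSON manifest recording
inputs, outputs, seeds and elapsed time per stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, birthdeath, dollo, enrichment, giants, simulate
from .errors import FamevolError
from .io import (BranchSet, GeneSet, config_hash, read_branch_set,
                 read_gene_counts, write_tsv)
from .trees import TimeTree, read_newick

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; every threshold has its standard default."""

    seed: int = 0
    out_dir: str = "famevol_out"
    # inputs (omitted => the synthetic stage must be enabled)
    tree_path: str | None = None
    counts_path: str | None = None
    giant_branches_path: str | None = None
    sister_branches_path: str | None = None
    # stage toggles
    do_simulate: bool = True
    do_dollo: bool = True
    do_enrich: bool = True
    do_bdfit: bool = True
    do_shifts: bool = True
    do_giants: bool = True
    do_ohnolog: bool = True
    # thresholds (defaults are the standard analysis settings)
    alpha: float = 0.05
    max_copies: int = 100
    min_species: int = 2
    n_perm: int = 100
    n_boot: int = 500
    k_random_branches: int = 6
    s_max: int = 100
    protein_frac: float = 0.75
    taxon_frac: float = 0.75
    # synthetic-data settings
    sim_n_tips: int = 12
    sim_n_families: int = 1500
    sim_lambda: float = 6e-4
    sim_giant_multiplier: float = 2.0
    sim_n_giant: int = 6
    sim_fraction_cancer: float = 0.05
    sim_effect: float = 3.0
    sim_ohnolog_split_fraction: float = 0.054

    @staticmethod
    def from_yaml(path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, val in data.items():
            if isinstance(val, dict):  # sections are flattened
                flat.update(val)
            else:
                flat[key] = val
        known = {f for f in RunConfig.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise FamevolError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**flat)

    def validate(self) -> None:
        if not self.do_simulate:
            for name in ("tree_path", "counts_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FamevolError(f"config: {name} missing or not found "
                                       "(and simulation is disabled)")

    def to_dict(self) -> dict:
        return asdict(self)


def _draw_giant(tree: TimeTree, cfg: RunConfig,
                rng: np.random.Generator) -> BranchSet:
    if cfg.giant_branches_path:
        return read_branch_set(cfg.giant_branches_path, tree, name="giant")
    branches = tree.branches()
    pick = rng.choice(len(branches), size=min(cfg.sim_n_giant, len(branches) - 1),
                      replace=False)
    return BranchSet("giant", frozenset(branches[i] for i in pick))


def _sister_of(tree: TimeTree, giant: BranchSet, cfg: RunConfig,
               rng: np.random.Generator) -> BranchSet:
    """The sister-control set: sibling branches of the giants, where distinct."""
    if cfg.sister_branches_path:
        return read_branch_set(cfg.sister_branches_path, tree, name="sister")
    sibs = set()
    for v in giant.branches:
        p = tree.parent[v]
        for ch in tree.children[p]:
            if ch != v and ch not in giant.branches and ch != tree.root:
                sibs.add(ch)
    if not sibs:  # fall back to a random disjoint draw
        pool = [b for b in tree.branches() if b not in giant.branches]
        pick = rng.choice(len(pool), size=min(len(giant), len(pool)),
                          replace=False)
        sibs = {pool[i] for i in pick}
    return BranchSet("sister", frozenset(sibs))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg.to_dict())
    manifest: dict = {"version": __version__, "config_hash": chash,
                      "seed": cfg.seed, "stages": []}
    rng = np.random.default_rng(cfg.seed)
    t_start = time.time()

    def stage(name):
        log.info("stage %s", name)
        return {"stage": name, "t0": time.time()}

    def done(rec, **outputs):
        rec["elapsed_s"] = round(time.time() - rec.pop("t0"), 3)
        rec["outputs"] = {k: str(v) for k, v in outputs.items()}
        manifest["stages"].append(rec)

    # ------------------------------------------------------------ inputs
    truth = None
    cancer: GeneSet | None = None
    if cfg.do_simulate:
        rec = stage("simulate")
        tree = simulate.simulate_tree(cfg.sim_n_tips, seed=cfg.seed)
        giant = _draw_giant(tree, cfg, rng)
        sim_cfg = simulate.SimConfig(
            seed=cfg.seed, n_families=cfg.sim_n_families,
            lambda_background=cfg.sim_lambda,
            giant_multiplier=cfg.sim_giant_multiplier,
            giant_branches=giant.branches, s_max=cfg.s_max,
            fraction_cancer=cfg.sim_fraction_cancer,
            enrichment_effect=cfg.sim_effect,
            min_surviving_tips=cfg.min_species)
        counts, truth = simulate.simulate_counts(tree, sim_cfg)
        cancer, amap = simulate.simulate_labels(counts.family_ids, truth, sim_cfg)
        tree_path = out / "tree.nwk"
        tree_path.write_text(tree.to_newick() + "\n")
        counts_df = counts.counts.copy()
        counts_df.insert(len(counts_df.columns), "Total", counts_df.sum(axis=1))
        counts_df.index.name = "Orthogroup"
        counts_df.to_csv(out / "gene_counts.tsv", sep="\t")
        write_tsv(truth.to_frame(), str(out / "truth.tsv"), cfg.to_dict())
        write_tsv(amap.to_frame(), str(out / "annotations.tsv"), cfg.to_dict(),
                  index=False)
        (out / "sim_config.yaml").write_text(yaml.safe_dump(sim_cfg.to_dict()))
        done(rec, tree=tree_path, counts=out / "gene_counts.tsv",
             truth=out / "truth.tsv")
        sister = _sister_of(tree, giant, cfg, rng)
    else:
        tree = read_newick(cfg.tree_path)
        counts = read_gene_counts(cfg.counts_path)
        giant = _draw_giant(tree, cfg, rng)
        sister = _sister_of(tree, giant, cfg, rng)
        amap = None

    results: dict = {"tree": tree, "counts": counts, "giant": giant,
                     "sister": sister, "truth": truth, "cancer": cancer}

    # -------------------------------------------------------------- dollo
    if cfg.do_dollo:
        rec = stage("dollo")
        presence = counts.presence().drop_empty()
        reconstruction = dollo.reconstruct(presence, tree)
        summaries = dollo.node_summaries(reconstruction, tree)
        write_tsv(reconstruction.to_frame(), str(out / "dollo_families.tsv"),
                  cfg.to_dict())
        write_tsv(summaries, str(out / "dollo_nodes.tsv"), cfg.to_dict())
        write_tsv(dollo.stratified_losses(reconstruction, tree),
                  str(out / "dollo_losses_by_origin.tsv"), cfg.to_dict(),
                  index=False)
        results["reconstruction"] = reconstruction
        results["summaries"] = summaries
        done(rec, families=out / "dollo_families.tsv", nodes=out / "dollo_nodes.tsv")

    # -------------------------------------------------------- enrichment
    if cfg.do_enrich and amap is not None and "reconstruction" in results:
        rec = stage("enrich")
        fam_ann = enrichment.assign_family_annotations(
            amap, cfg.protein_frac, cfg.taxon_frac)
        reconstruction = results["reconstruction"]
        root_novel = [f for f, o in zip(reconstruction.family_ids,
                                        reconstruction.origin)
                      if o == tree.root]
        rows = []
        if root_novel:
            for res in enrichment.term_enrichment(root_novel,
                                                  reconstruction.family_ids,
                                                  fam_ann, alpha=cfg.alpha):
                t = res.table
                rows.append([res.name, t.a, t.b, t.c, t.d, res.odds_ratio,
                             res.p, res.q, res.significant])
        df = pd.DataFrame(rows, columns=["term", "a", "b", "c", "d",
                                         "odds_ratio", "p", "q", "flagged"])
        write_tsv(df, str(out / "enrichment_root_novel.tsv"), cfg.to_dict(),
                  index=False)
        results["fam_ann"] = fam_ann
        done(rec, enrichment=out / "enrichment_root_novel.tsv")

    # ------------------------------------------------------------- bdfit
    if cfg.do_bdfit:
        rec = stage("bdfit")
        reconstruction = results.get("reconstruction")
        if reconstruction is not None:
            filtered = dollo.filter_for_bd(counts, reconstruction, tree.root,
                                           max_copies=cfg.max_copies,
                                           min_species=cfg.min_species)
        else:
            filtered = counts
        classes = {v: "giant" for v in giant.branches}
        fit1 = birthdeath.fit_lambda(filtered, tree, seed=cfg.seed)
        fit2 = birthdeath.fit_lambda(filtered, tree, classes, seed=cfg.seed,
                                     x0=dict(fit1.lam, giant=fit1.lam["background"]))
        lrt = birthdeath.lrt_bootstrap(filtered, tree, None, classes,
                                       n_reps=cfg.n_boot, seed=cfg.seed)
        fit_df = pd.DataFrame(
            {"model": ["single_lambda"] * len(fit1.lam) + ["two_lambda"] * len(fit2.lam),
             "class": list(fit1.lam) + list(fit2.lam),
             "lambda": list(fit1.lam.values()) + list(fit2.lam.values()),
             "loglik": [fit1.loglik] * len(fit1.lam) + [fit2.loglik] * len(fit2.lam)})
        write_tsv(fit_df, str(out / "bd_fit.tsv"), cfg.to_dict(), index=False)
        write_tsv(pd.DataFrame({"stat_2dlnl": [lrt.observed], "p": [lrt.p],
                                "n_reps": [len(lrt.null_stats)],
                                "n_dropped": [lrt.n_dropped]}),
                  str(out / "bd_lrt.tsv"), cfg.to_dict(), index=False)
        results.update(filtered=filtered, fit1=fit1, fit2=fit2, lrt=lrt)
        done(rec, fit=out / "bd_fit.tsv", lrt=out / "bd_lrt.tsv")

    # ------------------------------------------------------------ shifts
    if cfg.do_shifts and "fit2" in results:
        rec = stage("shifts")
        filtered = results["filtered"]
        anc = birthdeath.ancestral_states(filtered, tree, results["fit2"].model,
                                          store_marginals=False)
        pvals = birthdeath.branch_shift_pvalues(anc)
        rates = birthdeath.branch_rates(anc)
        write_tsv(pvals, str(out / "branch_shift_pvalues.tsv"), cfg.to_dict())
        write_tsv(rates, str(out / "branch_rates.tsv"), cfg.to_dict())
        results.update(anc=anc, pvals=pvals, rates=rates)
        done(rec, pvalues=out / "branch_shift_pvalues.tsv",
             rates=out / "branch_rates.tsv")

    # ------------------------------------------------------------ giants
    if cfg.do_giants and "pvals" in results and cancer is not None:
        rec = stage("giants")
        pvals, rates = results["pvals"], results["rates"]
        ss = giants.shifted_sets(pvals, [giant, sister], alpha=cfg.alpha)
        all_fams = list(pvals.index)
        res_all = giants.branch_set_enrichment(ss, giant, cancer,
                                               "all_families", all_fams)
        res_shift = giants.branch_set_enrichment(ss, giant, cancer, "all_shifted")
        res_sister = giants.sister_control(ss, sister, cancer, "all_shifted")
        perm = giants.permutation_null(pvals, tree, cancer,
                                       k=cfg.k_random_branches,
                                       n_perm=cfg.n_perm, seed=cfg.seed,
                                       observed=res_shift, alpha=cfg.alpha)
        shifted = sorted(ss.all_shifted)
        lmm = None
        try:
            lmm = giants.interaction_model(rates.loc[shifted], giant, cancer)
        except FamevolError as exc:
            log.warning("interaction model skipped: %s", exc)
        ratio = giants.rate_ratio(rates.loc[shifted], giant, cancer)

        def row(r, name):
            t = r.table
            return [name, t.a, t.b, t.c, t.d, r.odds_ratio, r.p]

        enr = pd.DataFrame([row(res_all, "giant_vs_all_families"),
                            row(res_shift, "giant_vs_all_shifted"),
                            row(res_sister, "sister_vs_all_shifted")],
                           columns=["test", "a", "b", "c", "d", "odds_ratio", "p"])
        write_tsv(enr, str(out / "giant_enrichment.tsv"), cfg.to_dict(),
                  index=False)
        write_tsv(pd.DataFrame({"null_odds_ratio": perm.null_or}),
                  str(out / "permutation_null.tsv"), cfg.to_dict(), index=False)
        if lmm is not None:
            write_tsv(lmm.to_frame(), str(out / "interaction_model.tsv"),
                      cfg.to_dict())
        write_tsv(ratio.to_frame(), str(out / "rate_ratio.tsv"), cfg.to_dict(),
                  index=False)
        results.update(shift_sets=ss, enrichment=enr, permutation=perm,
                       interaction=lmm, rate_ratio=ratio)
        done(rec, enrichment=out / "giant_enrichment.tsv",
             permutation=out / "permutation_null.tsv")

    # ----------------------------------------------------------- ohnolog
    if cfg.do_ohnolog and truth is not None:
        rec = stage("ohnolog_split")
        ours, ref = simulate.simulate_ohnolog_reference(
            counts.family_ids, cfg.sim_ohnolog_split_fraction, cfg.seed)
        report = dollo.split_report(ours, ref, set(counts.family_ids))
        write_tsv(report.to_frame(), str(out / "ohnolog_split.tsv"),
                  cfg.to_dict(), index=False)
        results["split_report"] = report
        done(rec, report=out / "ohnolog_split.tsv")

    manifest["elapsed_s"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
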