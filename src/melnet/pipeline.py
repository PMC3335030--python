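"""Orchestrate the full analysis as a reproducible, configured, logged run.

Stage order mirrors the analysis narrative: generate synthetic data,
preprocess (batch scale + noise floor + knockdown efficacy), cluster,
screen gene sets, infer the consensus network, screen survival, classify
prognosis.  Every stage writes plain-text artefacts into the run directory
and records itself in a JSON manifest that suffices to reproduce the run
(config snapshot, global seed, per-stage derived seeds, output paths and
summary metrics).  Timings go to the log only, keeping the manifest
deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import coexpression as coex
from . import genesets as gs
from . import network as net
from . import preprocess as prep
from . import survival as surv_mod
from . import synthetic as syn
from .dataio import (
    ConfigError,
    DataFormatError,
    read_expression_tsv,
    read_gmt,
    read_survival_csv,
    write_edge_list_tsv,
    write_expression_tsv,
    write_gmt,
    write_survival_csv,
)

log = logging.getLogger("melnet")

STAGES = [
    "generate",
    "preprocess",
    "cluster",
    "screen",
    "network",
    "survive",
    "classify",
]

#: All analysis thresholds surfaced as named config keys, with the
#: defaults used throughout the pipeline.
DEFAULT_CONFIG: dict = {
    # generator (see synthetic.GeneratorConfig)
    "generator": {f.name: f.default for f in dataclasses.fields(syn.GeneratorConfig)
                  if f.name not in ("module_size_range", "loading_range")},
    "module_size_range": [8, 15],
    "loading_range": [0.5, 0.9],
    "n_random_sets": 10,
    # preprocessing
    "noise_floor_percentile": 20.0,
    "noise_floor_factor": 1.5,
    # clustering
    "cluster_k": None,  # default: n_genes/10, floor 10
    "min_abs_rho": 0.4,
    "median_abs_rho": 0.5,
    "n_boot": 20,
    # gene-set screen
    "pair_rho_threshold": 0.5,
    "enrich_score_min": 1.3,
    "n_perm": 1000,
    # network
    "n_subnets": 500,
    "subnet_size": 15,
    "consensus_freq_threshold": 0.2,
    "consensus_denominator": "cooccurrence",
    "hub_min_children": 5,
    "conservation_rho": 0.4,
    "min_conserved_children": 5,
    # survival / classifier
    "cox_p_max": 0.05,
    "classifier_p_max": 0.05,
    "t_early": 2.0,
    "t_late": 3.0,
    "delta_grid": [round(0.1 * i, 2) for i in range(31)],
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if k == "generator":
                cfg["generator"].update(v)
            else:
                cfg[k] = v
    for k, v in (overrides or {}).items():
        if v is None:
            continue
        if k in cfg["generator"]:
            cfg["generator"][k] = v
        else:
            cfg[k] = v
    return cfg


def generator_config(cfg: dict) -> syn.GeneratorConfig:
    g = dict(cfg["generator"])
    g["module_size_range"] = tuple(cfg["module_size_range"])
    g["loading_range"] = tuple(cfg["loading_range"])
    return syn.GeneratorConfig(**g)


class RunManifest:
    """Mutable JSON-backed run manifest."""

    def __init__(self, outdir: Path, cfg: dict):
        self.outdir = Path(outdir)
        self.data = {
            "config": cfg,
            "seed": cfg["generator"]["seed"],
            "stage_seeds": {
                s: syn.stage_seed(cfg["generator"]["seed"], k)
                for s, k in (("generate", "truth"), ("cluster", "bootstrap"),
                             ("network", "network"), ("classify", "classifier"),
                             ("screen", "enrichment"))
            },
            "stages": {},
        }

    @property
    def path(self) -> Path:
        return self.outdir / "manifest.json"

    def record(self, stage: str, outputs: dict[str, str], metrics: dict) -> None:
        self.data["stages"][stage] = {"outputs": outputs, "metrics": metrics}
        self.save()

    def save(self) -> None:
        with open(self.path, "w", encoding="utf-8") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, outdir) -> "RunManifest":
        outdir = Path(outdir)
        with open(outdir / "manifest.json", encoding="utf-8") as fh:
            data = json.load(fh)
        m = cls(outdir, data["config"])
        m.data = data
        return m


def _timed(stage):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %-10s finished in %.1fs", stage, time.perf_counter() - t0)
            return out
        wrapper.__name__ = fn.__name__
        return wrapper
    return deco


@_timed("generate")
def stage_generate(manifest: RunManifest) -> None:
    cfg = manifest.data["config"]
    gcfg = generator_config(cfg)
    d = manifest.outdir
    truth = syn.generate_truth(gcfg)
    expr, design = syn.simulate_perturbation_dataset(truth, gcfg)
    tumours = syn.simulate_tumour_cohort(truth, gcfg)
    survival = syn.simulate_survival(truth, tumours, gcfg)
    sets = syn.generate_gene_sets(truth, cfg["n_random_sets"], gcfg.seed)

    truth.to_json(d / "truth.json")
    write_expression_tsv(expr, d / "perturbation_expression.tsv")
    write_expression_tsv(tumours, d / "tumour_expression.tsv")
    expr.module_activity.to_csv(d / "perturbation_activity.tsv", sep="\t")
    tumours.module_activity.to_csv(d / "tumour_activity.tsv", sep="\t")
    pd.Series(design.target_of_sample).rename("target").to_csv(
        d / "design.tsv", sep="\t", index_label="sample"
    )
    expr.batch_of_sample.rename("batch").to_csv(
        d / "batches.tsv", sep="\t", index_label="sample"
    )
    write_survival_csv(survival, d / "survival.csv")
    write_gmt(sets, d / "gene_sets.gmt")
    manifest.record(
        "generate",
        {
            "truth": "truth.json",
            "perturbation": "perturbation_expression.tsv",
            "tumours": "tumour_expression.tsv",
            "design": "design.tsv",
            "survival": "survival.csv",
            "gene_sets": "gene_sets.gmt",
        },
        {
            "n_genes": gcfg.n_genes,
            "n_modules": truth.n_modules,
            "n_samples": expr.n_samples,
            "n_tumours": tumours.n_samples,
            "n_gene_sets": len(sets),
        },
    )


def _load_perturbation(manifest: RunManifest):
    d = manifest.outdir
    expr = read_expression_tsv(d / "perturbation_expression.tsv")
    batches = pd.read_csv(d / "batches.tsv", sep="\t", index_col=0)["batch"]
    expr.batch_of_sample = batches
    design_series = pd.read_csv(d / "design.tsv", sep="\t", index_col=0)["target"]
    from .dataio import PerturbationDesign

    return expr, PerturbationDesign(design_series.to_dict())


@_timed("preprocess")
def stage_preprocess(manifest: RunManifest) -> None:
    cfg = manifest.data["config"]
    d = manifest.outdir
    expr, design = _load_perturbation(manifest)
    efficacy = prep.knockdown_efficacy(expr, design)
    scaled = prep.batch_median_scale(expr)
    # synthetic floor: percentile of per-gene medians of the unscaled matrix
    floor = float(
        np.percentile(expr.values.median(axis=1), cfg["noise_floor_percentile"])
    )
    filtered = prep.noise_floor_filter(expr, floor, cfg["noise_floor_factor"] / 1.5)
    scaled = scaled.subset_genes(filtered.gene_ids)
    write_expression_tsv(scaled, d / "preprocessed_expression.tsv")
    efficacy.to_tsv(d / "knockdown_efficacy.tsv")
    manifest.record(
        "preprocess",
        {
            "expression": "preprocessed_expression.tsv",
            "knockdown_efficacy": "knockdown_efficacy.tsv",
        },
        {
            "n_genes_kept": scaled.n_genes,
            "noise_floor": floor,
            "median_fold_reduction": float(
                efficacy.table["fold_reduction"].median()
            ),
        },
    )


@_timed("cluster")
def stage_cluster(manifest: RunManifest) -> None:
    cfg = manifest.data["config"]
    d = manifest.outdir
    expr = read_expression_tsv(d / "preprocessed_expression.tsv")
    expr.batch_of_sample = pd.read_csv(d / "batches.tsv", sep="\t", index_col=0)["batch"]
    corr = coex.spearman_matrix(expr)
    k = cfg["cluster_k"] or coex.default_k(expr.n_genes)
    cut = coex.ward_cluster(corr, k)
    retained = coex.filter_clusters(cut, corr)
    stability = coex.bootstrap_stability(
        expr, k, cfg["n_boot"], syn.stage_seed(manifest.data["seed"], "bootstrap"),
        clusters=retained,
    )
    table = retained.to_frame()
    table["stability"] = table["cluster"].map(stability)
    table.to_csv(d / "clusters.tsv", sep="\t", index=False)
    manifest.record(
        "cluster",
        {"clusters": "clusters.tsv"},
        {
            "k_requested": k,
            "n_cut_clusters": len(cut),
            "n_retained_clusters": len(retained),
            "n_clustered_genes": int(sum(c.size for c in retained.clusters)),
        },
    )


@_timed("screen")
def stage_screen(manifest: RunManifest) -> None:
    cfg = manifest.data["config"]
    d = manifest.outdir
    expr = read_expression_tsv(d / "preprocessed_expression.tsv")
    tumours = read_expression_tsv(d / "tumour_expression.tsv")
    sets = read_gmt(d / "gene_sets.gmt").min_size_filter(5)
    fractions = gs.compare_fractions(
        sets,
        [("perturbation", expr), ("tumour", tumours)],
        rho_threshold=cfg["pair_rho_threshold"],
    )
    fractions.to_csv(d / "pair_fractions.tsv", sep="\t", index=False)

    clusters = pd.read_csv(d / "clusters.tsv", sep="\t")
    queries = {
        f"cluster_{cid}": sub["gene"].tolist()
        for cid, sub in clusters.groupby("cluster")
    }
    enr = gs.enrichment_table(
        queries,
        sets,
        expr.gene_ids,
        n_perm=cfg["n_perm"],
        seed=syn.stage_seed(manifest.data["seed"], "enrichment"),
        score_min=cfg["enrich_score_min"],
    )
    enr.to_csv(d / "cluster_enrichment.tsv", sep="\t", index=False)
    n_sig = int(enr["significant"].sum()) if len(enr) else 0
    manifest.record(
        "screen",
        {"pair_fractions": "pair_fractions.tsv", "enrichment": "cluster_enrichment.tsv"},
        {
            "n_sets": len(sets),
            "n_significant_enrichments": n_sig,
            "n_shared_high": int(
                (fractions.drop_duplicates("set_name")["classification"] == "shared-high").sum()
            ),
            "n_tumour_only_high": int(
                (fractions.drop_duplicates("set_name")["classification"] == "tumour-only-high").sum()
            ),
        },
    )


@_timed("network")
def stage_network(manifest: RunManifest) -> None:
    cfg = manifest.data["config"]
    d = manifest.outdir
    expr = read_expression_tsv(d / "preprocessed_expression.tsv")
    tumours = read_expression_tsv(d / "tumour_expression.tsv")
    _pert, design = _load_perturbation(manifest)
    corr = coex.spearman_matrix(expr)
    subnet_size = min(cfg["subnet_size"], expr.n_genes)
    neighbourhoods = net.sample_neighbourhoods(
        corr, cfg["n_subnets"], subnet_size,
        syn.stage_seed(manifest.data["seed"], "network"),
    )
    subnets = [net.fit_subnetwork(expr, nodes) for nodes in neighbourhoods]
    consensus = net.consensus_network(
        subnets,
        cfg["consensus_freq_threshold"],
        denominator=cfg["consensus_denominator"],
    )
    write_edge_list_tsv(consensus.edges, d / "consensus_edges.tsv")
    hubs = net.find_hubs(consensus, cfg["hub_min_children"])
    annotated = net.hub_conservation(
        consensus, tumours, cfg["conservation_rho"], cfg["min_conserved_children"],
        hubs=hubs,
    )
    hub_df = pd.DataFrame(
        [
            {
                "gene": h.gene,
                "n_children": h.n_children,
                "n_conserved_children": h.n_conserved_children,
                "conserved": h.conserved,
            }
            for h in annotated
        ],
        columns=["gene", "n_children", "n_conserved_children", "conserved"],
    )
    hub_df.to_csv(d / "hubs.tsv", sep="\t", index=False)
    try:
        consistency = net.parent_knockdown_consistency(consensus, expr, design)
    except Exception:  # no targeted parent in the consensus network
        consistency = pd.DataFrame(
            columns=["parent", "child", "sample", "signed_ratio", "rho"]
        )
    consistency.to_csv(d / "knockdown_consistency.tsv", sep="\t", index=False)
    manifest.record(
        "network",
        {
            "edges": "consensus_edges.tsv",
            "hubs": "hubs.tsv",
            "knockdown_consistency": "knockdown_consistency.tsv",
        },
        {
            "n_subnets": len(subnets),
            "n_edges": len(consensus.edges),
            "n_hubs": len(hubs),
            "n_conserved_hubs": int(sum(bool(h.conserved) for h in annotated)),
        },
    )


@_timed("survive")
def stage_survive(manifest: RunManifest) -> None:
    cfg = manifest.data["config"]
    d = manifest.outdir
    tumours = read_expression_tsv(d / "tumour_expression.tsv")
    survival = read_survival_csv(d / "survival.csv")
    fits = surv_mod.cox_screen(tumours, survival)
    fits.to_csv(d / "cox_fits.tsv", sep="\t", index=False)

    # categories: hub genes vs everything else, refined by enriched set name
    hubs = pd.read_csv(d / "hubs.tsv", sep="\t")
    enr = pd.read_csv(d / "cluster_enrichment.tsv", sep="\t")
    categories = {g: "hub" for g in hubs["gene"]}
    summaries = surv_mod.category_summary(fits, categories)
    rows = [
        {
            "category": s.category,
            "n_genes": len(s.genes),
            "median_neg_log2_p": s.median,
            "iqr_low": s.iqr[0],
            "iqr_high": s.iqr[1],
            "fraction_significant": s.fraction_significant,
            "threshold": s.threshold,
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(d / "category_survival.tsv", sep="\t", index=False)
    n_sig_hubs = int(
        (fits.set_index("gene").reindex(hubs["gene"])["p"] <= cfg["cox_p_max"]).sum()
    )
    manifest.record(
        "survive",
        {"cox_fits": "cox_fits.tsv", "category_survival": "category_survival.tsv"},
        {
            "n_fits": len(fits),
            "n_significant_hubs": n_sig_hubs,
            "n_enrichment_rows": len(enr),
        },
    )


@_timed("classify")
def stage_classify(manifest: RunManifest) -> None:
    cfg = manifest.data["config"]
    d = manifest.outdir
    tumours = read_expression_tsv(d / "tumour_expression.tsv")
    survival = read_survival_csv(d / "survival.csv")
    fits = pd.read_csv(d / "cox_fits.tsv", sep="\t")
    edges = pd.read_csv(d / "consensus_edges.tsv", sep="\t")
    consensus = net.ConsensusNetwork(
        {(r.parent, r.child): r.frequency for r in edges.itertuples(index=False)},
        cfg["consensus_freq_threshold"],
    )
    labels = clf.derive_outcome_classes(survival, cfg["t_early"], cfg["t_late"])
    # try the configured thresholds first, then relax stepwise (logged):
    # at desk scale the hub list is short and a borderline out-degree or Cox p
    # would otherwise abort the whole run
    mc, p_max = cfg["hub_min_children"], cfg["classifier_p_max"]
    ladder = [(mc, p_max)] + [
        (max(mc - step, 3), min(p_max * 2**step, 0.2)) for step in range(1, 4)
    ]
    candidates = None
    for mc_try, p_try in ladder:
        try:
            candidates = clf.hub_candidate_filter(fits, consensus, mc_try, p_try)
        except DataFormatError:
            continue
        if (mc_try, p_try) != (mc, p_max):
            log.warning(
                "hub candidate filter relaxed to min_children=%d, p_max=%g",
                mc_try, p_try,
            )
        break
    if candidates is None:
        raise DataFormatError(
            "no hub passed the candidate filter even after relaxation"
        )
    features = tumours.values.loc[candidates, labels.index]
    cv = clf.cross_validate(
        features, labels, cfg["delta_grid"],
        seed=syn.stage_seed(manifest.data["seed"], "classifier"),
    )
    pd.DataFrame(
        {"delta": list(cv.errors), "cv_error": list(cv.errors.values())}
    ).to_csv(d / "classifier_path.tsv", sep="\t", index=False)
    with open(d / "classifier_model.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "classes": cv.model.classes,
                "chosen_delta": cv.chosen_delta,
                "selected_genes": cv.selected_genes,
                "per_class_sensitivity": cv.per_class_sensitivity,
                "cv_error": cv.errors[cv.chosen_delta],
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    manifest.record(
        "classify",
        {"path": "classifier_path.tsv", "model": "classifier_model.json"},
        {
            "n_candidates": len(candidates),
            "n_labelled": len(labels),
            "chosen_delta": cv.chosen_delta,
            "n_selected_genes": len(cv.selected_genes),
            "cv_error": cv.errors[cv.chosen_delta],
        },
    )


_STAGE_FNS = {
    "generate": stage_generate,
    "preprocess": stage_preprocess,
    "cluster": stage_cluster,
    "screen": stage_screen,
    "network": stage_network,
    "survive": stage_survive,
    "classify": stage_classify,
}


def run_pipeline(config_path=None, outdir="melnet_run", seed: int | None = None,
                 overrides: dict | None = None) -> RunManifest:
    """Execute all stages in order; abort names the failing stage."""
    overrides = dict(overrides or {})
    if seed is not None:
        overrides["seed"] = int(seed)
    cfg = load_config(config_path, overrides)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(outdir, cfg)
    for stage in STAGES:
        try:
            _STAGE_FNS[stage](manifest)
        except Exception as exc:
            manifest.save()
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return manifest


def report(manifest: RunManifest) -> str:
    """Human-readable summary of a (possibly partial) run."""
    lines = ["melnet run report", "=" * 17, ""]
    d = manifest.outdir
    stages = manifest.data["stages"]
    for stage in STAGES:
        if stage not in stages:
            lines.append(f"[{stage}] MISSING (stage did not complete)")
            continue
        metrics = stages[stage]["metrics"]
        lines.append(
            f"[{stage}] "
            + ", ".join(f"{k}={v}" for k, v in sorted(metrics.items()))
        )
    lines.append("")
    if "preprocess" in stages:
        eff = pd.read_csv(d / "knockdown_efficacy.tsv", sep="\t")
        per_target = (
            eff.groupby("target")["fold_reduction"].median().round(2).reset_index()
        )
        per_target["percent_reduction"] = per_target["fold_reduction"].map(
            prep.percent_from_fold
        )
        lines.append("knockdown efficacy (median per target):")
        lines.append(per_target.to_string(index=False))
        lines.append("")
    if "screen" in stages:
        fr = pd.read_csv(d / "pair_fractions.tsv", sep="\t")
        pivot = fr.pivot_table(
            index="set_name", columns="dataset_label", values="fraction"
        ).round(3)
        lines.append("correlated-pair fractions (|rho| >= threshold):")
        lines.append(pivot.to_string())
        lines.append("")
    if "survive" in stages:
        cat = pd.read_csv(d / "category_survival.tsv", sep="\t")
        lines.append("category survival summary (-log2 p; threshold 4.32 = p 0.05):")
        lines.append(cat.round(3).to_string(index=False))
        lines.append("")
    if "classify" in stages:
        with open(d / "classifier_model.json", encoding="utf-8") as fh:
            model = json.load(fh)
        lines.append(
            "classifier: delta={chosen_delta}, genes={n}, CV error={cv_error:.3f}".format(
                chosen_delta=model["chosen_delta"],
                n=len(model["selected_genes"]),
                cv_error=model["cv_error"],
            )
        )
        lines.append("selected genes: " + ", ".join(model["selected_genes"]))
    missing = [s for s in STAGES if s not in stages]
    if missing:
        lines.append("")
        lines.append("WARNING: incomplete run; missing stages: " + ", ".join(missing))
    return "\n".join(lines) + "\n"
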