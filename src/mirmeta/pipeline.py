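"""End-to-end orchestration: synth -> preprocess -> DE -> meta -> targets ->
enrichment -> network -> survival, from one config and one root seed.

``run_all`` executes every stage in order, optionally persisting every
intermediate as TSV plus a JSON/TSV summary, and returns an in-memory
:class:`RunReport`.  Runs are deterministic given the config seed.  An empty
DEM set (e.g. alpha = 0) short-circuits the downstream stages and still exits
successfully with an explicit note in the summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import diffexpr, enrich, io as mio, meta, network, preprocess, survival, synth, targets
from .config import RunConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and input."""


@dataclass
class RunReport:
    """All intermediates and the machine-readable summary of one run."""

    config: RunConfig
    truth: synth.GroundTruth | None = None
    mirna_de: dict = field(default_factory=dict)
    mrna_de: dict = field(default_factory=dict)
    meta_table: pd.DataFrame | None = None
    dems: list = field(default_factory=list)
    target_map: dict = field(default_factory=dict)
    intersection: targets.IntersectionReport | None = None
    enrichment: pd.DataFrame | None = None
    hubs: pd.DataFrame | None = None
    survival_result: survival.SurvivalResult | None = None
    summary: dict = field(default_factory=dict)


def _persist(outdir: Path | None, name: str, df: pd.DataFrame, index=True) -> None:
    if outdir is not None:
        df.to_csv(outdir / name, sep="\t", index=index)


def run_all(cfg: RunConfig, outdir=None) -> RunReport:
    """Run the full pipeline on synthetic data; see the module docstring."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=cfg)
    summary: dict = {"seed": cfg.seed, "version": __version__}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage '{name}' failed: {exc}") from exc

    # -- synth -------------------------------------------------------------
    mirna_studies, truth = stage("synth-mirna", synth.generate_mirna_studies, cfg.synth)
    mrna_studies = stage("synth-mrna", synth.generate_mrna_studies, cfg.synth, truth)
    interactions = stage("synth-interactions", synth.generate_interactions, truth, cfg.synth)
    report.truth = truth
    if out is not None:
        for s in mirna_studies + mrna_studies:
            s.to_tsv(out / f"{s.study_id}_matrix.tsv", out / f"{s.study_id}_groups.tsv")
        mio.write_interactions(interactions, out / "interactions.tsv")

    # -- preprocess + per-study DE ------------------------------------------
    de_mirna = {}
    for s in mirna_studies:
        if not s.log_scale:
            s = stage("preprocess-log2", preprocess.log2_transform, s)
        if s.n_missing:
            s = stage(
                "preprocess-impute", preprocess.impute_missing, s,
                method=cfg.impute_method, seed=cfg.seed,
            )
        de = stage("diffexpr-mirna", diffexpr.de_workflow, s, alpha=cfg.alpha)
        de_mirna[s.study_id] = de
        _persist(out, f"de_{s.study_id}.tsv", de)
    report.mirna_de = de_mirna

    de_mrna = {}
    for s in mrna_studies:
        de = stage(
            "diffexpr-mrna", diffexpr.de_workflow, s,
            alpha=cfg.alpha, lfc_cut=cfg.lfc_cut,
        )
        de_mrna[s.study_id] = de
        _persist(out, f"de_{s.study_id}.tsv", de)
    report.mrna_de = de_mrna
    summary["degs_per_study"] = {
        sid: int(de["is_de"].sum()) for sid, de in de_mrna.items()
    }

    # -- meta-analysis ------------------------------------------------------
    meta_table = stage(
        "meta", meta.run_meta, de_mirna,
        model=cfg.model, alpha=cfg.alpha, effect=cfg.effect,
    )
    report.meta_table = meta_table
    _persist(out, "meta.tsv", meta_table)
    sig = meta_table[meta_table["significant"]]
    summary["n_dems"] = int(len(sig))
    summary["n_dems_up"] = int((sig["direction"] == "up").sum())
    summary["n_dems_down"] = int((sig["direction"] == "down").sum())

    if sig.empty:
        summary["note"] = "no significant DEMs; downstream stages skipped"
        report.summary = summary
        _write_summary(out, summary)
        return report

    # -- targets -------------------------------------------------------------
    dems = targets.filter_human(sig.index)
    report.dems = dems
    target_map = stage("targets-lookup", targets.lookup_targets, dems, interactions)
    report.target_map = target_map
    deg_lists = {
        sid: set(de.index[de["is_de"]]) for sid, de in de_mrna.items()
    }
    inter = stage("targets-intersect", targets.intersect_targets_with_degs, target_map, deg_lists)
    report.intersection = inter
    _persist(out, "overlap.tsv", inter.to_frame(), index=False)
    summary["n_dem_targets"] = len(inter.dem_targets)
    summary["n_deg_union"] = len(inter.deg_union)
    summary["n_overlap"] = len(inter.overlap)
    summary["venn"] = inter.venn_counts

    if not inter.overlap:
        summary["note"] = "empty target/DEG overlap; downstream stages skipped"
        report.summary = summary
        _write_summary(out, summary)
        return report

    # -- enrichment ----------------------------------------------------------
    genesets = stage("synth-genesets", synth.generate_genesets, cfg.synth, truth)
    collection = enrich.GeneSetCollection(terms=genesets)
    enr = stage(
        "enrich", enrich.hypergeom_enrich, inter.overlap, collection,
        method=cfg.enrich_method, alpha=cfg.alpha,
    )
    enr = stage("enrich-kappa", enrich.kappa_group, enr, collection, threshold=cfg.kappa)
    report.enrichment = enr
    _persist(out, "enrichment.tsv", enr, index=False)
    top = enr.head(5)
    summary["top_terms"] = list(zip(top["term_id"], top["p"].round(6)))
    summary["n_significant_terms"] = int(enr["significant"].sum())

    # -- network -------------------------------------------------------------
    edges = stage("synth-edges", synth.generate_edgelist, cfg.synth, truth)
    net = stage("network-build", network.build_network, edges,
                min_score=cfg.min_score, nodes=sorted(inter.overlap))
    hubs = stage("network-hubs", network.rank_hubs, net, top_n=cfg.top_hubs)
    report.hubs = hubs
    _persist(out, "hubs.tsv", hubs, index=False)
    summary["top_hubs"] = list(zip(hubs["gene"], hubs["degree"].astype(int)))

    # -- survival ------------------------------------------------------------
    surv_table = stage("synth-survival", synth.generate_survival, cfg.synth, truth)
    if out is not None:
        mio.write_survival(surv_table, out / "survival.tsv")
    sres = stage("survival", survival.analyze_gene, surv_table, rule=cfg.split_rule)
    report.survival_result = sres
    summary["survival"] = {
        "gene": truth.hub_gene,
        **{k: (round(v, 6) if isinstance(v, float) else v) for k, v in sres.summary().items()},
    }

    if cfg.make_plots and out is not None:
        from . import plots

        plots.volcano(meta_table, out / "volcano_meta.png", alpha=cfg.alpha)
        plots.km_plot(sres, out / "km_hub.png")

    report.summary = summary
    _write_summary(out, summary)
    return report


def _write_summary(out: Path | None, summary: dict) -> None:
    if out is None:
        return
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    flat = pd.json_normalize(summary, sep=".").T
    flat.columns = ["value"]
    flat.to_csv(out / "summary.tsv", sep="\t")
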