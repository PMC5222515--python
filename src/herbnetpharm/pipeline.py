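"""Pipeline orchestration: association -> screening -> consensus ->
networks -> enrichment -> descriptor comparison.

A single YAML/JSON config document drives the run; each stage writes its
outputs under the output directory and contributes counts to a
:class:`PipelineReport` serialised as JSON and text.  Inputs come either
from files (``inputs`` block) or from the synthetic generators
(``simulate`` block).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import adme_screen, association, descriptor_profiles, enrichment
from . import network_pharm, synthetic_data, target_consensus
from .core_model_io import (
    ConfigurationError,
    CorpusStats,
    load_reference_drugs,
    read_compound_table,
    read_gene_sets,
    read_herb_table,
    read_interaction_table,
    read_target_table,
    write_compound_table,
    write_network,
)

log = logging.getLogger("herbnetpharm")

__all__ = ["PipelineReport", "run_pipeline", "write_report"]


@dataclass
class PipelineReport:
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)
    herbs_total: int = 0
    herbs_selected: int = 0
    compounds_total: int = 0
    candidates: int = 0
    rescued: int = 0
    interactions_scored: int = 0
    interactions_accepted: int = 0
    compounds_dropped: int = 0
    ct_nodes: int = 0
    ct_edges: int = 0
    tp_nodes: int = 0
    tp_edges: int = 0
    multi_pathway_targets: int = 0
    herb_roles: dict[str, str] = field(default_factory=dict)
    top_terms: list[str] = field(default_factory=list)
    descriptor_flags: dict[str, str] = field(default_factory=dict)
    stages_run: list[str] = field(default_factory=list)
    notices: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineReport":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def write_report(report: PipelineReport, path, format: str = "json") -> None:
    """Serialise a report as round-trippable JSON or pipeline-ordered text."""
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    elif format == "text":
        lines = [
            f"seed: {report.seed}",
            f"association: {report.herbs_selected}/{report.herbs_total} herbs selected",
            f"screening: {report.candidates} candidates "
            f"({report.rescued} rescued) of {report.compounds_total} compounds",
            f"consensus: {report.interactions_accepted} of "
            f"{report.interactions_scored} interactions accepted",
            f"ct_network: {report.ct_nodes} nodes, {report.ct_edges} edges, "
            f"{report.compounds_dropped} compounds dropped",
            f"tp_network: {report.tp_nodes} nodes, {report.tp_edges} edges, "
            f"{report.multi_pathway_targets} multi-pathway targets",
            f"enrichment: top terms {', '.join(report.top_terms) or '(none)'}",
            f"descriptors: " + (
                ", ".join(f"{k}={v}" for k, v in report.descriptor_flags.items())
                or "(not compared)"
            ),
        ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ConfigurationError(f"unknown report format: {format!r}")


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    with open(config, encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ConfigurationError(f"{config}: config must be a mapping")
    return loaded


def run_pipeline(config, outdir, seed: Optional[int] = None) -> PipelineReport:
    """Execute all stages in order and write outputs under ``outdir``.

    ``config`` is a path to a YAML/JSON document or an equivalent dict
    with optional blocks: ``simulate`` or ``inputs``, plus per-stage
    ``association``, ``screen``, ``consensus``, ``enrichment``,
    ``network`` and ``descriptors`` blocks.  ``seed`` overrides the
    config seed for all synthetic draws.
    """
    cfg = _load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config=cfg)
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        report.stages_run.append(stage)
        report.timings[stage] = round(time.perf_counter() - t0, 4)

    # ----- inputs -------------------------------------------------------
    sim_cfg = None
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        if seed is not None:
            sim_kwargs["seed"] = seed
        if "tiers" in sim_kwargs:
            sim_kwargs["tiers"] = tuple(
                tuple(t) for t in sim_kwargs["tiers"]
            )
        sim_cfg = synthetic_data.SimConfig(**sim_kwargs)
        report.seed = sim_cfg.seed
        compounds = synthetic_data.gen_compound_table(sim_cfg)
        target_ids = sim_cfg.target_ids()
        scores = synthetic_data.gen_interaction_scores(sim_cfg, compounds, target_ids)
        corpus, herbs = synthetic_data.gen_corpus_counts(sim_cfg)
        gene_sets = synthetic_data.gen_gene_sets(sim_cfg, target_ids)
    elif "inputs" in cfg:
        inp = cfg["inputs"]
        report.seed = seed
        compounds = read_compound_table(inp["compounds"])
        herbs = read_herb_table(inp["herbs"]) if "herbs" in inp else []
        corpus = CorpusStats(
            n_corpus=int(inp.get("corpus_n", CorpusStats().n_corpus)),
            k_disease_corpus=int(inp.get("corpus_k", CorpusStats().k_disease_corpus)),
        )
        scores = (read_interaction_table(inp["interactions"])
                  if "interactions" in inp else [])
        target_ids = ([t.target_id for t in read_target_table(inp["targets"])]
                      if "targets" in inp else [])
        gene_sets = (read_gene_sets(inp["gene_sets"])
                     if "gene_sets" in inp else None)
    else:
        raise ConfigurationError("config needs an 'inputs' or 'simulate' block")

    report.compounds_total = len(compounds)
    report.herbs_total = len(herbs)

    # ----- stage 1: herb-disease association ----------------------------
    assoc_cfg = cfg.get("association", {})
    alpha = float(assoc_cfg.get("alpha", 0.01))
    assoc = association.herb_association(corpus, herbs, alpha=alpha)
    selected_herbs = {a.herb_id for a in assoc if a.selected}
    report.herbs_selected = len(selected_herbs)
    with open(outdir / "association.tsv", "w", encoding="utf-8") as fh:
        fh.write("herb_id\tp_value\texpected_k\tenrichment_ratio\tselected\n")
        for a in assoc:
            fh.write(f"{a.herb_id}\t{a.p_value:.6g}\t{a.expected_k:.4f}\t"
                     f"{a.enrichment_ratio:.4f}\t{str(a.selected).lower()}\n")
    log.info("association: %d/%d herbs selected at alpha=%g",
             len(selected_herbs), len(herbs), alpha)
    tick("association")
    if herbs and not selected_herbs:
        report.notices.append(
            "no herb passed the association screen; downstream stages skipped"
        )
        log.info("%s", report.notices[-1])
        return _finalise(report, outdir)
    if herbs:
        compounds = [c for c in compounds if c.herb_id in selected_herbs]

    # ----- stage 2: OB/DL screening -------------------------------------
    screen_cfg = cfg.get("screen", {})
    scfg = adme_screen.ScreenConfig(
        ob_min=float(screen_cfg.get("ob_min", 30.0)),
        dl_min=float(screen_cfg.get("dl_min", 0.18)),
        rescue_ids=frozenset(screen_cfg.get("rescue_ids", [])
                             or [c.compound_id for c in compounds if c.rescued]),
    )
    screened = adme_screen.apply_ob_dl_filter(compounds, scfg)
    report.candidates = len(screened.candidates)
    report.rescued = screened.n_rescued
    write_compound_table(screened.candidates, outdir / "candidates.tsv")
    log.info("screening: %d candidates (%d rescued) of %d compounds",
             report.candidates, report.rescued, len(compounds))
    tick("screening")

    # ----- stage 3: consensus target acceptance -------------------------
    cons_cfg = cfg.get("consensus", {})
    ccfg = target_consensus.ConsensusConfig(
        rf_min=float(cons_cfg.get("rf_min", 0.8)),
        svm_min=float(cons_cfg.get("svm_min", 0.7)),
        target_whitelist=(frozenset(cons_cfg["target_whitelist"])
                          if "target_whitelist" in cons_cfg else None),
    )
    cand_ids = {c.compound_id for c in screened.candidates}
    scores_for_candidates = [s for s in scores if s.compound_id in cand_ids]
    accepted = target_consensus.consensus_filter(scores_for_candidates, ccfg)
    report.interactions_scored = len(scores_for_candidates)
    report.interactions_accepted = len(accepted)
    log.info("consensus: %d of %d interactions accepted",
             len(accepted), len(scores_for_candidates))
    tick("consensus")

    # ----- stage 4: networks, degrees, herb roles -----------------------
    net_cfg = cfg.get("network", {})
    ct, dropped = network_pharm.build_ct_network(screened.candidates, accepted)
    report.compounds_dropped = len(dropped)
    ct_sum = network_pharm.network_summary(ct)
    report.ct_nodes, report.ct_edges = ct_sum.n_nodes, ct_sum.n_edges
    write_network(ct, outdir / "ct_network.sif", "sif")
    write_network(ct, outdir / "ct_network.graphml", "graphml")
    aggs = network_pharm.herb_aggregates(
        ct, all_herbs={c.herb_id for c in screened.candidates}
    )
    roles = network_pharm.classify_roles(
        aggs, chen_fraction=float(net_cfg.get("chen_fraction", 0.35))
    )
    report.herb_roles = {r.herb_id: r.role for r in roles}
    with open(outdir / "herb_aggregates.tsv", "w", encoding="utf-8") as fh:
        fh.write("herb_id\tn_active_compounds\ttotal_degree\t"
                 "mean_targets_per_compound\trole\trank\n")
        role_by_herb = {r.herb_id: r for r in roles}
        for a in sorted(aggs, key=lambda a: role_by_herb[a.herb_id].rank):
            r = role_by_herb[a.herb_id]
            fh.write(f"{a.herb_id}\t{a.n_active_compounds}\t{a.total_degree}\t"
                     f"{a.mean_targets_per_compound:.4f}\t{r.role}\t{r.rank}\n")
    targets_in_net = sorted(ct.right_nodes)
    if gene_sets is not None:
        tp, multi = network_pharm.build_tp_network(targets_in_net, gene_sets)
        tp_sum = network_pharm.network_summary(tp)
        report.tp_nodes, report.tp_edges = tp_sum.n_nodes, tp_sum.n_edges
        report.multi_pathway_targets = multi
        write_network(tp, outdir / "tp_network.sif", "sif")
    log.info("networks: C-T %d nodes / %d edges (%d compounds dropped)",
             report.ct_nodes, report.ct_edges, report.compounds_dropped)
    tick("networks")

    # ----- stage 5: over-representation analysis ------------------------
    enr_cfg = cfg.get("enrichment", {})
    if gene_sets is not None and targets_in_net:
        uni = gene_sets.effective_universe() | set(targets_in_net)
        results = enrichment.ora(
            set(targets_in_net),
            gene_sets,
            universe=uni,
            alpha=float(enr_cfg.get("alpha", 0.05)),
            variant=enr_cfg.get("variant", "standard"),
        )
        top = enrichment.top_terms(results, int(enr_cfg.get("top", 20)))
        report.top_terms = [r.term_id for r in top]
        with open(outdir / "enrichment.tsv", "w", encoding="utf-8") as fh:
            fh.write("rank\tterm_id\tterm_name\tk_overlap\tK_term\t"
                     "n_selected\tN_universe\tp_raw\tp_adjusted\n")
            for r in results:
                fh.write(f"{r.rank}\t{r.term_id}\t{r.term_name}\t{r.k_overlap}\t"
                         f"{r.K_term}\t{r.n_selected}\t{r.N_universe}\t"
                         f"{r.p_raw:.6g}\t{r.p_adjusted:.6g}\n")
        log.info("enrichment: %d significant terms", len(results))
    tick("enrichment")

    # ----- stage 6: descriptor group comparison -------------------------
    desc_cfg = cfg.get("descriptors", {})
    cand_desc = [c.descriptors for c in screened.candidates
                 if c.descriptors is not None]
    if len(cand_desc) >= 2:
        if sim_cfg is not None:
            ref = synthetic_data.gen_reference_descriptors(sim_cfg)
        else:
            ref = load_reference_drugs().to_numpy()
        comp = descriptor_profiles.compare_groups(
            cand_desc, list(ref), test=desc_cfg.get("test", "welch")
        )
        report.descriptor_flags = dict(comp.flag)
        descriptor_profiles.summary_frame(
            comp, "candidates", "reference"
        ).to_csv(outdir / "descriptor_comparison.tsv", sep="\t", index=False)
    tick("descriptors")

    return _finalise(report, outdir)


def _finalise(report: PipelineReport, outdir: Path) -> PipelineReport:
    write_report(report, outdir / "report.json", "json")
    write_report(report, outdir / "report.txt", "text")
    return report
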