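"""End-to-end orchestration: simulate -> call -> annotate -> motif/ARE -> stability -> nascent."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .editcall import EditCallConfig, call_edits, intersect_replicates, write_bedgraph
from .motif_are import AREScoreParams, extract_edit_windows, gene_are_scores, kmer_enrichment
from .nascent import build_intron_annotation, nascent_class_fractions
from .refmodel import GeneModelIndex
from .regionmap import annotate_edits, region_fractions
from .stability import are_vs_change, bootstrap_class_fractions, classify_de, stability_contingency
from .synthetic_data import CountSimConfig, SimConfig, simulate_counts, simulate_reference, simulate_tribe_pileups

log = logging.getLogger(__name__)


def _config_hash(obj) -> str:
    return hashlib.md5(repr(obj).encode()).hexdigest()[:10]


def _header(seed, cfg) -> str:
    return f"editscope v{__version__} config={_config_hash(cfg)} seed={seed}"


def _write_tsv(df: pd.DataFrame, path, seed, cfg) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header(seed, cfg)}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_tribe(
    genome, models, pileups: dict[str, pd.DataFrame], call_cfg: EditCallConfig,
    outdir, flank: int = 100, k: int = 8, n_shuffles: int = 100, seed: int = 0,
    control_sample: str = "control",
) -> dict:
    """Edit calling, replicate intersection, region/metagene summary, motif report.

    ``pileups`` maps sample id -> SiteCount table and must include the
    control sample. Outputs per-replicate bedGraphs, the common-edit
    (heatmap) table, a region-summary JSON, and the k-mer enrichment table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if control_sample not in pileups:
        raise ValueError(f"a control sample named {control_sample!r} is required")
    ctrl = pileups[control_sample]
    rep_names = [s for s in pileups if s != control_sample]
    if not rep_names:
        raise ValueError("at least one experiment replicate is required")

    index = GeneModelIndex(models)
    per_rep = []
    funnel = {}
    for name in rep_names:
        res = call_edits(pileups[name], ctrl, call_cfg)
        funnel[name] = {
            "exp_pass": res.n_exp_pass,
            "no_control": res.n_no_control,
            "control_edited": res.n_control_edited,
            "called": len(res.sites),
        }
        log.info("replicate %s: %s", name, funnel[name])
        write_bedgraph(res.sites, outdir / f"edits_{name}.bedgraph", header=_header(seed, call_cfg))
        per_rep.append(res.sites)

    common = intersect_replicates(per_rep)
    heat_cols = ["contig", "pos0", "strand"] + [c for c in common.columns if c.startswith("frac_")]
    heat = common[heat_cols].copy()
    for c in heat.columns:
        if c.startswith("frac_"):
            heat[c] = 100 * heat[c]
    _write_tsv(heat, outdir / "common_edits.tsv", seed, call_cfg)

    annots = annotate_edits(common, index)
    _write_tsv(annots, outdir / "edit_annotations.tsv", seed, call_cfg)
    summary = region_fractions(annots) if len(annots) else None

    enrichment = None
    if len(annots) >= 5:
        windows = extract_edit_windows(annots, index, genome, flank=flank)
        try:
            enrichment = kmer_enrichment(windows, k=k, n_shuffles=n_shuffles, seed=seed)
            _write_tsv(enrichment, outdir / "kmer_enrichment.tsv", seed, call_cfg)
        except ValueError as e:
            log.warning("k-mer enrichment skipped: %s", e)

    report = {
        "header": _header(seed, call_cfg),
        "funnel": funnel,
        "n_common_edits": len(common),
        "region_fractions": summary.fractions if summary else None,
        "other_region_counts": summary.other_counts if summary else None,
        "single_site_gene_count": summary.single_site_gene_count if summary else None,
    }
    with open(outdir / "tribe_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return {
        "common": common, "annotations": annots, "summary": summary,
        "enrichment": enrichment, "funnel": funnel, "report": report,
    }


def run_stability(
    exon_counts: pd.DataFrame, labels: list[str], targets, outdir,
    intron_counts: pd.DataFrame | None = None, are_scores: dict | None = None,
    alpha: float = 0.05, n_boot: int = 1000, seed: int = 0, **classify_kwargs,
) -> dict:
    """Differential classification plus target-stratified stability statistics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    targets = list(targets)
    if not targets:
        raise ValueError("targets file/list is required and empty")
    if len(labels) != exon_counts.shape[1]:
        raise ValueError("design labels do not match count-matrix columns")

    de = classify_de(exon_counts, labels, alpha=alpha, seed=seed, **classify_kwargs)
    _write_tsv(de.reset_index(drop=True), outdir / "de_table.tsv", seed, (alpha, n_boot))

    rep = stability_contingency(de, targets)
    boot = bootstrap_class_fractions(de, targets, n_boot=n_boot, seed=seed)
    rep.bootstrap_ci = boot["ci"]
    rep.combined_p = boot["combined_p"]
    rep.n_boot = n_boot
    rep.seed = seed

    are = None
    if are_scores:
        try:
            are = are_vs_change(are_scores, de, targets)
        except ValueError as e:
            log.warning("ARE stratification skipped: %s", e)

    nascent = None
    if intron_counts is not None:
        try:
            nascent = nascent_class_fractions(intron_counts, labels, targets, alpha=alpha, seed=seed)
        except ValueError as e:
            log.warning("nascent analysis skipped: %s", e)

    report = {
        "header": _header(seed, (alpha, n_boot)),
        "contingency": {c: rep.contingency.loc[c].to_dict() for c in rep.contingency.index},
        "chi2": rep.chi2,
        "chi2_p": rep.chi2_p,
        "low_expected_cells": rep.low_expected,
        "target_fractions": rep.target_fractions,
        "background_fractions": rep.background_fractions,
        "bootstrap_ci": rep.bootstrap_ci,
        "fisher_combined_p": rep.combined_p,
        "are": asdict(are) if are else None,
        "nascent": {"fractions": nascent["fractions"], "n_targets": nascent["n_targets"]} if nascent else None,
        "seed": seed,
    }
    with open(outdir / "stability_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return {"de": de, "stability": rep, "bootstrap": boot, "are": are, "nascent": nascent, "report": report}


def run_all(
    sim_cfg: SimConfig, count_cfg: CountSimConfig, outdir,
    call_cfg: EditCallConfig | None = None, are_params: AREScoreParams | None = None,
    alpha: float = 0.05, n_boot: int = 1000,
) -> dict:
    """Full synthetic end-to-end run; seeds come from the two sim configs."""
    outdir = Path(outdir)
    call_cfg = call_cfg or EditCallConfig()
    genome, models, truth = simulate_reference(sim_cfg)
    pileups = simulate_tribe_pileups(genome, models, truth, sim_cfg)
    tribe = run_tribe(
        genome, models, pileups, call_cfg, outdir / "tribe", seed=sim_cfg.seed
    )

    called_targets = sorted(set(tribe["annotations"]["gene_id"]) - {""})
    exo, intr, labels = simulate_counts(
        [t.gene_id for t in models], truth.target_genes, count_cfg, truth
    )
    scores = gene_are_scores(models, genome, are_params)
    stab = run_stability(
        exo, labels, called_targets or truth.target_genes, outdir / "stability",
        intron_counts=intr, are_scores=scores, alpha=alpha, n_boot=n_boot,
        seed=count_cfg.seed,
    )
    return {"genome": genome, "models": models, "truth": truth, "tribe": tribe, "stability": stab}
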