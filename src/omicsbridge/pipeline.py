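"""End-to-end orchestration: simulate -> proteome -> transcriptome ->
integrate -> qPCR, with every intermediate table written to disk, a JSON
run manifest (seed, parameter echo, row counts, content hashes) and a
human-readable summary.  Reruns with the same configuration produce
byte-identical tables and manifests."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import pandas as pd

from . import __version__
from .config import LIBRARIES, REFERENCE_GENE, PipelineConfig
from .integrate import (canonical_gene_id, correlation_ladder, go_category_tally,
                        ladder_pairs, overlap_deps_degs)
from .proteome import (call_deps, quantify_proteins, replicate_reproducibility,
                       threshold_from_quant)
from .qpcr import concordance, delta_delta_ct
from .simulate import simulate_dataset
from .tables import write_table
from .transcriptome import (deg_analysis, replicate_correlation,
                            saturation_curve, summarize_mapping, tpm_normalize)

logger = logging.getLogger("omicsbridge")


def _configure_logging(verbose: bool = False) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


def _log(stage: str, message: str) -> None:
    logger.info(message, extra={"stage": stage})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, out_dir: str | Path,
            go_map: pd.DataFrame | None = None, verbose: bool = False) -> dict:
    """Execute the full pipeline and return the run manifest."""
    _configure_logging(verbose)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, schema: str | None = None) -> None:
        written[name] = write_table(df, out / f"{name}.tsv", schema)

    # ---- simulate -------------------------------------------------------
    _log("simulate", f"generating dataset (n_genes={config.simulation.n_genes}, "
         f"seed={config.seed})")
    data = simulate_dataset(config.simulation)
    if go_map is None:
        go_map = data["go_map"]
    emit("truth", data["truth"], "truth")
    emit("peptides", data["peptides"], "peptides")
    emit("tags", data["tags"], "tags")
    emit("mapping_summary", data["mapping"], "mapping_summary")
    emit("qpcr", data["qpcr"], "qpcr")
    emit("go_map", go_map, "go_map")

    # ---- proteome -------------------------------------------------------
    prot = config.proteome
    _log("proteome", f"quantifying proteins (min_score={prot.min_score}, "
         f"min_unique_peptides={prot.min_unique_peptides})")
    quant, pep_report = quantify_proteins(
        data["peptides"], min_score=prot.min_score,
        min_unique_peptides=prot.min_unique_peptides)
    thr_report = threshold_from_quant(
        quant, level=prot.quantile, min_threshold=prot.min_threshold,
        round_up_to=prot.round_up_to)
    threshold = (thr_report.chosen_threshold if prot.threshold == "auto"
                 else float(prot.threshold))
    _log("proteome", f"fold-change threshold = {threshold:.4f} "
         f"({'auto @ q' + format(prot.quantile, 'g') if prot.threshold == 'auto' else 'fixed'})")
    dep_calls, dep_counts = call_deps(
        quant, threshold, alpha=prot.alpha,
        min_unique_peptides=prot.min_unique_peptides)
    prot_rep = replicate_reproducibility(quant)
    emit("protein_quant", quant, "protein_quant")
    emit("threshold_report", thr_report.table, "threshold_report")
    emit("dep_calls",
         dep_calls[["protein_id", "ratio_rep1", "ratio_rep2", "p_value",
                    "n_unique_peptides", "call"]], "dep_calls")
    _log("proteome", f"DEPs: {dep_counts['up']} up, {dep_counts['down']} down")

    # ---- transcriptome --------------------------------------------------
    trans = config.transcriptome
    _log("transcriptome", "normalizing tag counts to TPM")
    mapping_pct = summarize_mapping(data["mapping"])
    denoms = dict(zip(data["mapping"]["library"], data["mapping"]["to_gene"]))
    tpm = tpm_normalize(data["tags"], denominators=denoms)
    deg = deg_analysis(tpm, q_min=trans.q_min, m_min=trans.m_min,
                       pseudocount=trans.pseudocount)
    mrna_rep = replicate_correlation(tpm, pseudocount=trans.pseudocount)
    deg_counts = deg["call"].value_counts().to_dict()
    _log("transcriptome", f"DEGs: {deg_counts.get('up', 0)} up, "
         f"{deg_counts.get('down', 0)} down")
    emit("tpm", tpm, "tpm")
    emit("deg_results", deg, "deg_results")
    if not config.simulation.exact_counts:
        curves = []
        for lib in LIBRARIES:
            c = saturation_curve(data["tags"], lib, seed=config.seed,
                                 steps=trans.saturation_steps)
            c.insert(0, "library", lib)
            curves.append(c)
        emit("saturation", pd.concat(curves, ignore_index=True), "saturation")

    # ---- integrate ------------------------------------------------------
    integ = config.integration
    _log("integrate", "computing DEP/DEG overlap and correlation ladder")
    ladder = correlation_ladder(quant, deg, dep_calls,
                                relaxed_mrna_log2=integ.relaxed_mrna_log2,
                                method=integ.correlation)
    n_overlap, overlap_ids = overlap_deps_degs(dep_calls, deg)
    emit("correlation_ladder", ladder, "correlation_ladder")
    emit("ladder_pairs", ladder_pairs(quant, deg), "ladder_pairs")
    emit("overlap", pd.DataFrame({"gene_id": overlap_ids}), "overlap")
    dep_ids = [canonical_gene_id(p) for p, c in
               zip(dep_calls["protein_id"], dep_calls["call"]) if c != "none"]
    tallies = []
    for ontology in sorted(go_map["ontology"].unique()):
        tally, _ = go_category_tally(dep_ids, go_map, ontology)
        tally.insert(0, "ontology", ontology)
        tallies.append(tally)
    if tallies:
        emit("go_tally", pd.concat(tallies, ignore_index=True), "go_tally")

    # ---- qPCR -----------------------------------------------------------
    _log("qpcr", "relative quantification and concordance")
    rq = delta_delta_ct(data["qpcr"])
    panel = [g for g in rq["gene_id"] if g != REFERENCE_GENE]
    conc = concordance(rq, deg, panel)
    emit("rq", rq, "rq")
    emit("concordance", conc["table"], "concordance")
    _log("qpcr", f"concordance: {conc['concordant']}/{conc['total']}")

    # ---- manifest & summary --------------------------------------------
    ladder_r = {row["level"]: (None if pd.isna(row["r"]) else round(row["r"], 6))
                for _, row in ladder.iterrows()}
    summary = {
        "peptides": pep_report,
        "threshold": round(threshold, 6),
        "deps": dep_counts,
        "degs": {k: int(deg_counts.get(k, 0)) for k in ("up", "down", "none")},
        "overlap_stringent": n_overlap,
        "ladder_r": ladder_r,
        "replicate_r": {"protein": {k: round(v, 6) for k, v in prot_rep.items()},
                        "mrna": {k: round(v, 6) for k, v in mrna_rep.items()}},
        "qpcr_concordance": {"concordant": conc["concordant"],
                             "total": conc["total"]},
    }
    manifest = {
        "package": "omicsbridge",
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "tables": {name: {"rows": sum(1 for _ in open(path)) - 1,
                          "sha256": _sha256(path)}
                   for name, path in sorted(written.items())},
        "summary": summary,
        "mapping_percentages": mapping_pct.to_dict(orient="records"),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    lines = [
        f"omicsbridge {__version__} run (seed {config.seed})",
        f"peptides retained/dropped: {pep_report['retained']}/{pep_report['dropped']}",
        f"proteins quantified: {pep_report['quantifiable']}/{pep_report['proteins']}",
        f"fold-change threshold: {threshold:.4f}",
        f"DEPs: {dep_counts['up']} up / {dep_counts['down']} down",
        f"DEGs: {deg_counts.get('up', 0)} up / {deg_counts.get('down', 0)} down",
        f"stringent DEP/DEG overlap: {n_overlap}",
        "ladder r: " + ", ".join(f"{k}={v}" for k, v in ladder_r.items()),
        f"qPCR concordance: {conc['concordant']}/{conc['total']}",
    ]
    (out / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return manifest
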