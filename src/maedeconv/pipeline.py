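"""End-to-end workflow: filter -> condense -> classify -> index -> cluster
-> nodes -> align -> logo -> deconvolute, with every intermediate written
to a run directory so stages can also be run (and re-loaded) separately."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import (
    abundance_indices,
    clustering,
    consensus_logo,
    deconvolution,
    epitope_assembly,
    io_tables,
)
from . import node_alignment as na
from .deconvolution import CLASS_I_LOCI

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "peptides": None,            # path to peptide TSV
    "genotypes": None,           # path to genotype TSV (optional)
    "dialect": "default",
    "replicate_filter": True,    # apply the >= min_reps of total_reps rule
    "min_reps": 2,
    "total_reps": 3,
    "short_max_len": 8,          # reject peptides of <= this many residues
    "condense_mode": "auto",     # coordinates when available, else string
    "min_overlap": 5,            # string-mode suffix/prefix overlap minimum
    "min_total_count": 3,
    "mhc1_range": (9, 11),
    "mhc2_range": (12, 20),
    "mhc2_min_constituents": 3,
    "metric": "correlation",
    "node_min_size": 9,
    "node_max_size": 100,
    "mhc1_max_align": 12,
    "mhc2_max_align": 30,
    "substitution_matrix": "BLOSUM62",
    "bootstrap_reps": 200,
    "logo_seed": 0,
    "max_mismatch": 0,
    "ei_floor": 0.0,
    "consensus_style": "full",
}


def resolve_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    """Merge user config over defaults; unknown keys are rejected."""
    resolved = dict(DEFAULTS)
    if config:
        unknown = set(config) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        resolved.update(config)
    for key in ("mhc1_range", "mhc2_range"):
        resolved[key] = tuple(resolved[key])
    return resolved


def run_pipeline(
    config: Mapping[str, Any], outdir: str | Path
) -> dict[str, Any]:
    """Execute the full workflow and return a machine-readable summary.

    Every stage writes its artifact under ``outdir``; any stage failure is
    re-raised with the stage name attached.
    """
    cfg = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(cfg, indent=2, default=str) + "\n"
    )
    logger.info("resolved config: %s", cfg)
    summary: dict[str, Any] = {}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # --- identification-level filtering -------------------------------
    s = stage("filter")
    try:
        if cfg["peptides"] is None:
            raise ValueError("config key 'peptides' (input table path) is required")
        records = io_tables.read_peptide_table(cfg["peptides"], cfg["dialect"])
        summary["n_input_records"] = len(records)
        if cfg["replicate_filter"]:
            records = io_tables.replicate_consistency_filter(
                records, cfg["min_reps"], cfg["total_reps"]
            )
        records = epitope_assembly.drop_short_peptides(records, cfg["short_max_len"])
        summary["n_filtered_records"] = len(records)
        io_tables.write_peptide_table(records, outdir / "peptides_filtered.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage {s!r} failed: {exc}") from exc

    # --- condensation and classification ------------------------------
    s = stage("condense")
    try:
        mode = cfg["condense_mode"]
        if mode == "auto":
            mode = (
                "coordinates"
                if records and all(r.has_coordinates for r in records)
                else "string"
            )
        epitopes = epitope_assembly.condense_peptides(
            records, mode=mode, min_overlap=cfg["min_overlap"]
        )
        summary["condense_mode"] = mode
        summary["n_epitopes"] = len(epitopes)
    except Exception as exc:
        raise RuntimeError(f"stage {s!r} failed: {exc}") from exc

    s = stage("classify")
    try:
        epitopes = epitope_assembly.classify_epitopes(
            epitopes,
            min_total_count=cfg["min_total_count"],
            mhc1_range=cfg["mhc1_range"],
            mhc2_range=cfg["mhc2_range"],
            mhc2_min_constituents=cfg["mhc2_min_constituents"],
        )
        epitope_assembly.write_epitope_table(epitopes, outdir / "epitopes.tsv")
        members = [
            {"epitope_id": e.epitope_id, "sequence": r.sequence,
             "cell_line": r.cell_line, "replicate": r.replicate,
             "spectral_count": r.spectral_count}
            for e in epitopes for r in e.constituents
        ]
        pd.DataFrame(members).to_csv(
            outdir / "epitope_members.tsv", sep="\t", index=False
        )
        by_class = {
            c: [e for e in epitopes if e.mhc_class == c] for c in ("I", "II")
        }
        summary["n_mhc1_epitopes"] = len(by_class["I"])
        summary["n_mhc2_epitopes"] = len(by_class["II"])
        summary["n_rejected_epitopes"] = sum(
            1 for e in epitopes if e.mhc_class == "rejected"
        )
    except Exception as exc:
        raise RuntimeError(f"stage {s!r} failed: {exc}") from exc

    # --- abundance indices --------------------------------------------
    s = stage("index")
    try:
        genotypes = (
            deconvolution.read_genotype_table(cfg["genotypes"])
            if cfg["genotypes"]
            else None
        )
        if genotypes is not None:
            cell_lines = [g.cell_line for g in genotypes]
        else:
            cell_lines = sorted({r.cell_line for r in records})
        pi_maps = abundance_indices.peptide_index_all(
            records, cell_lines, cfg["total_reps"]
        )
        matrices = {
            c: abundance_indices.epitope_index_matrix(
                by_class[c], pi_maps, cell_lines
            )
            for c in ("I", "II")
            if by_class[c]
        }
        for c, m in matrices.items():
            m.write_tsv(outdir / f"ei_matrix_mhc{c}.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage {s!r} failed: {exc}") from exc

    # --- clustering and node extraction --------------------------------
    s = stage("cluster")
    nodes_by_class: dict[str, list[clustering.EpitopeNode]] = {}
    trees: dict[str, clustering.Dendrogram] = {}
    try:
        for c, m in matrices.items():
            if len(m.epitope_ids) < 2:
                logger.warning("class %s has < 2 epitopes; skipping clustering", c)
                continue
            tree = clustering.cluster_matrix(m, axis="epitopes", metric=cfg["metric"])
            trees[c] = tree
            (outdir / f"epitopes_mhc{c}.nwk").write_text(tree.to_newick() + "\n")
            if len(m.cell_lines) >= 2:
                line_tree = clustering.cluster_matrix(
                    m, axis="cell_lines", metric=cfg["metric"]
                )
                (outdir / f"cell_lines_mhc{c}.nwk").write_text(
                    line_tree.to_newick() + "\n"
                )
            nodes = clustering.extract_nodes(
                tree, m, cfg["node_min_size"], cfg["node_max_size"]
            )
            nodes_by_class[c] = nodes
            clustering.write_node_members(nodes, outdir / f"nodes_mhc{c}.tsv")
            summary[f"n_mhc{c}_nodes"] = len(nodes)
    except Exception as exc:
        raise RuntimeError(f"stage {s!r} failed: {exc}") from exc

    # --- alignment and consensus logos ---------------------------------
    s = stage("align/logo")
    try:
        consensus: dict[str, consensus_logo.ConsensusLine] = {}
        seq_of = {e.epitope_id: e.sequence for e in epitopes}
        for c, nodes in nodes_by_class.items():
            m = matrices[c]
            max_len = cfg["mhc1_max_align"] if c == "I" else cfg["mhc2_max_align"]
            for node in nodes:
                members = sorted(node.member_epitopes)
                seqs = [seq_of[e] for e in members]
                weights = [float(m.row(e).sum()) for e in members]
                aln = na.align_node(
                    seqs, max_len=max_len,
                    matrix=cfg["substitution_matrix"],
                    weights=weights, node_id=node.node_id,
                )
                na.write_fasta_alignment(
                    aln, outdir / f"aln_mhc{c}_{node.node_id}.afa", names=members
                )
                cols = consensus_logo.score_alignment(
                    aln, bootstrap_reps=cfg["bootstrap_reps"], seed=cfg["logo_seed"]
                )
                consensus[f"mhc{c}:{node.node_id}"] = consensus_logo.render_consensus(
                    cols, style=cfg["consensus_style"]
                )
        consensus_logo.write_consensus_lines(consensus, outdir / "consensus.txt")
        summary["n_consensus_lines"] = len(consensus)
    except Exception as exc:
        raise RuntimeError(f"stage {s!r} failed: {exc}") from exc

    # --- deconvolution --------------------------------------------------
    s = stage("deconvolute")
    try:
        if genotypes is not None:
            loci = sorted({l for g in genotypes for l in g.alleles})
            loci_by_class = {
                "I": [l for l in loci if l in CLASS_I_LOCI],
                "II": [l for l in loci if l not in CLASS_I_LOCI],
            }
            for c, m in matrices.items():
                use = loci_by_class[c] or loci
                profiles = deconvolution.theoretical_profiles(genotypes, loci=use)
                table = deconvolution.assignment_table(
                    m, profiles,
                    max_mismatch=cfg["max_mismatch"], floor=cfg["ei_floor"],
                )
                table.to_csv(
                    outdir / f"assignments_mhc{c}.tsv", sep="\t", index=False
                )
                summary[f"n_mhc{c}_assigned"] = int(
                    (table["n_candidates"] > 0).sum()
                )
            trace = deconvolution.traceability_by_panel_size(genotypes)
            trace.to_csv(outdir / "traceability.tsv", sep="\t", index=False)
            trace_locus = deconvolution.traceability_by_panel_size(
                genotypes, per_locus=True
            )
            trace_locus.to_csv(
                outdir / "traceability_per_locus.tsv", sep="\t", index=False
            )
            summary["n_traceable_alleles"] = int(trace["n_traceable"].iloc[-1])
            summary["n_traceable_alleles_per_locus"] = int(
                trace_locus["n_traceable"].iloc[-1]
            )
    except Exception as exc:
        raise RuntimeError(f"stage {s!r} failed: {exc}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
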