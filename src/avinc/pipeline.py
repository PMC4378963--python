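"""End-to-end orchestration of the annotation pipeline.

``run_all`` composes the stages exactly as running them one by one:
per-genome consolidation, copy-number matrix + conservation filter, absence
report, microchromosome enrichment, synteny report, expression validation.
Every threshold, seed and stage count is echoed into a plain-text manifest so
a run is reproducible from its outputs; identical inputs give identical
outputs (no timestamps).
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from . import __version__, formats_io
from .consolidate import compete_clans, collapse_overlaps, filter_hits
from .conservation import (
    ConservationConfig,
    absence_report,
    build_matrix,
    export_heatmap,
    filter_conserved,
    flag_missing,
    microchromosome_enrichment,
)
from .expression import (
    call_expression,
    count_reads,
    sample_null_regions,
    select_threshold,
    summarize,
)
from .model import AvincError, FilterConfig
from .synteny import read_domain_specs, synteny_report

log = logging.getLogger("avinc")


@dataclass
class GenomeInputs:
    genome_id: str
    tblout: str
    lengths: Optional[str] = None
    trnascan: Optional[str] = None


@dataclass
class PipelineConfig:
    """File paths and thresholds for one pipeline run."""

    genomes: List[GenomeInputs]
    families: str
    out_dir: str
    reference_genome: Optional[str] = None   # defaults to the first genome
    chrom_classes: Optional[str] = None
    reads: Optional[str] = None              # BED6 for the reference genome
    synteny_specs: Optional[str] = None
    evalue_max: float = 5e-4
    apply_ga: bool = True
    min_genome_fraction: float = 0.10
    missing_absent_fraction: float = 0.5
    target_fpr: float = 0.10
    n_null: int = 10000
    strand_aware: bool = True
    seed: int = 17
    max_span: int = 1_000_000

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        genomes = [GenomeInputs(**g) for g in raw.pop("genomes", [])]
        return cls(genomes=genomes, **raw)


def run_all(config: PipelineConfig) -> Dict[str, object]:
    """Run every stage; returns a result dict and writes the report bundle."""
    if not config.genomes:
        raise AvincError("no genomes configured")
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: Dict[str, object] = {
        "version": __version__,
        "thresholds": {
            "evalue_max": config.evalue_max,
            "apply_ga": config.apply_ga,
            "min_genome_fraction": config.min_genome_fraction,
            "missing_absent_fraction": config.missing_absent_fraction,
            "target_fpr": config.target_fpr,
            "n_null": config.n_null,
            "strand_aware": config.strand_aware,
            "max_span": config.max_span,
        },
        "seed": config.seed,
        "stages": {},
    }
    results: Dict[str, object] = {"manifest": manifest}

    family_meta = formats_io.read_family_metadata(config.families)
    fcfg = FilterConfig(evalue_max=config.evalue_max, apply_ga=config.apply_ga)

    annotations_by_genome = {}
    stage_counts = {}
    for g in config.genomes:
        raw = formats_io.read_cmsearch_tblout(g.tblout, g.genome_id)
        trna = (
            formats_io.read_trnascan(g.trnascan, g.genome_id) if g.trnascan else []
        )
        filtered = filter_hits(list(raw) + list(trna), family_meta, fcfg)
        competed = compete_clans(filtered, family_meta)
        anns = collapse_overlaps(competed, family_meta)
        annotations_by_genome[g.genome_id] = anns
        stage_counts[g.genome_id] = {
            "raw": len(raw) + len(trna),
            "filtered": len(filtered),
            "competed": len(competed),
            "annotations": len(anns),
        }
        log.info(
            "%s: %d raw -> %d filtered -> %d competed -> %d loci",
            g.genome_id, len(raw) + len(trna), len(filtered), len(competed), len(anns),
        )
        for fmt, ext in (("GFF3", "gff3"), ("BED6", "bed")):
            path = os.path.join(config.out_dir, f"{g.genome_id}.{ext}")
            with open(path, "w", encoding="utf-8") as fh:
                formats_io.write_annotations(anns, fmt, stream=fh, family_meta=family_meta)
    manifest["stages"]["consolidate"] = stage_counts

    declared = {m.family_id: m.rna_class for m in family_meta.values()}
    matrix = build_matrix(annotations_by_genome, families=declared)
    with open(os.path.join(config.out_dir, "copy_number_matrix.tsv"), "w",
              encoding="utf-8") as fh:
        export_heatmap(matrix, stream=fh)
    conserved, removed = filter_conserved(
        matrix, ConservationConfig(min_genome_fraction=config.min_genome_fraction)
    )
    with open(os.path.join(config.out_dir, "copy_number_matrix.conserved.tsv"), "w",
              encoding="utf-8") as fh:
        export_heatmap(conserved, stream=fh)
    manifest["stages"]["conservation"] = {
        "families_total": len(matrix.families),
        "families_removed": removed,
    }
    results["matrix"] = matrix
    results["conserved_matrix"] = conserved

    report = absence_report(conserved)
    report.to_csv(os.path.join(config.out_dir, "absence_report.tsv"), sep="\t")
    results["absence_report"] = report

    reference = config.reference_genome or config.genomes[0].genome_id
    if config.chrom_classes:
        chrom_map = formats_io.read_chromosome_classes(config.chrom_classes)
        missing = flag_missing(conserved, config.missing_absent_fraction)
        ref_locus = {
            a.family_id: a.scaffold_id
            for a in reversed(annotations_by_genome.get(reference, []))
        }
        missing_loci = {f: ref_locus[f] for f in missing if f in ref_locus}
        all_loci = {f: ref_locus[f] for f in conserved.families if f in ref_locus}
        if all_loci:
            enrichment = microchromosome_enrichment(missing_loci, all_loci, chrom_map)
            results["enrichment"] = enrichment
            manifest["stages"]["enrichment"] = {
                "table": [enrichment.a, enrichment.b, enrichment.c, enrichment.d],
                "p_value": enrichment.p_value_str,
                "odds_ratio": "inf" if enrichment.odds_ratio == float("inf")
                else enrichment.odds_ratio,
            }

    if config.synteny_specs:
        specs = read_domain_specs(config.synteny_specs)
        table, summary = synteny_report(annotations_by_genome, specs,
                                        max_span=config.max_span)
        table.to_csv(os.path.join(config.out_dir, "synteny_report.tsv"),
                     sep="\t", index=False)
        results["synteny"] = (table, summary)
        manifest["stages"]["synteny"] = summary

    if config.reads:
        gin = next(g for g in config.genomes if g.genome_id == reference)
        if not gin.lengths:
            raise AvincError(f"expression stage needs scaffold lengths for {reference}")
        index = formats_io.read_scaffold_lengths(gin.lengths, reference)
        reads = formats_io.read_bed_reads(config.reads)
        anns = annotations_by_genome[reference]
        counts = count_reads(reads, anns, strand_aware=config.strand_aware)
        null = sample_null_regions(index, anns, config.n_null, seed=config.seed)
        null_counts = count_reads(reads, null.regions,
                                  strand_aware=config.strand_aware)
        threshold = select_threshold(null_counts, config.target_fpr)
        calls = call_expression(counts, threshold)
        summary = summarize(calls, anns, null_counts=null_counts,
                            threshold=threshold)
        with open(os.path.join(config.out_dir, "expression_summary.tsv"), "w",
                  encoding="utf-8") as fh:
            fh.write(summary.to_tsv())
        results["expression"] = summary
        manifest["stages"]["expression"] = {
            "min_count": threshold.min_count,
            "achieved_fpr": threshold.achieved_fpr,
            "total_annotated": summary.total_annotated,
            "total_expressed": summary.total_expressed,
            "pct_expressed": summary.total_pct,
        }

    with open(os.path.join(config.out_dir, "manifest.json"), "w",
              encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return results
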