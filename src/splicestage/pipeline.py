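"""End-to-end pipeline: classification, SSI, splicing order and recursive
splicing per gene, across a sample manifest."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import recursive as rec
from .classification import classify_sample
from .config import RunConfig
from .gene_model import GeneModel, load_annotation
from .splice_site_index import (InsufficientDataError, SpliceSiteTable,
                                per_base_depth, rank_intron_retention)
from .splicing_order import call_nonsequential, evidence_table

log = logging.getLogger("splicestage")


@dataclass
class GeneOutputs:
    gene_id: str
    files: dict[str, Path]


def run_pipeline(config: RunConfig) -> dict[str, GeneOutputs]:
    """Run all stages for every gene in the manifest.

    Per gene and sample: classification summary + per-pair table and SSI
    table; per gene across samples: retention ranking, non-sequential
    calls, per-sample and consensus peak wiggles, junction matrix and
    recursive event list.  Every threshold actually used is logged.
    Genes are processed independently.
    """
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    log.info(
        "thresholds: expected_distance=%d large_distance=%d anchor=%d "
        "ratio_cutoff=%.2f quartile=%s novel_exon_ratio=%.1f "
        "min_peak_magnitude=%d retention_alpha=%.2f",
        config.expected_distance, config.large_distance, config.anchor,
        config.ratio_cutoff, config.quartile, config.novel_exon_ratio,
        config.min_peak_magnitude, config.retention_alpha,
    )
    models = load_annotation(config.gtf, config.genes,
                             config.transcript_overrides)
    results = {}
    for model in models:
        results[model.gene_id] = _run_gene(model, config, out_root)
    return results


def _run_gene(model: GeneModel, config: RunConfig,
              out_root: Path) -> GeneOutputs:
    gene_dir = out_root / model.gene_id
    gene_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    rna = config.rna_samples
    min_samples = config.min_samples or len(rna)

    summaries, pair_frames, ssi_frames = [], [], []
    evidence = {}
    depth_total = np.zeros(model.span[1] - model.span[0], dtype=np.int64)
    for spec in rna:
        cls = classify_sample(spec.path, model, sample=spec.name,
                              expected_distance=config.expected_distance,
                              large_distance=config.large_distance)
        if not cls.pairs:
            log.warning("gene %s: no read pairs overlap in sample %s",
                        model.gene_id, spec.name)
        summaries.append(cls.summary())
        pair_frames.append(cls.to_frame().assign(sample=spec.name))
        table = SpliceSiteTable.from_alignments(spec.path, model,
                                                anchor=config.anchor)
        ssi_frames.append(table.to_frame().assign(sample=spec.name))
        evidence[spec.name] = evidence_table(cls, table.intron_medians,
                                             config.quartile)
        depth_total += per_base_depth(spec.path, model)
        if spec is rna[0]:
            try:
                retention = rank_intron_retention(table,
                                                  alpha=config.retention_alpha)
            except InsufficientDataError as exc:
                log.warning("gene %s: retention ranking skipped (%s)",
                            model.gene_id, exc)
                retention = pd.DataFrame()
            files["retention"] = gene_dir / "retention.tsv"
            retention.to_csv(files["retention"], sep="\t", index=False)

    files["classification_summary"] = gene_dir / "classification_summary.tsv"
    pd.concat(summaries, ignore_index=True).to_csv(
        files["classification_summary"], sep="\t", index=False)
    files["pairs"] = gene_dir / "pairs.tsv"
    pd.concat(pair_frames, ignore_index=True).to_csv(
        files["pairs"], sep="\t", index=False)
    files["ssi"] = gene_dir / "ssi.tsv"
    pd.concat(ssi_frames, ignore_index=True).to_csv(
        files["ssi"], sep="\t", index=False)

    control_evidence = None
    if config.dna_control is not None:
        spec = config.dna_control
        ctrl_cls = classify_sample(spec.path, model, sample=spec.name,
                                   expected_distance=config.expected_distance,
                                   large_distance=config.large_distance)
        ctrl_table = SpliceSiteTable.from_alignments(spec.path, model,
                                                     anchor=config.anchor)
        control_evidence = evidence_table(ctrl_cls, ctrl_table.intron_medians,
                                          config.quartile)
    calls = call_nonsequential(evidence, control_evidence,
                               min_samples=min_samples,
                               ratio_cutoff=config.ratio_cutoff)
    files["order_calls"] = gene_dir / "order_calls.tsv"
    calls.calls.assign(pearson_r=calls.pearson_r,
                       spearman_r=calls.spearman_r).to_csv(
        files["order_calls"], sep="\t", index=False)

    rna_paths = [s.path for s in rna]
    rr = rec.detect_recursive(
        rna_paths, model, genome=config.genome, min_samples=min_samples,
        min_magnitude=config.min_peak_magnitude,
        novel_exon_ratio=config.novel_exon_ratio, depth=depth_total,
        sample_names=[s.name for s in rna],
    )
    for spec, ps in zip(rna, rr.peaksets):
        wig = gene_dir / f"peaks.{spec.name}.wig"
        ps.to_wiggle(wig)
        files[f"peaks_{spec.name}"] = wig
    files["consensus_peaks"] = gene_dir / "consensus_peaks.wig"
    rec.consensus_to_wiggle(rr.consensus, model.chrom,
                            files["consensus_peaks"])
    files["junction_matrix"] = gene_dir / "junction_matrix.tsv"
    rr.junctions.matrix().to_csv(files["junction_matrix"], sep="\t")
    files["events"] = gene_dir / "events.tsv"
    rr.events.to_csv(files["events"], sep="\t", index=False)
    files["novel_exons"] = gene_dir / "novel_exons.tsv"
    rr.novel_exons.to_csv(files["novel_exons"], sep="\t", index=False)
    if not rr.summary.empty:
        files["motif_summary"] = gene_dir / "motif_summary.tsv"
        rr.summary.to_csv(files["motif_summary"], sep="\t", index=False)
    return GeneOutputs(model.gene_id, files)
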