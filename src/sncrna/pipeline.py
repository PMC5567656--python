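"""One-command annotation pipeline and per-class summaries.

Stages run in a fixed hierarchy so a read never counts twice:
optional adapter trimming -> low-complexity filter -> miRNA tiers ->
ncRNA/cDNA with tRF classification -> piRNA clusters -> not annotated.
The summary is a table of fractional read counts per category whose sum
equals the total input reads.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

from . import __version__
from .adapter import infer_and_trim
from .complexity import ComplexityParams, filter_low_complexity
from .core import ReadSet, ReferenceRecord
from .io import load_reference_fasta, write_outputs
from .mirna import MirnaParams, MirnaRef, annotate_mirnas, modification_matrix, tail_composition
from .ncrna import (
    NcrnaParams, annotate_ncrna, apportion_counts, build_trna_model, classify_trf_hits,
)
from .pirna import call_pirna_candidates, pingpong_profile

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one annotation run."""

    input_path: str = ""
    input_format: str = "fasta"  # fasta | fastq | collapsed-fasta
    refs_dir: str = ""
    output_dir: str = "sncrna-out"
    trim: bool = False
    adapter: str | None = None
    trim_ignore_5p: int = 22
    bias_threshold: float = 0.8
    complexity_filter: bool = True
    complexity_threshold: float = 0.75
    run_mirna: bool = True
    species: str = ""
    max_tail: int = 2
    max_internal: int = 1
    offset_window: int = 5
    ncrna_max_mismatch: int = 1
    trf_tolerance: int = 2
    pirna_max_mismatch: int = 0
    seed: int = 1

    def mirna_params(self) -> MirnaParams:
        return MirnaParams(
            max_tail=self.max_tail, max_internal=self.max_internal,
            offset_window=self.offset_window, species=self.species,
        )


@dataclass
class AnnotationSummary:
    total_input_reads: float
    categories: dict[str, float]
    mirna_tier_counts: dict[str, float] = dc_field(default_factory=dict)
    class_counts: dict[str, float] = dc_field(default_factory=dict)
    trf_counts: dict[str, float] = dc_field(default_factory=dict)
    pingpong_z: float | None = None


def summarize_class(reads: ReadSet) -> tuple[dict[int, int], list[dict[str, float]]]:
    """Length distribution and positional nucleotide composition.

    Returns a count-weighted length histogram and, per 1-based read
    position, A/C/G/T(/N) fractions over the reads long enough to have
    that position (each row sums to 1).
    """
    histogram: dict[int, int] = defaultdict(int)
    position_counts: list[dict[str, float]] = []
    for seq, count in reads:
        histogram[len(seq)] += count
        while len(position_counts) < len(seq):
            position_counts.append(defaultdict(float))
        for pos, base in enumerate(seq):
            position_counts[pos][base] += count
    composition = []
    for counts in position_counts:
        total = sum(counts.values())
        composition.append({b: c / total for b, c in sorted(counts.items())})
    return dict(histogram), composition


def _load_refs(refs_dir: str) -> list[ReferenceRecord]:
    records: list[ReferenceRecord] = []
    for path in sorted(Path(refs_dir).glob("*.fa")) + sorted(Path(refs_dir).glob("*.fasta")):
        records.extend(load_reference_fasta(path))
    return records


def run_pipeline(
    config: RunConfig,
    reads: ReadSet | None = None,
    references: Sequence[ReferenceRecord] | None = None,
    write_files: bool = True,
) -> AnnotationSummary:
    """Run the full annotation hierarchy.

    ``reads`` and ``references`` may be passed in memory; otherwise they
    are loaded from ``config.input_path`` / ``config.refs_dir``.  The
    summary's category counts sum to the total input reads.
    """
    from .io import read_sequences  # local import to keep module load light

    if reads is None:
        reads = read_sequences(config.input_path, config.input_format)
    if references is None:
        references = _load_refs(config.refs_dir) if config.refs_dir else []

    total_input = float(reads.total_reads)
    categories: dict[str, float] = defaultdict(float)
    tables: dict[str, tuple[Sequence[str], list]] = {}

    if config.trim and len(reads) > 0:
        reads, model = infer_and_trim(
            reads, motif=config.adapter, ignore_5p=config.trim_ignore_5p,
            bias_threshold=config.bias_threshold,
        )
        logger.info("adapter motif %s; %d reads after trimming", model.motif, reads.total_reads)
        categories["trimmed-away"] = total_input - reads.total_reads

    if config.complexity_filter and len(reads) > 0:
        params = ComplexityParams(f_threshold=config.complexity_threshold)
        reads, rejected = filter_low_complexity(reads, params)
        categories["low-complexity"] = float(rejected.total_reads)
        logger.info("low-complexity filter rejected %d reads", rejected.total_reads)

    mirna_hits = []
    tier_counts: dict[str, float] = defaultdict(float)
    if config.run_mirna:
        mirna_records = [r for r in references if r.rna_class in ("mirna", "hairpin")]
        if mirna_records:
            ref = MirnaRef.from_records(mirna_records)
            mirna_hits, reads = annotate_mirnas(reads, ref, config.mirna_params())
            for hit in mirna_hits:
                tier_counts[f"miRNA ({hit.scope} {hit.tier})"] += hit.count
            for key, value in tier_counts.items():
                categories[key] += value
            logger.info("miRNA stage assigned %.1f reads", sum(tier_counts.values()))

    class_counts: dict[str, float] = {}
    trf_counts: dict[str, float] = {}
    nc_records = [r for r in references if r.rna_class in ("ncrna", "trna")]
    if nc_records and len(reads) > 0:
        nc_params = NcrnaParams(
            max_mismatch=config.ncrna_max_mismatch, tolerance=config.trf_tolerance
        )
        hits = annotate_ncrna(reads, nc_records, nc_params)
        class_counts = apportion_counts(hits)
        models = {
            r.record_id: build_trna_model(r) for r in nc_records if r.rna_class == "trna"
        }
        trf_counts = classify_trf_hits(hits, models, config.trf_tolerance)
        for cls, value in class_counts.items():
            categories[cls] += value
        reads = reads.without(h.read_seq for h in hits)
        logger.info("ncRNA stage assigned %.1f reads", sum(class_counts.values()))

    pingpong_z = None
    cluster_records = [r for r in references if r.rna_class == "picluster"]
    if cluster_records and len(reads) > 0:
        candidates, reads, cluster_alns = call_pirna_candidates(
            reads, cluster_records, config.pirna_max_mismatch
        )
        categories["piRNA candidate"] = float(candidates.total_reads)
        if cluster_alns:
            pingpong_z = pingpong_profile(cluster_alns).z_score
        if len(candidates) > 0:
            histogram, composition = summarize_class(candidates)
            tables["pirna_length_distribution"] = (
                ("length", "reads"), sorted(histogram.items()),
            )
            tables["pirna_positional_composition"] = (
                ("position", "A", "C", "G", "T"),
                [
                    (pos + 1,) + tuple(round(row.get(b, 0.0), 6) for b in "ACGT")
                    for pos, row in enumerate(composition)
                ],
            )
        logger.info("piRNA stage: %.0f candidate reads", categories["piRNA candidate"])

    categories["not annotated"] = float(reads.total_reads)

    summary = AnnotationSummary(
        total_input_reads=total_input,
        categories=dict(categories),
        mirna_tier_counts=dict(tier_counts),
        class_counts=class_counts,
        trf_counts=trf_counts,
        pingpong_z=pingpong_z,
    )
    balance = sum(summary.categories.values())
    if abs(balance - total_input) > 1e-6:
        raise AssertionError(
            f"category counts ({balance}) do not balance input reads ({total_input})"
        )

    if write_files:
        outdir = Path(config.output_dir)
        tables["summary"] = (
            ("category", "reads"),
            [(k, round(v, 6)) for k, v in sorted(summary.categories.items())],
        )
        if mirna_hits:
            tables["mirna_table"] = (
                ("read", "gene", "species", "scope", "tier", "tail", "modifications", "count"),
                [
                    (
                        h.read_seq, h.gene, h.species, h.scope, h.tier, h.tail or ".",
                        ";".join(f"{p}:{a}->{b}" for p, a, b in h.modifications) or ".",
                        round(h.count, 6),
                    )
                    for h in sorted(mirna_hits, key=lambda h: (h.read_seq, h.gene))
                ],
            )
            mod = modification_matrix(mirna_hits)
            tables["mirna_modifications"] = (
                ("position", "change", "count"),
                [(p, c, round(v, 6)) for (p, c), v in sorted(mod.items())],
            )
            tails = tail_composition(mirna_hits)
            tables["mirna_tails"] = (
                ("tail", "count"), [(k, round(v, 6)) for k, v in sorted(tails.items())],
            )
        if class_counts:
            tables["class_counts"] = (
                ("class", "count"),
                [(k, round(v, 6)) for k, v in sorted(class_counts.items())],
            )
        if trf_counts:
            tables["trf_table"] = (
                ("trf_class", "count"),
                [(k, round(v, 6)) for k, v in sorted(trf_counts.items())],
            )
        histogram, composition = summarize_class(reads) if len(reads) else ({}, [])
        tables["unannotated_length_distribution"] = (
            ("length", "reads"), sorted(histogram.items()),
        )
        write_outputs(tables, outdir)
        report = {
            "version": __version__,
            "parameters": {k: v for k, v in vars(config).items()},
            "total_input_reads": total_input,
            "categories": {k: summary.categories[k] for k in sorted(summary.categories)},
        }
        (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return summary
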