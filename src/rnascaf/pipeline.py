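"""End-to-end orchestration: split -> ingest -> denoise -> graph -> reconcile
-> update, with per-stage accounting.

The in-memory entry point is :func:`scaffold_pipeline`; :func:`run_scaffold`
wraps it with file I/O for the command line. Every joining-pair that enters
the pipeline is accounted for in exactly one ledger category, and simple
conservation identities (sequence counts, base counts, gene counts) are
asserted after every run.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from . import alignment_ingest, annotation_io, assembly_io
from .alignment_ingest import ExtractionStats, JoiningPair
from .annotation_io import ContigAnnotation
from .assembly_io import ContigRecord, SplitMap
from .denoiser import DenoiseResult, denoise
from .reconciler import ScaffoldPath, commit_paths
from .scaffold_graph import DEFAULT_K, build_graph
from .updater import DEFAULT_GAP_LEN, UpdateResult, sequence_fidelity_check, update_assembly

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    assembly_path: str = ""
    alignment_path: str = ""
    gff_path: str = ""
    out_dir: str = "."
    K: int = DEFAULT_K
    max_frac_mm: float = 0.05
    min_frac_ovl: float = 0.70
    gap_len: int = DEFAULT_GAP_LEN
    split_mode: bool = False
    min_gap_len: int = 25

    def __post_init__(self) -> None:
        if not (0 <= self.max_frac_mm <= 1):
            raise ValueError("max_frac_mm must be in [0,1]")
        if not (0 <= self.min_frac_ovl <= 1):
            raise ValueError("min_frac_ovl must be in [0,1]")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.gap_len < 0:
            raise ValueError("gap_len must be >= 0")


@dataclass
class PipelineResult:
    contigs: dict[str, ContigRecord]
    annotations: dict[str, ContigAnnotation]
    paths: list[ScaffoldPath]
    update: UpdateResult
    denoise: DenoiseResult
    split_map: Optional[SplitMap] = None
    extraction: Optional[ExtractionStats] = None
    inconsistencies: list[dict] = field(default_factory=list)
    ledger: dict = field(default_factory=dict)


def scaffold_pipeline(
    contigs: dict[str, ContigRecord],
    annotations: dict[str, ContigAnnotation],
    pairs: list[JoiningPair],
    K: int = DEFAULT_K,
    gap_len: int = DEFAULT_GAP_LEN,
    split_map: Optional[SplitMap] = None,
    enforce_reconciliation: bool = True,
) -> PipelineResult:
    """Run denoising, graph traversal, reconciliation and update in memory."""
    lengths = {name: rec.length for name, rec in contigs.items()}
    den = denoise(pairs, annotations, lengths)
    graph = build_graph(den.edges, K=K, vertices=contigs)
    paths = commit_paths(graph, annotations, den.registry, enforce=enforce_reconciliation)
    update = update_assembly(paths, contigs, annotations, den.registry, gap_len=gap_len)

    problems = sequence_fidelity_check(contigs, update.scaffolds)
    if problems:
        raise AssertionError("sequence fidelity violated: " + "; ".join(problems))

    committed_pairs = sum(j.weight for p in paths for j in p.junctions)
    edge_weights = [e.weight for e in den.edges]
    below_k = sum(w for w in edge_weights if w < K)
    uncommitted = sum(edge_weights) - below_k - committed_pairs
    genes_in = sum(len(a.genes) for a in annotations.values())
    ledger = {
        "pairs_in": len(pairs),
        "rejected_between_genes": den.rejected_assign,
        "rejected_orientation": den.rejected_orientation,
        "minority_combo_dropped": den.minority_dropped,
        "tied_combo_dropped": den.tie_dropped,
        "edges_pre_filter": len(den.edges),
        "edges_post_filter": sum(1 for w in edge_weights if w >= K),
        "pairs_below_k": below_k,
        "pairs_on_uncommitted_edges": uncommitted,
        "pairs_in_committed_junctions": committed_pairs,
        "junctions": update.junction_count,
        "scaffolds": len(update.scaffolds),
        "contigs_in": len(contigs),
        "sequences_out": len(update.assembly),
        "genes_in": genes_in,
        "genes_out": update.gene_count,
        "artificial_created": len(den.registry.models),
        "artificial_kept": update.artificial_kept,
        "artificial_discarded": update.artificial_discarded,
    }
    result = PipelineResult(
        contigs=contigs,
        annotations=annotations,
        paths=paths,
        update=update,
        denoise=den,
        split_map=split_map,
        ledger=ledger,
    )
    if split_map is not None:
        result.inconsistencies = scaffolding_inconsistencies(paths, split_map)
    check_conservation(result, gap_len)
    return result


def check_conservation(result: PipelineResult, gap_len: int) -> None:
    """Assert the sequence/base/gene conservation identities of a run."""
    led = result.ledger
    if led["sequences_out"] != led["contigs_in"] - led["junctions"]:
        raise AssertionError("sequence count not conserved")
    bases_in = sum(r.length for r in result.contigs.values())
    bases_out = sum(r.length for r in result.update.assembly.values())
    if bases_out != bases_in + gap_len * led["junctions"]:
        raise AssertionError("base count not conserved")
    expected_genes = (
        led["genes_in"]
        + led["artificial_created"]
        - led["junctions"]
        - led["artificial_discarded"]
    )
    if led["genes_out"] != expected_genes:
        raise AssertionError(
            f"gene count not conserved: {led['genes_out']} != {expected_genes}"
        )
    accounted = (
        led["pairs_in_committed_junctions"]
        + led["pairs_on_uncommitted_edges"]
        + led["pairs_below_k"]
        + led["minority_combo_dropped"]
        + led["tied_combo_dropped"]
        + led["rejected_between_genes"]
        + led["rejected_orientation"]
    )
    if accounted != led["pairs_in"]:
        raise AssertionError("joining-pair ledger does not balance")


def scaffolding_inconsistencies(paths: list[ScaffoldPath], split_map: SplitMap) -> list[dict]:
    """Disagreements between RNA-based junctions and the original scaffolding.

    For every originally adjacent part pair (u, v) — u's right end faced v's
    left end in the source scaffold — a row is reported when the RNA evidence
    consumes one of those ends with a different partner or different facing
    ends. Unused ends are not disagreements (absence of evidence).
    """
    usage: dict[tuple[str, int], tuple[str, int]] = {}
    for p in paths:
        for j in p.junctions:
            usage[(j.left_contig, j.side_left)] = (j.right_contig, j.side_right)
            usage[(j.right_contig, j.side_right)] = (j.left_contig, j.side_left)
    rows: list[dict] = []
    for u, v in split_map.adjacent_part_pairs():
        got_u = usage.get((u, 3))
        got_v = usage.get((v, 5))
        if got_u is not None and got_u != (v, 5):
            rows.append({"part": u, "end": 3, "expected_partner": v, "observed": got_u})
        if got_v is not None and got_v != (u, 3):
            rows.append({"part": v, "end": 5, "expected_partner": u, "observed": got_v})
    return rows


def run_scaffold(config: RunConfig) -> PipelineResult:
    """File-based pipeline entry point: read inputs, run, write outputs."""
    assembly = assembly_io.read_fasta(config.assembly_path)
    split_map = None
    if config.split_mode:
        assembly, split_map = assembly_io.split_scaffolds(assembly, config.min_gap_len)
        raw_ann = annotation_io.read_gff(config.gff_path, {e.source_scaffold: None for e in split_map.entries})
        annotations = annotation_io.split_annotation(raw_ann, split_map)
    else:
        annotations = annotation_io.read_gff(config.gff_path, assembly)

    pairs, extraction = alignment_ingest.extract_joining_pairs(
        config.alignment_path, config.max_frac_mm, config.min_frac_ovl
    )
    unknown = {
        e.contig
        for p in pairs
        for e in p.ends()
        if e.contig not in assembly
    }
    if unknown:
        raise ValueError(
            f"alignment references absent from the assembly: {sorted(unknown)}"
        )

    result = scaffold_pipeline(
        assembly,
        annotations,
        pairs,
        K=config.K,
        gap_len=config.gap_len,
        split_map=split_map,
    )
    result.extraction = extraction
    result.ledger["extraction"] = extraction.as_dict()

    os.makedirs(config.out_dir, exist_ok=True)
    assembly_io.write_fasta(
        result.update.assembly.values(), os.path.join(config.out_dir, "updated_assembly.fa")
    )
    annotation_io.write_gff(
        result.update.annotations, os.path.join(config.out_dir, "updated_genes.gff3")
    )
    write_join_table(result.paths, os.path.join(config.out_dir, "join_table.tsv"))
    with open(os.path.join(config.out_dir, "rejections.tsv"), "w") as fh:
        fh.write("read_id\treason\n")
        for rid, reason in result.denoise.rejections:
            fh.write(f"{rid}\t{reason}\n")
    if split_map is not None:
        split_map.write_tsv(os.path.join(config.out_dir, "split_map.tsv"))
        with open(os.path.join(config.out_dir, "inconsistencies.tsv"), "w") as fh:
            fh.write("part\tend\texpected_partner\tobserved_partner\tobserved_end\n")
            for row in result.inconsistencies:
                fh.write(
                    f"{row['part']}\t{row['end']}\t{row['expected_partner']}\t"
                    f"{row['observed'][0]}\t{row['observed'][1]}\n"
                )
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(result.ledger, fh, indent=2)
    logger.info("pipeline summary: %s", result.ledger)
    return result


def write_join_table(paths: list[ScaffoldPath], path: str, prefix: str = "scaffold") -> None:
    with open(path, "w") as fh:
        fh.write(
            "scaffold\tposition\tcontig\torientation\tgene_left\tgene_right\tweight\n"
        )
        for idx, p in enumerate(sorted(paths, key=lambda p: p.contigs[0]), start=1):
            name = f"{prefix}_{idx}"
            for pos, (contig, orient) in enumerate(p.entries):
                j = p.junctions[pos - 1] if pos > 0 else None
                gene_l = j.gene_left if j else "."
                gene_r = j.gene_right if j else "."
                w = j.weight if j else 0
                fh.write(f"{name}\t{pos}\t{contig}\t{orient}\t{gene_l}\t{gene_r}\t{w}\n")
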