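"""Materialize scaffolds and lift/merge gene models onto them.

Committed paths become scaffold sequences: components concatenated in path
order, reverse-complemented where the path orientation is '-', separated by
runs of N of a user-chosen length (default 1000, roughly an intron-scale
spacer). Gene models are lifted into scaffold coordinates (reflected and
strand-flipped on reversed components) and the two connecting gene models of
every junction are merged into a single model whose exon set is the union of
both lifted exon sets. Chains of junctions through single-gene contigs
collapse into one merged model, so the gene count always drops by exactly the
number of junctions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotation_io import ContigAnnotation, GeneModel
from .assembly_io import ContigRecord, reverse_complement
from .denoiser import ArtificialGeneRegistry
from .reconciler import ScaffoldPath

logger = logging.getLogger(__name__)

DEFAULT_GAP_LEN = 1000


@dataclass
class ScaffoldRecord:
    name: str
    sequence: str
    # (contig, orientation, offset of the contig's first base in the scaffold)
    components: list[tuple[str, str, int]]
    gap_len: int


def build_scaffold(
    path: ScaffoldPath,
    contigs: dict[str, ContigRecord],
    gap_len: int = DEFAULT_GAP_LEN,
    name: str = "scaffold_1",
) -> ScaffoldRecord:
    """Concatenate a path's contigs (rc-aware) with N-gaps between them."""
    chunks: list[str] = []
    components: list[tuple[str, str, int]] = []
    offset = 0
    for i, (cname, orient) in enumerate(path.entries):
        if cname not in contigs:
            raise KeyError(f"contig {cname!r} missing from assembly")
        seq = contigs[cname].sequence
        if orient == "-":
            seq = reverse_complement(seq)
        if i > 0:
            chunks.append("N" * gap_len)
            offset += gap_len
        chunks.append(seq)
        components.append((cname, orient, offset))
        offset += len(seq)
    return ScaffoldRecord(name=name, sequence="".join(chunks), components=components, gap_len=gap_len)


def _lift_gene(
    gene: GeneModel, comp_len: int, orient: str, offset: int, scaffold: str
) -> GeneModel:
    if orient == "+":
        exons = [(offset + s, offset + e) for s, e in gene.exons]
        strand = gene.strand
    else:
        exons = sorted((offset + comp_len - e, offset + comp_len - s) for s, e in gene.exons)
        strand = {"+": "-", "-": "+"}.get(gene.strand, ".")
    return GeneModel(
        gene_id=gene.gene_id,
        contig=scaffold,
        start=exons[0][0],
        end=exons[-1][1],
        strand=strand,
        exons=exons,
        is_artificial=gene.is_artificial,
        merged_from=list(gene.merged_from),
    )


@dataclass
class UpdateResult:
    scaffolds: list[ScaffoldRecord]
    assembly: dict[str, ContigRecord]  # scaffolds + pass-through contigs
    annotations: dict[str, ContigAnnotation]
    junction_count: int
    genes_merged: int
    artificial_kept: int
    artificial_discarded: int
    gene_count: int = 0
    ledger: dict = field(default_factory=dict)


def update_assembly(
    paths: list[ScaffoldPath],
    contigs: dict[str, ContigRecord],
    annotations: dict[str, ContigAnnotation],
    registry: Optional[ArtificialGeneRegistry] = None,
    gap_len: int = DEFAULT_GAP_LEN,
    scaffold_prefix: str = "scaffold",
) -> UpdateResult:
    """Build the updated assembly + annotation from committed paths.

    Artificial gene models that participate in a junction are kept (inside
    merged models); all other artificial models are discarded. Pass-through
    contigs and their annotations are emitted unchanged.
    """
    used_genes: set[str] = set()
    junction_genes: dict[str, list[str]] = {}
    scaffolds: list[ScaffoldRecord] = []
    out_assembly: dict[str, ContigRecord] = {}
    out_ann: dict[str, ContigAnnotation] = {}
    placed: set[str] = set()
    n_junctions = 0

    # genes available per contig = input models + artificial models actually
    # referenced by a junction on that contig
    art_by_id: dict[str, GeneModel] = {}
    if registry is not None:
        art_by_id = {m.gene_id: m for m in registry.models.values()}
    junction_gene_ids: set[str] = set()
    for p in paths:
        for j in p.junctions:
            junction_gene_ids.update((j.gene_left, j.gene_right))

    for idx, path in enumerate(sorted(paths, key=lambda p: p.contigs[0]), start=1):
        scaf = build_scaffold(path, contigs, gap_len, name=f"{scaffold_prefix}_{idx}")
        scaffolds.append(scaf)
        placed.update(path.contigs)
        n_junctions += len(path.junctions)
        out_assembly[scaf.name] = ContigRecord(scaf.name, scaf.sequence)

        # lift every gene of every component onto the scaffold
        lifted: dict[str, GeneModel] = {}
        for cname, orient, offset in scaf.components:
            comp_len = contigs[cname].length
            source_genes: list[GeneModel] = []
            if cname in annotations:
                source_genes.extend(annotations[cname].genes)
            for (rc, side), m in (registry.models.items() if registry else []):
                if rc == cname and m.gene_id in junction_gene_ids:
                    source_genes.append(m)
            for g in source_genes:
                lifted[g.gene_id] = _lift_gene(g, comp_len, orient, offset, scaf.name)

        # union-find over genes connected by this path's junctions: chains of
        # junctions through single-gene contigs merge into one model
        parent: dict[str, str] = {gid: gid for gid in lifted}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        merged_in_path = 0
        for j in path.junctions:
            if j.gene_left in parent and j.gene_right in parent:
                ra, rb = find(j.gene_left), find(j.gene_right)
                if ra != rb:
                    parent[ra] = rb
                    merged_in_path += 1
        if merged_in_path != len(path.junctions):
            logger.warning(
                "scaffold %s: %d junctions but %d merges", scaf.name, len(path.junctions), merged_in_path
            )

        groups: dict[str, list[GeneModel]] = {}
        for gid in lifted:
            groups.setdefault(find(gid), []).append(lifted[gid])
        ann = ContigAnnotation(scaf.name)
        merge_counter = 0
        for members in groups.values():
            if len(members) == 1:
                ann.genes.append(members[0])
                continue
            merge_counter += 1
            members.sort(key=lambda g: (g.start, g.end, g.gene_id))
            exons = sorted(ex for g in members for ex in g.exons)
            strands = [g.strand for g in members if g.strand in "+-"]
            if strands and strands.count(strands[0]) != len(strands):
                logger.warning("merged gene with conflicting strands on %s; using '+'", scaf.name)
            strand = (
                max(("+", "-"), key=lambda s: strands.count(s)) if strands else "+"
            )
            if strands.count("+") == strands.count("-") and strands:
                strand = "+"
            ann.genes.append(
                GeneModel(
                    gene_id=f"merged_{scaf.name}_{merge_counter}",
                    contig=scaf.name,
                    start=exons[0][0],
                    end=exons[-1][1],
                    strand=strand,
                    exons=_merge_touching(exons),
                    merged_from=[g.gene_id for g in members],
                )
            )
            used_genes.update(g.gene_id for g in members)
        ann.sort()
        out_ann[scaf.name] = ann

    # pass-through contigs
    for cname, rec in contigs.items():
        if cname not in placed:
            out_assembly[cname] = rec
            if cname in annotations:
                out_ann[cname] = annotations[cname]

    art_kept = sum(1 for gid in art_by_id if gid in used_genes)
    art_discarded = len(art_by_id) - art_kept
    gene_count = sum(len(a.genes) for a in out_ann.values())
    result = UpdateResult(
        scaffolds=scaffolds,
        assembly=out_assembly,
        annotations=out_ann,
        junction_count=n_junctions,
        genes_merged=len(used_genes),
        artificial_kept=art_kept,
        artificial_discarded=art_discarded,
        gene_count=gene_count,
    )
    result.ledger = {
        "scaffolds": len(scaffolds),
        "junctions": n_junctions,
        "genes_out": gene_count,
        "artificial_kept": art_kept,
        "artificial_discarded": art_discarded,
    }
    return result


def _merge_touching(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union overlapping exon intervals after a merge (distinct exons kept)."""
    merged: list[list[int]] = []
    for s, e in sorted(exons):
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def sequence_fidelity_check(
    original: dict[str, ContigRecord], scaffolds: Iterable[ScaffoldRecord]
) -> list[str]:
    """Verify every scaffold component slice equals its source contig (rc-aware).

    Returns a list of mismatch descriptions; non-empty means an offset or
    reverse-complement bug, and callers should treat it as a hard error.
    """
    problems: list[str] = []
    for scaf in scaffolds:
        for cname, orient, offset in scaf.components:
            src = original[cname].sequence
            piece = scaf.sequence[offset : offset + len(src)]
            if orient == "-":
                piece = reverse_complement(piece)
            if piece != src:
                problems.append(f"{scaf.name}:{cname}@{offset}({orient}) does not match source")
    return problems
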