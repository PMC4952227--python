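"""GFF gene-model I/O and per-contig gene queries.

Gene models are stored with 0-based half-open coordinates internally and
converted to/from the 1-based inclusive GFF3 convention at the file boundary.
A gene model is the union of exon intervals of all its transcripts (isoforms
are collapsed per gene id). "Artificial" models are single-exon placeholders
created where joining-pair reads map outside a contig's terminal genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import gffutils

logger = logging.getLogger(__name__)


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+', '-' or '.'
    exons: list[tuple[int, int]] = field(default_factory=list)
    is_artificial: bool = False
    merged_from: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons.sort()
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        for (s, e) in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene span")

    def overlaps(self, start: int, end: int) -> bool:
        """True if [start,end) intersects the gene span by >= 1 base."""
        return start < self.end and end > self.start


@dataclass
class ContigAnnotation:
    contig: str
    genes: list[GeneModel] = field(default_factory=list)

    def sort(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.end, g.gene_id))

    def add(self, gene: GeneModel) -> None:
        self.genes.append(gene)
        self.sort()


def terminal_genes(
    annotation: Optional[ContigAnnotation],
) -> tuple[Optional[GeneModel], Optional[GeneModel]]:
    """The 5'-most (lowest start) and 3'-most (highest end) genes on a contig.

    "5'/3' of a contig" means the contig's coordinate ends (left/right),
    independent of gene strand. A single-gene contig returns that gene twice;
    an empty or missing annotation returns (None, None). Ties broken by the
    (start, end, gene_id) sort.
    """
    if annotation is None or not annotation.genes:
        return None, None
    genes = sorted(annotation.genes, key=lambda g: (g.start, g.end, g.gene_id))
    five = genes[0]
    three = max(genes, key=lambda g: (g.end, -g.start, g.gene_id))
    return five, three


def make_artificial_gene(
    contig: str,
    contig_length: int,
    interval: tuple[int, int],
    side: int,
    annotation: Optional[ContigAnnotation],
    index: int,
) -> GeneModel:
    """Create a single-exon artificial gene model at a contig edge.

    ``side`` is 5 (left of the 5'-most gene) or 3 (right of the 3'-most gene).
    The interval must lie strictly outside the span between the terminal genes
    — otherwise the caller must discard the joining-pair instead — or the
    contig may carry no genes at all.
    """
    s, e = interval
    if not (0 <= s < e <= contig_length):
        raise ValueError(f"interval ({s},{e}) outside contig {contig}")
    five, three = terminal_genes(annotation)
    if five is not None:
        if side == 5 and e > five.start:
            raise ValueError(
                f"interval ({s},{e}) not strictly left of 5'-most gene on {contig}"
            )
        if side == 3 and s < three.end:
            raise ValueError(
                f"interval ({s},{e}) not strictly right of 3'-most gene on {contig}"
            )
    return GeneModel(
        gene_id=f"art_{contig}_{index}",
        contig=contig,
        start=s,
        end=e,
        strand=".",
        exons=[(s, e)],
        is_artificial=True,
    )


def read_gff(path: str, assembly: dict) -> dict[str, ContigAnnotation]:
    """Read gene predictions into a contig -> ContigAnnotation mapping.

    Accepts gene -> (mRNA ->) exon hierarchies and flat gene+exon files; CDS
    features are used where a gene has no exon children. Exons of all isoforms
    of one gene are merged into one model. Seqids absent from the assembly are
    a hard error.
    """
    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    out: dict[str, ContigAnnotation] = {}
    missing: set[str] = set()
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.seqid not in assembly:
            missing.add(gene.seqid)
            continue
        exons = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype="exon", order_by="start")
        ]
        if not exons:
            exons = [
                (f.start - 1, f.end)
                for f in db.children(gene, featuretype="CDS", order_by="start")
            ]
        if not exons:
            logger.warning(
                "gene %s has no exon/CDS children; using a single exon over its span",
                gene.id,
            )
            exons = [(gene.start - 1, gene.end)]
        exons = _merge_intervals(exons)
        model = GeneModel(
            gene_id=gene.id,
            contig=gene.seqid,
            start=gene.start - 1,
            end=gene.end,
            strand=gene.strand if gene.strand in "+-" else ".",
            exons=exons,
        )
        out.setdefault(gene.seqid, ContigAnnotation(gene.seqid)).genes.append(model)
    if missing:
        raise ValueError(
            f"GFF seqids absent from the assembly: {sorted(missing)}"
        )
    for ann in out.values():
        ann.sort()
    return out


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly overlapping intervals (collapses isoforms)."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def write_gff(annotations: dict[str, ContigAnnotation], path: str) -> None:
    """Write GFF3 (gene + exon rows, 1-based inclusive).

    Artificial models that were never used in scaffolding must already have
    been dropped by the caller; this writer emits whatever it is given.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in sorted(annotations):
            ann = annotations[contig]
            for g in sorted(ann.genes, key=lambda g: (g.start, g.end, g.gene_id)):
                attrs = f"ID={g.gene_id}"
                if g.merged_from:
                    attrs += ";merged_from=" + ",".join(g.merged_from)
                if g.is_artificial:
                    attrs += ";artificial=true"
                strand = g.strand if g.strand in "+-" else "."
                fh.write(
                    f"{contig}\trnascaf\tgene\t{g.start + 1}\t{g.end}\t.\t{strand}\t.\t{attrs}\n"
                )
                for i, (s, e) in enumerate(g.exons, start=1):
                    fh.write(
                        f"{contig}\trnascaf\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                    )


def split_annotation(
    annotations: dict[str, ContigAnnotation], split_map
) -> dict[str, ContigAnnotation]:
    """Lift gene models from scaffolds onto their split parts.

    Exons are clipped at part boundaries; a gene straddling a gap becomes one
    fragment per part it touches, named ``<gene_id>_p<k>``. Mirrors what a
    gene predictor would report on the split assembly.
    """
    out: dict[str, ContigAnnotation] = {}
    for entry in split_map.entries:
        src_ann = annotations.get(entry.source_scaffold)
        if src_ann is None:
            continue
        part_ann = ContigAnnotation(entry.contig_name)
        for g in src_ann.genes:
            clipped = [
                (max(s, entry.start_offset) - entry.start_offset,
                 min(e, entry.end_offset) - entry.start_offset)
                for s, e in g.exons
                if s < entry.end_offset and e > entry.start_offset
            ]
            if not clipped:
                continue
            whole = g.start >= entry.start_offset and g.end <= entry.end_offset
            gid = g.gene_id if whole else f"{g.gene_id}_p{entry.part_index}"
            part_ann.genes.append(
                GeneModel(
                    gene_id=gid,
                    contig=entry.contig_name,
                    start=clipped[0][0],
                    end=clipped[-1][1],
                    strand=g.strand,
                    exons=clipped,
                )
            )
        if part_ann.genes:
            part_ann.sort()
            out[entry.contig_name] = part_ann
    return out
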