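"""Ground-truthed synthetic worlds for exercising the scaffolding pipeline.

A world is a set of source sequences carrying planted multi-exon genes, a
tiling of each source into contigs (breakpoints placed inside introns, so
gene models are split across contigs the way a fragmented assembly splits
them), per-contig gene predictions (the planted models clipped at contig
boundaries, as a gene predictor would report them), and paired-end alignments
rendered directly as SAM records: for every breakpoint inside a gene, several
read pairs straddle it with one mate in each flanking exon, inward-facing
(FR), MAPQ 60, NM=0. Chimeric "noise" pairs connecting random non-adjacent
contigs emulate mis-mappings caused by similar sequences in different parts
of a genome.

Reads are emitted pre-aligned rather than run through a mapper: the pipeline
consumes any mapper's SAM/BAM anyway, and constructing alignments from truth
keeps tests hermetic and exactly reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import pysam

from .annotation_io import ContigAnnotation, GeneModel
from .assembly_io import ContigRecord, reverse_complement

DEFAULT_EXON_LEN = 300
DEFAULT_INTRON_LEN = 600


@dataclass
class TruthContig:
    name: str
    source: str
    start: int  # source coordinates, 0-based half-open
    end: int
    strand: str = "+"  # '-' if the assembly stores the reverse complement


@dataclass
class PlantedGene:
    gene_id: str
    source: str
    strand: str
    exons: list[tuple[int, int]]  # source coordinates

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class TruthTable:
    contigs: dict[str, TruthContig] = field(default_factory=dict)
    adjacencies: list[tuple[str, str]] = field(default_factory=list)
    genes: list[PlantedGene] = field(default_factory=list)

    def order_index(self) -> dict[str, tuple[str, int]]:
        """contig -> (source, position in the source tiling)."""
        by_src: dict[str, list[TruthContig]] = {}
        for tc in self.contigs.values():
            by_src.setdefault(tc.source, []).append(tc)
        out: dict[str, tuple[str, int]] = {}
        for src, tcs in by_src.items():
            for i, tc in enumerate(sorted(tcs, key=lambda t: t.start)):
                out[tc.name] = (src, i)
        return out

    def write_tsvs(self, prefix: str) -> None:
        with open(prefix + ".contigs.tsv", "w") as fh:
            fh.write("contig\tsource\tstart\tend\tstrand\n")
            for tc in self.contigs.values():
                fh.write(f"{tc.name}\t{tc.source}\t{tc.start}\t{tc.end}\t{tc.strand}\n")
        with open(prefix + ".adjacencies.tsv", "w") as fh:
            fh.write("left\tright\n")
            for a, b in self.adjacencies:
                fh.write(f"{a}\t{b}\n")
        with open(prefix + ".genes.tsv", "w") as fh:
            fh.write("gene_id\tsource\tstrand\texons\n")
            for g in self.genes:
                ex = ",".join(f"{s}-{e}" for s, e in g.exons)
                fh.write(f"{g.gene_id}\t{g.source}\t{g.strand}\t{ex}\n")


@dataclass
class SimulatedWorld:
    contigs: dict[str, ContigRecord]
    annotations: dict[str, ContigAnnotation]
    sam_records: list[tuple]  # raw mate tuples, rendered by write_sam
    truth: TruthTable
    sources: dict[str, str] = field(default_factory=dict)

    def write_sam(self, path: str) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": rec.length} for name, rec in self.contigs.items()
            ],
        }
        ref_ids = {name: i for i, name in enumerate(self.contigs)}
        with pysam.AlignmentFile(path, "wh", header=header) as fh:
            for (rid, c1, p1, s1, c2, p2, s2, rlen) in self.sam_records:
                for mate in (0, 1):
                    a = pysam.AlignedSegment(fh.header)
                    a.query_name = rid
                    me = (c1, p1, s1) if mate == 0 else (c2, p2, s2)
                    other = (c2, p2, s2) if mate == 0 else (c1, p1, s1)
                    a.reference_id = ref_ids[me[0]]
                    a.reference_start = me[1]
                    a.mapping_quality = 60
                    a.cigartuples = [(0, rlen)]
                    a.flag = (
                        0x1
                        | (0x40 if mate == 0 else 0x80)
                        | (0x10 if me[2] == "R" else 0)
                        | (0x20 if other[2] == "R" else 0)
                    )
                    a.next_reference_id = ref_ids[other[0]]
                    a.next_reference_start = other[1]
                    a.query_sequence = self.contigs[me[0]].sequence[me[1] : me[1] + rlen].upper()
                    a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
                    a.set_tag("NM", 0)
                    fh.write(a)

    def write_all(self, out_dir: str) -> dict[str, str]:
        """Write FASTA/GFF/SAM/truth files; returns the paths."""
        import os

        from .annotation_io import write_gff
        from .assembly_io import write_fasta

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "fasta": os.path.join(out_dir, "assembly.fa"),
            "gff": os.path.join(out_dir, "genes.gff3"),
            "sam": os.path.join(out_dir, "pairs.sam"),
            "truth_prefix": os.path.join(out_dir, "truth"),
        }
        write_fasta(self.contigs.values(), paths["fasta"])
        write_gff(self.annotations, paths["gff"])
        self.write_sam(paths["sam"])
        self.truth.write_tsvs(paths["truth_prefix"])
        return paths


class WorldBuilder:
    """Compose a synthetic world piece by piece (used by simulate_world and
    by tests that need bespoke layouts, e.g. read-through or flipped-contig
    scenarios)."""

    def __init__(self, seed: int = 0):
        self.rng = random.Random(seed)
        self.sources: dict[str, str] = {}
        self.genes: list[PlantedGene] = []
        self.breakpoints: dict[str, list[int]] = {}
        self.flipped: set[str] = set()
        self._pairs: list[tuple] = []
        self._pair_n = 0
        self.contig_names: dict[str, list[str]] = {}

    # -- world definition ---------------------------------------------------
    def add_source(self, name: str, length: Optional[int] = None, sequence: Optional[str] = None) -> None:
        if sequence is None:
            sequence = "".join(self.rng.choice("ACGT") for _ in range(length))
        self.sources[name] = sequence
        self.breakpoints[name] = []

    def plant_gene(self, source: str, exons: list[tuple[int, int]], gene_id: str, strand: str = "+") -> PlantedGene:
        g = PlantedGene(gene_id=gene_id, source=source, strand=strand, exons=sorted(exons))
        self.genes.append(g)
        return g

    def add_breakpoint(self, source: str, pos: int) -> None:
        self.breakpoints[source].append(pos)

    def flip_contig(self, contig_name: str) -> None:
        """Store this contig reverse-complemented in the emitted assembly."""
        self.flipped.add(contig_name)

    # -- derived layout -----------------------------------------------------
    def _tiles(self, source: str) -> list[tuple[str, int, int]]:
        cuts = sorted(set(self.breakpoints[source]))
        bounds = [0] + cuts + [len(self.sources[source])]
        names = self.contig_names.get(source)
        tiles = []
        for i, (s, e) in enumerate(zip(bounds, bounds[1:])):
            name = names[i] if names else f"{source}_c{i + 1}"
            tiles.append((name, s, e))
        return tiles

    def truth(self) -> TruthTable:
        t = TruthTable(genes=list(self.genes))
        for src in self.sources:
            tiles = self._tiles(src)
            for name, s, e in tiles:
                strand = "-" if name in self.flipped else "+"
                t.contigs[name] = TruthContig(name, src, s, e, strand)
            for (a, _, _), (b, _, _) in zip(tiles, tiles[1:]):
                t.adjacencies.append((a, b))
        return t

    def _locate(self, source: str, pos: int) -> tuple[str, int, int]:
        """(contig name, contig start in source, contig end) containing pos."""
        for name, s, e in self._tiles(source):
            if s <= pos < e:
                return name, s, e
        raise ValueError(f"position {pos} outside {source}")

    def source_to_contig(self, source: str, start: int, end: int, strand: str) -> tuple[str, int, str]:
        """Map a source-coordinate interval (must sit inside one contig) to
        (contig, contig-local start, local strand), honouring flips."""
        name, cs, ce = self._locate(source, start)
        if end > ce:
            raise ValueError("interval crosses a breakpoint")
        local = start - cs
        if name in self.flipped:
            clen = ce - cs
            local = clen - (end - cs)
            strand = "R" if strand == "F" else "F"
        return name, local, strand

    # -- read pairs ----------------------------------------------------------
    def add_pair_source_coords(
        self, source: str, m1: tuple[int, int], m2: tuple[int, int], read_len: int, read_id: Optional[str] = None
    ) -> None:
        """A fragment with forward mate at m1 and reverse mate at m2 (source
        coordinates); mates are mapped through the tiling and any flips."""
        self._pair_n += 1
        rid = read_id or f"pair_{self._pair_n:06d}"
        c1, p1, s1 = self.source_to_contig(source, m1[0], m1[1], "F")
        c2, p2, s2 = self.source_to_contig(source, m2[0], m2[1], "R")
        self._pairs.append((rid, c1, p1, s1, c2, p2, s2, read_len))

    def add_raw_pair(
        self, c1: str, p1: int, s1: str, c2: str, p2: int, s2: str, read_len: int, read_id: Optional[str] = None
    ) -> None:
        self._pair_n += 1
        rid = read_id or f"pair_{self._pair_n:06d}"
        self._pairs.append((rid, c1, p1, s1, c2, p2, s2, read_len))

    def span_breakpoint_pairs(
        self, gene: PlantedGene, breakpoint: int, n: int, read_len: int
    ) -> None:
        """n pairs straddling a breakpoint inside one of the gene's introns,
        one mate in each flanking exon."""
        left_exon = max((ex for ex in gene.exons if ex[1] <= breakpoint), key=lambda x: x[1])
        right_exon = min((ex for ex in gene.exons if ex[0] >= breakpoint), key=lambda x: x[0])
        for _ in range(n):
            max_j1 = left_exon[1] - left_exon[0] - read_len
            max_j2 = right_exon[1] - right_exon[0] - read_len
            if max_j1 < 0 or max_j2 < 0:
                raise ValueError("reads longer than exons: infeasible configuration")
            s1 = left_exon[0] + self.rng.randint(0, max_j1)
            s2 = right_exon[0] + self.rng.randint(0, max_j2)
            self.add_pair_source_coords(gene.source, (s1, s1 + read_len), (s2, s2 + read_len), read_len)

    # -- emission -------------------------------------------------------------
    def contigs(self) -> dict[str, ContigRecord]:
        out: dict[str, ContigRecord] = {}
        for src, seq in self.sources.items():
            for name, s, e in self._tiles(src):
                piece = seq[s:e]
                if name in self.flipped:
                    piece = reverse_complement(piece)
                out[name] = ContigRecord(name, piece)
        return out

    def annotations(self) -> dict[str, ContigAnnotation]:
        """Planted genes clipped to contigs: per-contig split gene models."""
        out: dict[str, ContigAnnotation] = {}
        for src in self.sources:
            tiles = self._tiles(src)
            for name, cs, ce in tiles:
                ann = ContigAnnotation(name)
                clen = ce - cs
                for g in (gg for gg in self.genes if gg.source == src):
                    clipped = [
                        (max(s, cs) - cs, min(e, ce) - cs)
                        for s, e in g.exons
                        if s < ce and e > cs
                    ]
                    clipped = [(s, e) for s, e in clipped if e > s]
                    if not clipped:
                        continue
                    strand = g.strand
                    if name in self.flipped:
                        clipped = sorted((clen - e, clen - s) for s, e in clipped)
                        strand = {"+": "-", "-": "+"}[strand]
                    whole = g.start >= cs and g.end <= ce
                    gid = g.gene_id if whole else f"{g.gene_id}_{name}"
                    ann.genes.append(
                        GeneModel(
                            gene_id=gid,
                            contig=name,
                            start=clipped[0][0],
                            end=clipped[-1][1],
                            strand=strand,
                            exons=clipped,
                        )
                    )
                if ann.genes:
                    ann.sort()
                    out[name] = ann
        return out

    def build(self) -> SimulatedWorld:
        return SimulatedWorld(
            contigs=self.contigs(),
            annotations=self.annotations(),
            sam_records=list(self._pairs),
            truth=self.truth(),
            sources=dict(self.sources),
        )


def simulate_world(
    n_sources: int = 2,
    source_len: int = 50_000,
    n_genes: int = 20,
    exons_per_gene: int = 4,
    frag_rate: float = 0.5,
    read_len: int = 75,
    pairs_per_junction: int = 5,
    noise_rate: float = 0.0,
    seed: int = 0,
    exon_len: int = DEFAULT_EXON_LEN,
    intron_len: int = DEFAULT_INTRON_LEN,
) -> SimulatedWorld:
    """Build the standard synthetic study world.

    Genes are laid out evenly along each source; every intron receives a
    breakpoint with probability ``frag_rate`` (at the intron midpoint), so all
    assembly breakpoints fall inside introns and every true adjacency is
    spanned by ``pairs_per_junction`` read pairs. ``noise_rate`` is the target
    fraction of chimeric pairs among all emitted pairs; each chimeric contig
    pair receives at most two supporting pairs, far below the default edge
    support threshold. Identical seeds give byte-identical outputs.
    """
    if exon_len < read_len:
        raise ValueError("reads longer than exons: infeasible configuration")
    if pairs_per_junction < 1:
        raise ValueError("pairs_per_junction must be >= 1")
    b = WorldBuilder(seed)
    footprint = exons_per_gene * exon_len + (exons_per_gene - 1) * intron_len
    per_source = [n_genes // n_sources] * n_sources
    for i in range(n_genes % n_sources):
        per_source[i] += 1
    gene_no = 0
    breaks: list[tuple[PlantedGene, int]] = []
    for si in range(n_sources):
        src = f"src{si + 1}"
        b.add_source(src, length=source_len)
        n_g = per_source[si]
        if n_g == 0:
            continue
        spacer = (source_len - n_g * footprint) // (n_g + 1)
        if spacer < 1:
            raise ValueError("sources too short for the requested gene layout")
        pos = spacer
        for _ in range(n_g):
            gene_no += 1
            exons = []
            p = pos
            for _e in range(exons_per_gene):
                exons.append((p, p + exon_len))
                p += exon_len + intron_len
            gene = b.plant_gene(src, exons, gene_id=f"gene_{gene_no:03d}")
            for (e1, e2) in zip(exons, exons[1:]):
                if b.rng.random() < frag_rate:
                    mid = (e1[1] + e2[0]) // 2
                    b.add_breakpoint(src, mid)
                    breaks.append((gene, mid))
            pos += footprint + spacer

    for gene, bp in breaks:
        b.span_breakpoint_pairs(gene, bp, pairs_per_junction, read_len)

    if noise_rate > 0:
        n_true = len(breaks) * pairs_per_junction
        n_noise = round(noise_rate * n_true / (1.0 - noise_rate))
        truth = b.truth()
        names = sorted(truth.contigs)
        adjacent = set(truth.adjacencies) | {(y, x) for x, y in truth.adjacencies}
        per_pair: dict[tuple[str, str], int] = {}
        emitted = 0
        while emitted < n_noise:
            c1, c2 = b.rng.sample(names, 2)
            if (c1, c2) in adjacent:
                continue
            key = tuple(sorted((c1, c2)))
            if per_pair.get(key, 0) >= 2:
                continue
            t1, t2 = truth.contigs[c1], truth.contigs[c2]
            p1 = b.rng.randint(0, (t1.end - t1.start) - read_len)
            p2 = b.rng.randint(0, (t2.end - t2.start) - read_len)
            s1 = b.rng.choice("FR")
            s2 = b.rng.choice("FR")
            emitted += 1
            per_pair[key] = per_pair.get(key, 0) + 1
            b.add_raw_pair(c1, p1, s1, c2, p2, s2, read_len, read_id=f"noise_{emitted:06d}")

    return b.build()


def three_exon_case(seed: int = 0) -> SimulatedWorld:
    """The adversarial skip-edge layout: one three-exon gene spanning contigs
    A, B, C (true order A-B-C) with edge supports dAB=3 < dAC=4 < dBC=5.

    Following the highest weights alone orders the contigs A,C,B; the
    gene-model reconciliation must recover A-B-C.
    """
    b = WorldBuilder(seed)
    exon_len, intron_len, read_len = 400, 800, 75
    src = "srcX"
    b.add_source(src, length=3 * exon_len + 2 * intron_len + 400)
    exons = []
    p = 100
    for _ in range(3):
        exons.append((p, p + exon_len))
        p += exon_len + intron_len
    gene = b.plant_gene(src, exons, gene_id="gene_3x")
    cut1 = (exons[0][1] + exons[1][0]) // 2
    cut2 = (exons[1][1] + exons[2][0]) // 2
    b.add_breakpoint(src, cut1)
    b.add_breakpoint(src, cut2)
    b.contig_names[src] = ["A", "B", "C"]
    # dAB = 3 (exon1<->exon2), dBC = 5 (exon2<->exon3), dAC = 4 (exon1<->exon3)
    b.span_breakpoint_pairs(gene, cut1, 3, read_len)
    b.span_breakpoint_pairs(gene, cut2, 5, read_len)
    for _ in range(4):
        s1 = exons[0][0] + b.rng.randint(0, exon_len - read_len)
        s2 = exons[2][0] + b.rng.randint(0, exon_len - read_len)
        b.add_pair_source_coords(src, (s1, s1 + read_len), (s2, s2 + read_len), read_len)
    return b.build()
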