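"""Denoise joining-pairs against terminal gene models.

A read pair comes from one cDNA fragment, so the two contigs it joins must be
connectable with *zero intervening gene models*: each mate must overlap the
gene model at the edge of its contig (the 5'-most or 3'-most gene), or map
outside the terminal genes toward a contig edge (in which case an artificial
gene model is created there). Mates that land strictly between the terminal
genes are evidence of paralogy/repeats and the pair is discarded.

Because mates of a fragment face each other, the end label must agree with
the mate's strand: a mate at a contig's 3' edge must point off that edge
(forward), one at the 5' edge must point reverse. Exactly four of the sixteen
(label, strand)^2 states survive:

    (3,F)+(5,R)  -> contigs joined as  +,+
    (3,F)+(3,F)  -> second contig reverse-complemented  (+,-)
    (5,R)+(5,R)  -> first contig reverse-complemented   (-,+)
    (5,R)+(3,F)  -> both reverse-complemented           (-,-)

Surviving pairs are aggregated per unordered contig pair into edge
candidates; the (end-label combo, connecting gene pair) signature is taken by
strict majority, disagreeing pairs are excluded from the weight, and an exact
tie drops the candidate.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional

from .alignment_ingest import JoiningPair, ReadEnd
from .annotation_io import ContigAnnotation, GeneModel, make_artificial_gene, terminal_genes

logger = logging.getLogger(__name__)

VALID_END_STATES = {(3, "F"), (5, "R")}


@dataclass
class EdgeCandidate:
    """A contig pair supported by agreeing joining-pairs."""

    contig_a: str  # lexicographically smaller name
    contig_b: str
    side_a: int  # 5 or 3: which end of contig_a faces the junction
    side_b: int
    gene_a: str  # connecting gene-model id on contig_a
    gene_b: str
    weight: int
    pairs: list[JoiningPair] = field(default_factory=list)

    def side_of(self, contig: str) -> int:
        return self.side_a if contig == self.contig_a else self.side_b

    def gene_of(self, contig: str) -> str:
        return self.gene_a if contig == self.contig_a else self.gene_b

    def other(self, contig: str) -> str:
        return self.contig_b if contig == self.contig_a else self.contig_a


@dataclass
class ArtificialGeneRegistry:
    """One artificial gene model per (contig, side), extended by union.

    Artificial models never displace the input terminal genes during
    labelling; they exist so the junction has a concrete connecting model and
    so unused ones can be discarded from the final annotation.
    """

    contig_lengths: dict[str, int]
    annotations: dict[str, ContigAnnotation]
    models: dict[tuple[str, int], GeneModel] = field(default_factory=dict)
    _counters: dict[str, int] = field(default_factory=dict)

    def get_or_create(self, contig: str, side: int, interval: tuple[int, int]) -> GeneModel:
        key = (contig, side)
        if key in self.models:
            m = self.models[key]
            s = min(m.start, interval[0])
            e = max(m.end, interval[1])
            m.start, m.end = s, e
            m.exons = [(s, e)]
            return m
        n = self._counters.get(contig, 0) + 1
        self._counters[contig] = n
        model = make_artificial_gene(
            contig,
            self.contig_lengths[contig],
            interval,
            side,
            self.annotations.get(contig),
            n,
        )
        self.models[key] = model
        return model


@dataclass
class DenoiseResult:
    retained: list[JoiningPair]
    edges: list[EdgeCandidate]
    rejected_assign: int
    rejected_orientation: int
    minority_dropped: int
    tie_dropped: int
    registry: ArtificialGeneRegistry
    rejections: list[tuple[str, str]] = field(default_factory=list)  # (read_id, reason)

    def counts(self) -> dict:
        return {
            "retained": len(self.retained),
            "rejected_assign": self.rejected_assign,
            "rejected_orientation": self.rejected_orientation,
            "minority_dropped": self.minority_dropped,
            "tie_dropped": self.tie_dropped,
            "artificial_created": len(self.registry.models),
        }


def assign_labels(
    pair: JoiningPair,
    annotations: dict[str, ContigAnnotation],
    registry: ArtificialGeneRegistry,
) -> bool:
    """Label both ends of a pair as 5 or 3; return False to reject the pair.

    An end overlapping the 5'-most / 3'-most terminal gene gets label 5 / 3;
    on a single-gene contig the strand decides (F -> 3, R -> 5). An end
    outside the terminal genes toward an edge gets an artificial model on that
    side; an end strictly between the terminal genes rejects the pair.
    """
    for end in pair.ends():
        if not _assign_end(end, annotations, registry):
            return False
    return True


def _assign_end(
    end: ReadEnd,
    annotations: dict[str, ContigAnnotation],
    registry: ArtificialGeneRegistry,
) -> bool:
    five, three = terminal_genes(annotations.get(end.contig))
    if five is None:
        # gene-less contig: allow scaffolding via an artificial model; the
        # mate's strand picks the side it can validly face.
        side = 3 if end.strand == "F" else 5
        model = registry.get_or_create(end.contig, side, (end.start, end.end))
        end.label, end.gene = side, model.gene_id
        return True
    ov5 = five.overlaps(end.start, end.end)
    ov3 = three.overlaps(end.start, end.end)
    if ov5 and ov3:
        # single gene (or overlapping terminals): label resolved by strand so
        # the end is valid whenever possible
        label = 3 if end.strand == "F" else 5
        end.label = label
        end.gene = (three if label == 3 else five).gene_id
        return True
    if ov3:
        end.label, end.gene = 3, three.gene_id
        return True
    if ov5:
        end.label, end.gene = 5, five.gene_id
        return True
    if end.end <= five.start:
        model = registry.get_or_create(end.contig, 5, (end.start, end.end))
        end.label, end.gene = 5, model.gene_id
        return True
    if end.start >= three.end:
        model = registry.get_or_create(end.contig, 3, (end.start, end.end))
        end.label, end.gene = 3, model.gene_id
        return True
    return False  # strictly between terminal genes


def orientation_filter(pair: JoiningPair) -> bool:
    """Keep the pair iff both ends are in a valid (label, strand) state."""
    return all((e.label, e.strand) in VALID_END_STATES for e in pair.ends())


def build_edge_candidates(pairs: list[JoiningPair]) -> tuple[list[EdgeCandidate], int, int]:
    """Aggregate retained pairs into per-contig-pair edge candidates.

    Returns (candidates, minority_dropped, tie_dropped_pairs).
    """
    groups: dict[tuple[str, str], list[JoiningPair]] = defaultdict(list)
    for p in pairs:
        key = tuple(sorted((p.left.contig, p.right.contig)))
        groups[key].append(p)

    edges: list[EdgeCandidate] = []
    minority = 0
    tie_dropped = 0
    for (a, b), members in sorted(groups.items()):
        sigs = Counter()
        by_sig: dict[tuple, list[JoiningPair]] = defaultdict(list)
        for p in members:
            ea, eb = (p.left, p.right) if p.left.contig == a else (p.right, p.left)
            sig = (ea.label, eb.label, ea.gene, eb.gene)
            sigs[sig] += 1
            by_sig[sig].append(p)
        ranked = sigs.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            tie_dropped += len(members)
            logger.info("edge %s-%s dropped: tied end-state signatures", a, b)
            continue
        sig, weight = ranked[0]
        minority += len(members) - weight
        edges.append(
            EdgeCandidate(
                contig_a=a,
                contig_b=b,
                side_a=sig[0],
                side_b=sig[1],
                gene_a=sig[2],
                gene_b=sig[3],
                weight=weight,
                pairs=by_sig[sig],
            )
        )
    return edges, minority, tie_dropped


def denoise(
    pairs: list[JoiningPair],
    annotations: dict[str, ContigAnnotation],
    contig_lengths: dict[str, int],
) -> DenoiseResult:
    """Full denoising pass: label, orientation-filter, aggregate."""
    registry = ArtificialGeneRegistry(contig_lengths, annotations)
    retained: list[JoiningPair] = []
    rej_assign = rej_orient = 0
    rejections: list[tuple[str, str]] = []
    for p in pairs:
        if not assign_labels(p, annotations, registry):
            rej_assign += 1
            rejections.append((p.read_id, "between_terminal_genes"))
            continue
        if not orientation_filter(p):
            rej_orient += 1
            rejections.append((p.read_id, "invalid_end_orientation"))
            continue
        retained.append(p)
    edges, minority, ties = build_edge_candidates(retained)
    return DenoiseResult(
        retained=retained,
        edges=edges,
        rejected_assign=rej_assign,
        rejected_orientation=rej_orient,
        minority_dropped=minority,
        tie_dropped=ties,
        registry=registry,
        rejections=rejections,
    )
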