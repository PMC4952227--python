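"""Reconcile candidate paths with gene-model constraints and select winners.

A greedy walk can order contigs so that joining them would place gene models
between the two connecting genes — e.g. with true order A-B-C and edge
supports dAB < dAC < dBC the greedy walk gives A,C,B. Reconciliation walks a
candidate path and truncates it at the first step that would (a) re-use a
contig end already consumed by the previous junction, or (b) connect through
a gene that is not the terminal (or registered artificial) model on the
facing side. Re-walking the subgraph from other start vertices and keeping
the reconciled path with the most vertices recovers the true order, so
reconciliation doubles as a reordering step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .annotation_io import ContigAnnotation, terminal_genes
from .denoiser import ArtificialGeneRegistry, EdgeCandidate
from .scaffold_graph import CandidatePath, WeightedGraph, enumerate_candidates

logger = logging.getLogger(__name__)


@dataclass
class Junction:
    left_contig: str
    right_contig: str
    side_left: int  # contig-local end (5/3) consumed on the left contig
    side_right: int
    gene_left: str
    gene_right: str
    weight: int
    pairs: list = field(default_factory=list)


@dataclass
class ScaffoldPath:
    entries: list[tuple[str, str]]  # (contig, orientation '+'/'-')
    junctions: list[Junction]
    start_vertex: str = ""

    @property
    def contigs(self) -> list[str]:
        return [c for c, _ in self.entries]

    @property
    def total_weight(self) -> int:
        return sum(j.weight for j in self.junctions)

    def __len__(self) -> int:
        return len(self.entries)

    def flipped(self) -> "ScaffoldPath":
        """Whole-path reverse complement: an equivalent, valid scaffold."""
        entries = [(c, "-" if o == "+" else "+") for c, o in reversed(self.entries)]
        junctions = [
            Junction(
                left_contig=j.right_contig,
                right_contig=j.left_contig,
                side_left=j.side_right,
                side_right=j.side_left,
                gene_left=j.gene_right,
                gene_right=j.gene_left,
                weight=j.weight,
                pairs=j.pairs,
            )
            for j in reversed(self.junctions)
        ]
        return ScaffoldPath(entries=entries, junctions=junctions, start_vertex=self.start_vertex)


def _legal_genes(
    contig: str,
    side: int,
    annotations: dict[str, ContigAnnotation],
    registry: Optional[ArtificialGeneRegistry],
) -> set:
    """Gene ids allowed to connect at a given contig end."""
    ids = set()
    five, three = terminal_genes(annotations.get(contig))
    if side == 5 and five is not None:
        ids.add(five.gene_id)
    if side == 3 and three is not None:
        ids.add(three.gene_id)
    if registry is not None and (contig, side) in registry.models:
        ids.add(registry.models[(contig, side)].gene_id)
    return ids


def _orient_exit(side: int) -> str:
    # side facing the NEXT contig: 3 (right end) faces forward unflipped
    return "+" if side == 3 else "-"


def _orient_entry(side: int) -> str:
    # side facing the PREVIOUS contig: 5 (left end) faces backward unflipped
    return "+" if side == 5 else "-"


def reconcile(
    path: CandidatePath,
    annotations: dict[str, ContigAnnotation],
    registry: Optional[ArtificialGeneRegistry] = None,
    enforce: bool = True,
) -> ScaffoldPath:
    """Validate/truncate a candidate path; induce contig orientations.

    With ``enforce=False`` no legality checks are applied (the raw greedy
    order is materialized); this exists to demonstrate the errors the
    constraint prevents, and for comparisons with unconstrained traversal.
    """
    verts = path.vertices
    if not verts:
        raise ValueError("empty candidate path")
    entries: list[tuple[str, str]] = []
    junctions: list[Junction] = []
    entry_side: Optional[int] = None  # side of the current vertex already consumed
    for i, edge in enumerate(path.edges):
        u, v = verts[i], verts[i + 1]
        s_u, s_v = edge.side_of(u), edge.side_of(v)
        if enforce:
            if entry_side is not None and s_u == entry_side:
                break  # this end of u was consumed by the previous junction
            if edge.gene_of(u) not in _legal_genes(u, s_u, annotations, registry):
                break
            if edge.gene_of(v) not in _legal_genes(v, s_v, annotations, registry):
                break
        if not entries:
            entries.append((u, _orient_exit(s_u)))
        entries.append((v, _orient_entry(s_v)))
        junctions.append(
            Junction(
                left_contig=u,
                right_contig=v,
                side_left=s_u,
                side_right=s_v,
                gene_left=edge.gene_of(u),
                gene_right=edge.gene_of(v),
                weight=edge.weight,
                pairs=edge.pairs,
            )
        )
        entry_side = s_v
    if not entries:
        entries = [(verts[0], "+")]
    result = ScaffoldPath(entries=entries, junctions=junctions, start_vertex=path.start_vertex)
    # canonical orientation: never start a scaffold with a flipped contig
    if result.entries[0][1] == "-":
        result = result.flipped()
    return result


def select_best(
    group: list[CandidatePath],
    annotations: dict[str, ContigAnnotation],
    registry: Optional[ArtificialGeneRegistry] = None,
    enforce: bool = True,
) -> ScaffoldPath:
    """Reconcile candidates in order; return the best reconciled path.

    A path incorporating every vertex of the group is optimal and returned
    immediately, skipping remaining candidates. Otherwise the path with the
    most vertices wins; ties go to the highest total weight, then to the
    first in the list.
    """
    if not group:
        raise ValueError("empty candidate group")
    all_vertices = set()
    for cand in group:
        all_vertices.update(cand.vertices)
    best: Optional[ScaffoldPath] = None
    for cand in group:
        rec = reconcile(cand, annotations, registry, enforce=enforce)
        if len(rec) == len(all_vertices):
            return rec
        if best is None or (len(rec), rec.total_weight) > (len(best), best.total_weight):
            best = rec
    return best


def commit_paths(
    graph: WeightedGraph,
    annotations: dict[str, ContigAnnotation],
    registry: Optional[ArtificialGeneRegistry] = None,
    enforce: bool = True,
) -> list[ScaffoldPath]:
    """Drive group enumeration/selection to a globally consistent result.

    Vertices of each committed path are marked visited; remaining subgraphs
    are re-walked (excluding visited vertices) until no component yields a
    path of two or more contigs. No contig ever appears in more than one
    committed path.
    """
    visited: set = set()
    blocked: set = set()
    committed: list[ScaffoldPath] = []
    while True:
        groups = enumerate_candidates(graph, exclude=visited | blocked)
        # deterministic processing order: longest best candidate first, then
        # lexicographic first contig
        groups.sort(key=lambda g: (-max(len(c) for c in g), min(c.vertices[0] for c in g)))
        progressed = False
        for group in groups:
            group_vertices = set()
            for c in group:
                group_vertices.update(c.vertices)
            if group_vertices & (visited | blocked):
                continue  # stale: re-walk next round against updated exclusions
            best = select_best(group, annotations, registry, enforce=enforce)
            if len(best) >= 2:
                committed.append(best)
                visited.update(best.contigs)
                progressed = True
            else:
                blocked.update(group_vertices)
                logger.info("component %s yielded no joinable path", sorted(group_vertices))
        if not progressed:
            break
    return committed
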