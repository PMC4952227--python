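"""Score scaffolding output against a ground truth and classify junctions.

Scaffolding accuracy is reported as counts of inter-chromosomal errors
(junction joins contigs from different source sequences), intra-chromosomal
errors (same source but wrong order/orientation), and repeated placements,
plus N50 of the final assembly. Junctions are also classified against a
reference annotation in source coordinates:

    Case 1  both mates inside the same reference gene (exons of one gene)
    Case 2  exactly one mate inside a gene (suggests an unannotated exon)
    Case 3  mates inside two different genes (gene merge or read-through)
    Case 4  neither mate inside a gene (possible novel gene)

Cases 2-4 on truth-consecutive contig pairs are informative findings, not
false positives, and are never added to the error counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .fixtures import TruthTable
from .reconciler import ScaffoldPath

_SIGN = {("+", "+"): "+", ("-", "-"): "+", ("+", "-"): "-", ("-", "+"): "-"}


@dataclass
class ScaffoldingScore:
    inter_chromosomal_errors: int = 0
    intra_chromosomal_errors: int = 0
    orientation_only_errors: int = 0  # sub-count of intra errors
    repeated_placements: int = 0
    contigs_scaffolded: int = 0
    scaffold_count: int = 0
    n50: int = 0
    junctions: int = 0
    true_adjacencies: int = 0
    adjacencies_recovered: int = 0

    @property
    def adjacency_recall(self) -> float:
        if not self.true_adjacencies:
            return float("nan")
        return self.adjacencies_recovered / self.true_adjacencies

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["adjacency_recall"] = self.adjacency_recall
        return d


def n50(lengths: Iterable[int]) -> int:
    """Length L such that sequences of length >= L cover half the total."""
    ls = sorted(lengths, reverse=True)
    if not ls:
        return 0
    half = sum(ls) / 2
    acc = 0
    for l in ls:
        acc += l
        if acc >= half:
            return l
    return ls[-1]


def _junction_consistent(truth: TruthTable, idx, u, ou, v, ov) -> tuple[bool, bool]:
    """(consistent, truth_adjacent) for a junction u(ou) -> v(ov)."""
    tu, tv = truth.contigs[u], truth.contigs[v]
    su, iu = idx[u]
    sv, iv = idx[v]
    adjacent = su == sv and abs(iu - iv) == 1
    e_u = _SIGN[(ou, tu.strand)]
    e_v = _SIGN[(ov, tv.strand)]
    consistent = (
        su == sv
        and e_u == e_v
        and ((e_u == "+" and iv == iu + 1) or (e_u == "-" and iu == iv + 1))
    )
    return consistent, adjacent


def score_scaffolding(
    paths: list[ScaffoldPath],
    truth: TruthTable,
    final_lengths: Iterable[int] = (),
) -> ScaffoldingScore:
    """Compare committed scaffold paths against the truth tiling.

    ``final_lengths`` are the sequence lengths of the final assembly
    (scaffolds plus leftover contigs) used for N50.
    """
    idx = truth.order_index()
    score = ScaffoldingScore()
    seen: Counter = Counter()
    recovered: set[tuple[str, str]] = set()
    adj_set = set(truth.adjacencies)
    for path in paths:
        for c, _ in path.entries:
            if c not in truth.contigs:
                raise KeyError(f"contig {c!r} not in truth")
            seen[c] += 1
        for (u, ou), (v, ov) in zip(path.entries, path.entries[1:]):
            score.junctions += 1
            tu, tv = truth.contigs[u], truth.contigs[v]
            if tu.source != tv.source:
                score.inter_chromosomal_errors += 1
                continue
            consistent, adjacent = _junction_consistent(truth, idx, u, ou, v, ov)
            if consistent:
                recovered.add((u, v) if (u, v) in adj_set else (v, u))
            else:
                score.intra_chromosomal_errors += 1
                if adjacent:
                    score.orientation_only_errors += 1
    score.repeated_placements = sum(c - 1 for c in seen.values() if c > 1)
    score.contigs_scaffolded = len(seen)
    score.scaffold_count = len(paths)
    score.n50 = n50(final_lengths)
    score.true_adjacencies = len(truth.adjacencies)
    score.adjacencies_recovered = len(recovered & adj_set)
    return score


@dataclass
class JunctionCase:
    left_contig: str
    right_contig: str
    case: int  # 1..4
    consecutive: bool
    gene_left: str | None = None
    gene_right: str | None = None


def _lift_to_source(truth: TruthTable, contig: str, start: int, end: int) -> tuple[str, int, int]:
    tc = truth.contigs[contig]
    if tc.strand == "+":
        return tc.source, tc.start + start, tc.start + end
    clen = tc.end - tc.start
    return tc.source, tc.start + (clen - end), tc.start + (clen - start)


def _gene_at(truth: TruthTable, source: str, start: int, end: int):
    for g in truth.genes:
        if g.source == source and start < g.end and end > g.start:
            return g
    return None


def classify_junction_cases(
    paths: list[ScaffoldPath], truth: TruthTable
) -> list[JunctionCase]:
    """Classify every junction into Cases 1-4 against the reference genes.

    Each supporting read pair's mate intervals are lifted to source
    coordinates via the truth tiling; the junction takes the modal case over
    its supporting pairs (ties resolved toward the lower case number).
    """
    idx = truth.order_index()
    out: list[JunctionCase] = []
    for path in paths:
        for j in path.junctions:
            votes: Counter = Counter()
            rep: dict[int, tuple] = {}
            for p in j.pairs:
                genes = []
                for end in p.ends():
                    src, s, e = _lift_to_source(truth, end.contig, end.start, end.end)
                    genes.append(_gene_at(truth, src, s, e))
                ga, gb = genes
                if ga is not None and gb is not None:
                    case = 1 if ga.gene_id == gb.gene_id else 3
                elif ga is None and gb is None:
                    case = 4
                else:
                    case = 2
                votes[case] += 1
                rep.setdefault(case, (ga, gb))
            if not votes:
                continue
            top = min(
                votes, key=lambda c: (-votes[c], c)
            )
            ga, gb = rep[top]
            su, iu = idx[j.left_contig]
            sv, iv = idx[j.right_contig]
            out.append(
                JunctionCase(
                    left_contig=j.left_contig,
                    right_contig=j.right_contig,
                    case=top,
                    consecutive=(su == sv and abs(iu - iv) == 1),
                    gene_left=ga.gene_id if ga else None,
                    gene_right=gb.gene_id if gb else None,
                )
            )
    return out
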