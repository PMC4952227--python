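"""Extract joining-pairs from SAM/BAM alignments.

A joining-pair is a read pair whose two mates align to *different* reference
sequences. These pairs are the evidence units for RNA-seq scaffolding: a cDNA
fragment spanning an intron that contains an assembly breakpoint puts its two
mates on two different contigs. Pairs are retained only when both mates are
uniquely mapped (MAPQ > 0) and pass per-mate mismatch-fraction and
alignment-length-fraction filters.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

import pysam

logger = logging.getLogger(__name__)

# CIGAR operation codes consuming query bases in an aligned (non-clipped) way
_ALN_OPS = {0, 7, 8}  # M, =, X


@dataclass
class ReadEnd:
    """One mate of a joining-pair, as aligned to its contig."""

    contig: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # 'F' or 'R'
    mapq: int
    mismatches: int
    aln_len: int
    read_len: int
    label: Optional[int] = None  # 5, 3 or None (unassigned)
    gene: Optional[str] = None  # connecting gene-model id


@dataclass
class JoiningPair:
    read_id: str
    left: ReadEnd
    right: ReadEnd

    def ends(self) -> tuple[ReadEnd, ReadEnd]:
        return self.left, self.right


@dataclass
class ExtractionStats:
    total_pairs_seen: int = 0
    same_contig: int = 0
    unmapped_or_unpaired: int = 0
    non_unique: int = 0  # MAPQ 0 on either mate, or multiple primary records
    failed_frac_mm: int = 0
    failed_frac_ovl: int = 0
    retained: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _mate_metrics(rec: pysam.AlignedSegment) -> tuple[int, int, int]:
    """(mismatches, aln_len, read_len) for one alignment record."""
    aln_len = sum(l for op, l in (rec.cigartuples or []) if op in _ALN_OPS)
    read_len = rec.infer_read_length() or rec.query_length or aln_len
    if rec.has_tag("NM"):
        nm = int(rec.get_tag("NM"))
    else:
        # fall back to explicit mismatch/indel CIGAR evidence
        nm = sum(l for op, l in (rec.cigartuples or []) if op in (1, 2, 8))
        logger.warning("record %s lacks NM tag; using CIGAR-derived count %d", rec.query_name, nm)
    return nm, aln_len, read_len


def _to_end(rec: pysam.AlignedSegment) -> ReadEnd:
    nm, aln_len, read_len = _mate_metrics(rec)
    return ReadEnd(
        contig=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        strand="R" if rec.is_reverse else "F",
        mapq=rec.mapping_quality,
        mismatches=nm,
        aln_len=aln_len,
        read_len=read_len,
    )


def extract_joining_pairs(
    alignment_path: str,
    max_frac_mm: float = 0.05,
    min_frac_ovl: float = 0.70,
) -> tuple[list[JoiningPair], ExtractionStats]:
    """Stream a SAM/BAM file and return filtered joining-pairs.

    A pair is retained iff both mates are mapped to different references, both
    have MAPQ > 0, each mate's mismatches/aln_len <= max_frac_mm and each
    mate's aln_len/read_len >= min_frac_ovl. Setting max_frac_mm=1.0 and
    min_frac_ovl=0.0 disables the two fraction filters. Secondary and
    supplementary records are ignored; input need not be sorted.
    """
    stats = ExtractionStats()
    # buffer primary records by read id: [first-mate records, second-mate records]
    buf: dict[str, tuple[list, list]] = defaultdict(lambda: ([], []))
    mode = "rb" if alignment_path.endswith(".bam") else "r"
    with pysam.AlignmentFile(alignment_path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.is_paired:
                stats.unmapped_or_unpaired += 1
                continue
            slot = 0 if rec.is_read1 else 1
            buf[rec.query_name][slot].append(rec)

    pairs: list[JoiningPair] = []
    for qname in buf:
        firsts, seconds = buf[qname]
        stats.total_pairs_seen += 1
        if len(firsts) > 1 or len(seconds) > 1:
            stats.non_unique += 1  # multiple primary-looking records
            continue
        if not firsts or not seconds:
            stats.unmapped_or_unpaired += 1
            continue
        r1, r2 = firsts[0], seconds[0]
        if r1.is_unmapped or r2.is_unmapped:
            stats.unmapped_or_unpaired += 1
            continue
        if r1.reference_name == r2.reference_name:
            stats.same_contig += 1
            continue
        if r1.mapping_quality == 0 or r2.mapping_quality == 0:
            stats.non_unique += 1
            continue
        ends = [_to_end(r1), _to_end(r2)]
        if any(e.aln_len == 0 or e.mismatches / e.aln_len > max_frac_mm for e in ends):
            stats.failed_frac_mm += 1
            continue
        if any(e.read_len == 0 or e.aln_len / e.read_len < min_frac_ovl for e in ends):
            stats.failed_frac_ovl += 1
            continue
        pairs.append(JoiningPair(read_id=qname, left=ends[0], right=ends[1]))
        stats.retained += 1

    if stats.retained == 0 and stats.total_pairs_seen:
        logger.warning("no joining-pairs retained from %s", alignment_path)
    logger.info("joining-pair extraction: %s", stats.as_dict())
    # deterministic output order regardless of file record order
    pairs.sort(key=lambda p: p.read_id)
    return pairs, stats


def pair_stats(pairs: list[JoiningPair]) -> dict[frozenset, int]:
    """Number of supporting joining-pairs per unordered contig pair."""
    counts: dict[frozenset, int] = defaultdict(int)
    for p in pairs:
        counts[frozenset((p.left.contig, p.right.contig))] += 1
    return dict(counts)
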