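"""FASTA assembly I/O and scaffold splitting.

An assembly is an ordered mapping of contig name -> :class:`ContigRecord`.
Scaffolded assemblies can be reduced to contig form by breaking them at runs
of N characters; the :class:`SplitMap` records enough information to
reconstruct every source scaffold byte-for-byte and to compare an RNA-based
re-scaffolding against the original one.

All internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ContigRecord:
    """A named assembly sequence, optionally tracking its source scaffold."""

    name: str
    sequence: str
    # (source_scaffold_name, start_offset, end_offset) if this contig was
    # produced by splitting a scaffold at gaps.
    origin: Optional[tuple[str, int, int]] = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.name!r} has an empty sequence")
        if self.origin is not None:
            src, s, e = self.origin
            if e - s != len(self.sequence):
                raise ValueError(
                    f"contig {self.name!r}: origin span {src}:{s}-{e} does not "
                    f"match sequence length {len(self.sequence)}"
                )


@dataclass
class SplitMapEntry:
    source_scaffold: str
    part_index: int
    contig_name: str
    start_offset: int
    end_offset: int
    gap_length_following: int  # 0 for the last part of a scaffold


@dataclass
class SplitMap:
    """Ordered record of how scaffolds were broken into parts."""

    entries: list[SplitMapEntry] = field(default_factory=list)
    # N-run length before the first part of each scaffold (usually 0)
    leading_gaps: dict[str, int] = field(default_factory=dict)

    def parts_of(self, source: str) -> list[SplitMapEntry]:
        return [e for e in self.entries if e.source_scaffold == source]

    def sources(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.source_scaffold, None)
        return list(seen)

    def adjacent_part_pairs(self) -> list[tuple[str, str]]:
        """(left_part, right_part) for consecutive parts of each scaffold."""
        out = []
        for src in self.sources():
            parts = self.parts_of(src)
            for a, b in zip(parts, parts[1:]):
                out.append((a.contig_name, b.contig_name))
        return out

    def rejoin(self, contigs: dict[str, "ContigRecord"]) -> dict[str, str]:
        """Reconstruct source scaffold sequences from their parts + gaps."""
        out: dict[str, str] = {}
        for src in self.sources():
            chunks: list[str] = []
            lead = self.leading_gaps.get(src, 0)
            if lead:
                chunks.append("N" * lead)
            for e in self.parts_of(src):
                chunks.append(contigs[e.contig_name].sequence)
                if e.gap_length_following:
                    chunks.append("N" * e.gap_length_following)
            out[src] = "".join(chunks)
        return out

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("source\tpart_index\tcontig\tstart\tend\tgap_after\n")
            for e in self.entries:
                fh.write(
                    f"{e.source_scaffold}\t{e.part_index}\t{e.contig_name}\t"
                    f"{e.start_offset}\t{e.end_offset}\t{e.gap_length_following}\n"
                )


def read_fasta(path: str) -> dict[str, ContigRecord]:
    """Read a FASTA assembly into an ordered name -> ContigRecord mapping.

    The header token before the first whitespace is the contig name. Duplicate
    names and empty sequences are hard errors.
    """
    records: dict[str, ContigRecord] = {}
    for rec in SeqIO.parse(path, "fasta"):
        name = rec.id
        if name in records:
            raise ValueError(f"duplicate sequence name in {path}: {name!r}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for {name!r} in {path}")
        records[name] = ContigRecord(name=name, sequence=seq)
    return records


def write_fasta(records: Iterable[ContigRecord], path: str, line_width: int = 60) -> None:
    """Write records as wrapped FASTA. Round-trips exactly through read_fasta."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            s = rec.sequence
            for i in range(0, len(s), line_width):
                fh.write(s[i : i + line_width] + "\n")


def split_scaffolds(
    assembly: dict[str, ContigRecord], min_gap_len: int = 25
) -> tuple[dict[str, ContigRecord], SplitMap]:
    """Break every scaffold at maximal N-runs of length >= min_gap_len.

    Parts are named ``<source>_p<index>`` (1-based). Runs shorter than
    min_gap_len stay inside parts; a gap touching a sequence boundary yields
    no empty part. Sequences with no qualifying gap pass through unchanged
    (original name kept, still recorded in the SplitMap as a single part).
    """
    if min_gap_len < 1:
        raise ValueError("min_gap_len must be >= 1")
    gap_re = re.compile(r"[Nn]{%d,}" % min_gap_len)
    out: dict[str, ContigRecord] = {}
    smap = SplitMap()
    for name, rec in assembly.items():
        seq = rec.sequence
        # part spans = maximal stretches between qualifying gap runs; gaps at
        # the boundaries produce no empty parts but their lengths are kept so
        # rejoin() is byte-exact.
        spans: list[tuple[int, int]] = []
        prev = 0
        leading = 0
        for m in gap_re.finditer(seq):
            if m.start() > prev:
                spans.append((prev, m.start()))
            elif prev == 0:
                leading = m.end() - m.start()
            prev = m.end()
        if prev < len(seq):
            spans.append((prev, len(seq)))
        if not spans:  # all-N scaffold: keep it intact rather than vanish
            out[name] = rec
            smap.entries.append(SplitMapEntry(name, 1, name, 0, len(seq), 0))
            continue
        if len(spans) == 1 and spans[0] == (0, len(seq)):
            out[name] = rec
            smap.entries.append(SplitMapEntry(name, 1, name, 0, len(seq), 0))
            continue
        if leading:
            smap.leading_gaps[name] = leading
        for idx, (s, e) in enumerate(spans, start=1):
            nxt = spans[idx][0] if idx < len(spans) else len(seq)
            pname = f"{name}_p{idx}"
            out[pname] = ContigRecord(pname, seq[s:e], origin=(name, s, e))
            smap.entries.append(SplitMapEntry(name, idx, pname, s, e, nxt - e))
    return out, smap
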