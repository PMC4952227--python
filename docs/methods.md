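# Methods

This note describes the model and procedure implemented by `rnascaf`, the
assumptions behind them, and the numerical choices that make runs
deterministic and auditable.

## Problem statement

Given

- a fragmented assembly *A* = {c₁ … cₙ} (FASTA),
- gene models on those contigs (GFF3, one model per contig fragment of a
  gene), and
- paired-end RNA-seq reads aligned to *A* (SAM/BAM, mates may map to
  different contigs),

produce an updated assembly in which contigs connected by transcript evidence
are ordered, oriented and joined, and an updated annotation in which the
corresponding split gene models are merged — with exact accounting of every
read pair and every sequence.

## 1. Joining-pair extraction (`alignment_ingest`)

A **joining-pair** is a read pair whose mates align to different contigs,
with both mates passing, per mate:

- uniquely mapped primary alignment with MAPQ > 0 (a read with more than one
  primary record is discarded as non-unique);
- mismatch fraction `NM / aligned_len` ≤ `max_frac_mm` (default **0.05**);
- aligned fraction `aligned_len / read_len` ≥ `min_frac_ovl` (default
  **0.70**).

Setting `max_frac_mm=1.0` / `min_frac_ovl=0.0` disables the respective
filter (useful for simulated, error-free reads). Every discarded record is
counted by reason in the extraction statistics.

## 2. End labelling and denoising (`denoiser`)

Transcripts run 5′→3′, so a mate that genuinely bridges two contigs must sit
in a *terminal* gene of its contig — the gene closest to the contig end that
faces the junction. Each mate is labelled:

- **3** if it overlaps the 3′-most (right-most) terminal gene, **5** for the
  5′-most; on a single-gene contig the mate strand decides (forward → 3,
  reverse → 5);
- if it lies outside both terminal genes *toward a contig edge*, it founds an
  **artificial gene model** for that (contig, end) — one per end, grown by
  union as more reads arrive, kept in a registry so it never displaces the
  real terminal genes (important under noise);
- if it lies strictly between the terminal genes, the pair is rejected
  (`between_genes`): an interior read cannot witness a junction.

Of the 16 (label, strand)² states of a pair, only those with both ends in
{(3, F), (5, R)} are geometrically possible — 4 combinations — and each
fixes the relative orientation of the two contigs: the exit end 3 means the
left contig is unflipped (`+`), exit 5 flipped (`-`); the entry end 5 means
the right contig is unflipped, entry 3 flipped.

Retained pairs for a contig pair are grouped by signature
(end labels + connecting genes); a **strict majority** signature becomes the
edge candidate with weight = its support, minority pairs are dropped and
counted, and a tie drops the whole contig pair (counted). This majority rule
resolves conflicting evidence without inventing a weighting scheme.

## 3. Graph and traversal (`scaffold_graph`)

Edge candidates with weight ≥ **K** (default **5**, CLI `-k`) form an
undirected weighted graph over all contigs. Per connected component,
candidate paths are generated by a weight-greedy walk (always step to the
heaviest unvisited neighbour; ties broken lexicographically by contig name
for determinism) started from every leaf, or — if the component has no leaf —
from every vertex.

## 4. Annotation reconciliation (`reconciler`)

A greedy path may contradict the annotation (e.g. it may enter and leave a
contig through the same end, which no transcript can do). Each candidate is
checked step by step; a step is legal iff

1. the end it consumes on the shared contig differs from the end consumed by
   the previous step, and
2. the connecting genes on the edge are the terminal genes (or registered
   artificial genes) at exactly those ends.

The path is truncated at the first illegal step. Within a component the best
reconciled candidate is committed (full coverage wins immediately; otherwise
most contigs, then highest support, then generation order), its contigs are
marked visited, and remaining vertices are re-walked until no further legal
join exists — so one bad edge does not sacrifice the rest of the component.
A committed path starting with a flipped contig is reverse-complemented as a
whole (an equivalent scaffold), giving a canonical representation.

## 5. Assembly and annotation update (`updater`)

Committed paths become scaffolds: component sequences (reverse-complemented
where flipped) joined by `N × gap_len` (default **1000**, an explicit "size
unknown" spacer). Gene models are lifted by offset for `+` components and by
reflection `x ↦ offset + (len − x)` with strand flip for `-` components.
Models connected by junctions are merged (union-find, so chains collapse into
one model per merged gene) with id `merged_<scaffold>_<n>` and a
`merged_from` attribute preserving provenance; artificial models not used by
any junction are discarded and counted.

Every run asserts, and the test suite re-asserts:

- `sequences_out = contigs_in − junctions`
- `bases_out = bases_in + gap_len × junctions`
- `genes_out = genes_in + artificial_created − junctions − artificial_discarded`
- every scaffold slice equals its source contig (up to reverse complement)
- the seven pair-ledger bins sum exactly to the number of input pairs.

## 6. Split mode (`--split`)

For inputs that are already scaffolded, scaffolds are first broken at maximal
N-runs of length ≥ `min_gap_len` (default **25**, the conventional minimum
annotated gap size); gap lengths (including leading/trailing runs) are kept
in a split map so the operation is byte-for-byte reversible. The annotation
is clipped to the parts, the pipeline runs on the parts, and an
**inconsistency report** lists every originally adjacent part pair whose
facing ends the RNA evidence joined to a different partner. Unused ends are
not reported: absence of evidence is not disagreement.

## 7. Simulator and evaluator (`fixtures`, `evaluator`)

The simulator builds worlds with known truth: random source sequences, evenly
spaced multi-exon genes (defaults: 2 × 50 kb sources, 20 genes, 4 × 300 bp
exons, 600 bp introns), breakpoints planted at intron midpoints with
probability `frag_rate` (0.5), optional per-contig flips, 5 read pairs per
junction with one 75 bp mate in each flanking exon, and optional chimeric
noise pairs (fraction `noise_rate`) between truth-non-adjacent contigs, at
most 2 per contig pair so they sit below the default K. All randomness comes
from one `random.Random(seed)`; identical seeds give byte-identical outputs.

The evaluator scores committed paths against truth: adjacency recall,
inter-source errors (contigs from different sources joined), intra-source
errors (wrong order/orientation within a source, with an orientation-only
sub-count; orientation is compared *effectively*, i.e. path orientation ⊗
truth strand, so a reverse-complemented scaffold is correct), repeated
placements, N50, and a classification of each junction by the gene context
of its supporting mates (same gene / one end unannotated / two genes /
no genes).

## Assumptions and limitations

- The annotation is trusted: terminal genes define which joins are legal.
  Wrong gene models can block true joins or admit false ones.
- Only pairs with both mates mapped and unique are used; split (chimeric)
  alignments of single reads are ignored.
- Gap lengths in output scaffolds are a fixed constant, not an insert-size
  estimate.
- The simulator emits error-free alignments (NM=0, MAPQ 60, full-length
  mates); it exercises the geometry, graph logic and accounting, not the
  aligner-noise filters (those are unit-tested on hand-written SAM records).
- The traversal is greedy per component with reconciliation and re-walking,
  not an exact maximum-weight legal path search; the acceptance suite checks
  it against a brute-force oracle on small random graphs.
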