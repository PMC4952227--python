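import pytest

from rnascaf.annotation_io import ContigAnnotation, GeneModel
from rnascaf.assembly_io import ContigRecord, reverse_complement
from rnascaf.reconciler import Junction, ScaffoldPath
from rnascaf.updater import (
    ScaffoldRecord,
    build_scaffold,
    sequence_fidelity_check,
    update_assembly,
)


@pytest.fixture
def contigs():
    return {
        "A": ContigRecord("A", "ACGTACGTAC" * 10),   # 100 bp
        "B": ContigRecord("B", "GGCCTTAAGG" * 20),   # 200 bp
    }


def _path(orient_b="+"):
    return ScaffoldPath(
        entries=[("A", "+"), ("B", orient_b)],
        junctions=[Junction("A", "B", 3, 5, "gA", "gB", weight=5)],
    )


def _ann(contigs):
    return {
        "A": ContigAnnotation("A", [GeneModel("gA", "A", 60, 100, "+", exons=[(60, 70), (90, 100)])]),
        "B": ContigAnnotation("B", [GeneModel("gB", "B", 0, 50, "+", exons=[(0, 10), (40, 50)])]),
    }


class TestBuildScaffold:
    def test_lengths_and_gap(self, contigs):
        scaf = build_scaffold(_path(), contigs, gap_len=1000)
        assert len(scaf.sequence) == 100 + 1000 + 200
        assert scaf.sequence[100:1100] == "N" * 1000
        assert scaf.components == [("A", "+", 0), ("B", "+", 1100)]

    def test_reverse_complement_component(self, contigs):
        scaf = build_scaffold(_path("-"), contigs, gap_len=10)
        assert scaf.sequence[110:] == reverse_complement(contigs["B"].sequence)

    def test_single_contig_identity(self, contigs):
        path = ScaffoldPath(entries=[("A", "+")], junctions=[])
        scaf = build_scaffold(path, contigs, gap_len=1000)
        assert scaf.sequence == contigs["A"].sequence

    def test_missing_contig_is_error(self, contigs):
        path = ScaffoldPath(entries=[("A", "+"), ("Z", "+")], junctions=[])
        with pytest.raises(KeyError):
            build_scaffold(path, contigs)


class TestLiftAndMerge:
    def test_forward_lift_identity_and_offset(self, contigs):
        res = update_assembly([_path()], contigs, _ann(contigs), gap_len=100)
        (ann,) = [a for a in res.annotations.values() if a.contig.startswith("scaffold")]
        (merged,) = ann.genes
        # two 2-exon genes merged into one 4-exon model
        assert len(merged.exons) == 4
        assert merged.merged_from == ["gA", "gB"]
        # gA's exons unchanged, gB's shifted by 100 (contig A) + 100 (gap)
        assert merged.exons == [(60, 70), (90, 100), (200, 210), (240, 250)]

    def test_reflected_lift_on_reversed_component(self, contigs):
        # gene [10,50) on a reversed 200 bp component at offset 0 lands at
        # [150,190) with flipped strand
        ann = {"B": ContigAnnotation("B", [GeneModel("g", "B", 10, 50, "+")])}
        path = ScaffoldPath(entries=[("B", "-")], junctions=[])
        res = update_assembly([path], contigs, ann, gap_len=0)
        lifted = res.annotations["scaffold_1"].genes[0]
        assert (lifted.start, lifted.end, lifted.strand) == (150, 190, "-")

    def test_gene_count_drops_by_exactly_junctions(self, contigs):
        ann = _ann(contigs)
        genes_in = sum(len(a.genes) for a in ann.values())
        res = update_assembly([_path()], contigs, ann, gap_len=100)
        assert res.gene_count == genes_in - res.junction_count

    def test_lifted_exon_sequences_preserved(self, contigs):
        ann = _ann(contigs)
        res = update_assembly([_path("-")], contigs, ann, gap_len=50)
        scaf = res.scaffolds[0]
        comp = {c: (o, off) for c, o, off in scaf.components}
        for contig, contig_ann in ann.items():
            orient, off = comp[contig]
            clen = contigs[contig].length
            for g in contig_ann.genes:
                for s, e in g.exons:
                    original = contigs[contig].sequence[s:e]
                    if orient == "+":
                        got = scaf.sequence[off + s : off + e]
                    else:
                        got = reverse_complement(
                            scaf.sequence[off + clen - e : off + clen - s]
                        )
                    assert got == original


class TestFidelityCheck:
    def test_clean_run_has_no_mismatches(self, contigs):
        scaf = build_scaffold(_path("-"), contigs, gap_len=20)
        assert sequence_fidelity_check(contigs, [scaf]) == []

    def test_corrupted_offset_detected(self, contigs):
        scaf = build_scaffold(_path(), contigs, gap_len=20)
        broken = ScaffoldRecord(
            scaf.name, scaf.sequence,
            [(c, o, off + (1 if c == "B" else 0)) for c, o, off in scaf.components],
            scaf.gap_len,
        )
        problems = sequence_fidelity_check(contigs, [broken])
        assert len(problems) == 1 and "B" in problems[0]

    def test_empty_path_set(self, contigs):
        assert sequence_fidelity_check(contigs, []) == []
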