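import pytest

from rnascaf.alignment_ingest import JoiningPair, ReadEnd
from rnascaf.evaluator import classify_junction_cases, n50, score_scaffolding
from rnascaf.fixtures import PlantedGene, TruthContig, TruthTable
from rnascaf.reconciler import Junction, ScaffoldPath


@pytest.fixture
def truth():
    t = TruthTable()
    # src1 tiled by c1[0,100) c2[100,250) c3[250,400); src2 by d1, d2
    for name, src, s, e in [
        ("c1", "src1", 0, 100), ("c2", "src1", 100, 250), ("c3", "src1", 250, 400),
        ("d1", "src2", 0, 100), ("d2", "src2", 100, 200),
    ]:
        t.contigs[name] = TruthContig(name, src, s, e)
    t.adjacencies = [("c1", "c2"), ("c2", "c3"), ("d1", "d2")]
    t.genes = [
        PlantedGene("gene1", "src1", "+", [(50, 80), (120, 150)]),
        PlantedGene("gene2", "src1", "+", [(300, 330), (360, 390)]),
    ]
    return t


def _path(entries, junctions=None):
    if junctions is None:
        junctions = [
            Junction(a, b, 3, 5, "x", "y", weight=5)
            for (a, _), (b, _) in zip(entries, entries[1:])
        ]
    return ScaffoldPath(entries=entries, junctions=junctions)


def test_n50_definition():
    # direct computation: sort desc, cumulate to half of 2000 -> first length
    assert n50([1000, 800, 200]) == 1000
    assert n50([500, 500, 500, 500]) == 500
    assert n50([]) == 0


class TestScoreScaffolding:
    def test_perfect_recovery(self, truth):
        paths = [
            _path([("c1", "+"), ("c2", "+"), ("c3", "+")]),
            _path([("d1", "+"), ("d2", "+")]),
        ]
        s = score_scaffolding(paths, truth, [400, 200])
        assert (s.inter_chromosomal_errors, s.intra_chromosomal_errors,
                s.repeated_placements) == (0, 0, 0)
        assert s.adjacency_recall == 1.0
        assert s.n50 == 400

    def test_reversed_scaffold_is_equivalent(self, truth):
        s = score_scaffolding([_path([("c3", "-"), ("c2", "-"), ("c1", "-")])], truth)
        assert s.intra_chromosomal_errors == 0
        assert s.adjacencies_recovered == 2

    def test_inter_chromosomal_error(self, truth):
        s = score_scaffolding([_path([("c1", "+"), ("d1", "+")])], truth)
        assert s.inter_chromosomal_errors == 1

    def test_intra_error_wrong_order_and_orientation_subcount(self, truth):
        # non-adjacent same-source pair: plain intra error
        s = score_scaffolding([_path([("c1", "+"), ("c3", "+")])], truth)
        assert s.intra_chromosomal_errors == 1
        assert s.orientation_only_errors == 0
        # adjacent but one contig flipped: intra error, orientation sub-count
        s = score_scaffolding([_path([("c1", "+"), ("c2", "-")])], truth)
        assert s.intra_chromosomal_errors == 1
        assert s.orientation_only_errors == 1

    def test_repeated_placement_counted_per_extra_occurrence(self, truth):
        paths = [
            _path([("c1", "+"), ("c2", "+")]),
            _path([("c2", "+"), ("c3", "+")]),
        ]
        s = score_scaffolding(paths, truth)
        assert s.repeated_placements == 1

    def test_unknown_contig_is_error(self, truth):
        with pytest.raises(KeyError):
            score_scaffolding([_path([("zz", "+"), ("c1", "+")])], truth)


def _pair_on(c1, s1, e1, c2, s2, e2):
    mk = lambda c, s, e: ReadEnd(c, s, e, "F", 60, 0, e - s, e - s)
    return JoiningPair("p", mk(c1, s1, e1), mk(c2, s2, e2))


class TestJunctionCases:
    def _score(self, truth, pair):
        j = Junction("c1", "c2", 3, 5, "x", "y", weight=1, pairs=[pair])
        path = ScaffoldPath(entries=[("c1", "+"), ("c2", "+")], junctions=[j])
        (case,) = classify_junction_cases([path], truth)
        return case

    def test_case1_same_gene(self, truth):
        # mates in the two exons of gene1, which spans the c1/c2 breakpoint
        case = self._score(truth, _pair_on("c1", 55, 75, "c2", 25, 45))
        assert case.case == 1 and case.consecutive

    def test_case2_one_end_unannotated(self, truth):
        case = self._score(truth, _pair_on("c1", 55, 75, "c2", 60, 90))
        assert case.case == 2

    def test_case3_two_genes(self, truth):
        # one mate in gene1, other inside gene2 (gene2 starts at src1:300,
        # i.e. c3-local 50)
        j = Junction("c2", "c3", 3, 5, "x", "y", weight=1,
                     pairs=[_pair_on("c2", 25, 45, "c3", 55, 75)])
        path = ScaffoldPath(entries=[("c2", "+"), ("c3", "+")], junctions=[j])
        (case,) = classify_junction_cases([path], truth)
        assert case.case == 3

    def test_case4_no_genes(self, truth):
        case = self._score(truth, _pair_on("c1", 5, 25, "c2", 60, 90))
        assert case.case == 4

    def test_cases_partition_junctions(self, truth):
        pairs = [
            _pair_on("c1", 55, 75, "c2", 25, 45),
            _pair_on("c1", 55, 75, "c2", 60, 90),
            _pair_on("c1", 5, 25, "c2", 60, 90),
        ]
        j = Junction("c1", "c2", 3, 5, "x", "y", weight=3, pairs=pairs)
        path = ScaffoldPath(entries=[("c1", "+"), ("c2", "+")], junctions=[j])
        cases = classify_junction_cases([path], truth)
        assert len(cases) == 1  # one junction, exactly one case label
        assert cases[0].case in (1, 2, 3, 4)
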