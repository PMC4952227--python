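import itertools

import pytest

from rnascaf.alignment_ingest import JoiningPair, ReadEnd
from rnascaf.annotation_io import ContigAnnotation, GeneModel
from rnascaf.denoiser import (
    ArtificialGeneRegistry,
    VALID_END_STATES,
    assign_labels,
    build_edge_candidates,
    denoise,
    orientation_filter,
)


def _end(contig, start, end, strand, label=None, gene=None):
    return ReadEnd(
        contig=contig, start=start, end=end, strand=strand,
        mapq=60, mismatches=0, aln_len=end - start, read_len=end - start,
        label=label, gene=gene,
    )


def _gene(gid, contig, start, end):
    return GeneModel(gene_id=gid, contig=contig, start=start, end=end, strand="+")


@pytest.fixture
def annotations():
    # c1 and c2 each have genes at both edges and one interior gene
    return {
        "c1": ContigAnnotation("c1", sorted(
            [_gene("c1_g5", "c1", 0, 200), _gene("c1_mid", "c1", 400, 500),
             _gene("c1_g3", "c1", 800, 1000)], key=lambda g: g.start)),
        "c2": ContigAnnotation("c2", sorted(
            [_gene("c2_g5", "c2", 50, 250), _gene("c2_mid", "c2", 400, 500),
             _gene("c2_g3", "c2", 700, 950)], key=lambda g: g.start)),
        "single": ContigAnnotation("single", [_gene("s_only", "single", 100, 300)]),
    }


@pytest.fixture
def registry(annotations):
    return ArtificialGeneRegistry({"c1": 1000, "c2": 1000, "single": 400, "bare": 500}, annotations)


def _pair(e1, e2, rid="p"):
    return JoiningPair(read_id=rid, left=e1, right=e2)


class TestAssignLabels:
    def test_terminal_overlaps(self, annotations, registry):
        p = _pair(_end("c1", 850, 900, "F"), _end("c2", 60, 110, "R"))
        assert assign_labels(p, annotations, registry)
        assert (p.left.label, p.left.gene) == (3, "c1_g3")
        assert (p.right.label, p.right.gene) == (5, "c2_g5")

    def test_between_interior_genes_rejected(self, annotations, registry):
        p = _pair(_end("c1", 300, 350, "F"), _end("c2", 60, 110, "R"))
        assert not assign_labels(p, annotations, registry)

    def test_outside_terminals_creates_artificial(self, annotations, registry):
        # c2 has no gene before position 50: reads there get an artificial
        # 5'-side model
        p = _pair(_end("c1", 850, 900, "F"), _end("c2", 0, 40, "R"))
        assert assign_labels(p, annotations, registry)
        assert p.right.label == 5
        assert p.right.gene == "art_c2_1"
        assert ("c2", 5) in registry.models
        # a second pair in the same region reuses (and extends) the model
        q = _pair(_end("c1", 850, 900, "F"), _end("c2", 5, 45, "R"))
        assert assign_labels(q, annotations, registry)
        assert q.right.gene == "art_c2_1"
        assert registry.models[("c2", 5)].exons == [(0, 45)]

    def test_single_gene_label_resolved_by_strand(self, annotations, registry):
        p = _pair(_end("single", 150, 200, "F"), _end("c1", 850, 900, "F"))
        assert assign_labels(p, annotations, registry)
        assert p.left.label == 3  # F points off the 3' edge
        q = _pair(_end("single", 150, 200, "R"), _end("c1", 850, 900, "F"))
        assert assign_labels(q, annotations, registry)
        assert q.left.label == 5

    def test_geneless_contig_allowed_with_artificial(self, annotations, registry):
        p = _pair(_end("bare", 400, 450, "F"), _end("c1", 850, 900, "F"))
        assert assign_labels(p, annotations, registry)
        assert p.left.label == 3 and p.left.gene.startswith("art_bare")


class TestOrientationFilter:
    def test_exactly_four_of_sixteen_states_survive(self):
        """Exhaustive check over all (label,strand)^2 end states: only the
        four inward-facing combinations survive."""
        survivors = set()
        for (l1, s1), (l2, s2) in itertools.product(
            itertools.product((5, 3), "FR"), repeat=2
        ):
            p = _pair(_end("c1", 0, 10, s1, label=l1), _end("c2", 0, 10, s2, label=l2))
            if orientation_filter(p):
                survivors.add(((l1, s1), (l2, s2)))
        assert survivors == {
            ((3, "F"), (5, "R")),
            ((3, "F"), (3, "F")),
            ((5, "R"), (5, "R")),
            ((5, "R"), (3, "F")),
        }
        assert all(state in VALID_END_STATES for combo in survivors for state in combo)


class TestEdgeCandidates:
    def _mk(self, rid, label_a, label_b, gene_a="ga", gene_b="gb"):
        return _pair(
            _end("a", 0, 10, "F", label=label_a, gene=gene_a),
            _end("b", 0, 10, "R", label=label_b, gene=gene_b),
            rid=rid,
        )

    def test_majority_rule_against_direct_tally(self):
        pairs = [self._mk(f"x{i}", 3, 5) for i in range(4)] + [self._mk("y", 5, 3, "g2", "g3")]
        edges, minority, ties = build_edge_candidates(pairs)
        assert len(edges) == 1
        e = edges[0]
        # direct tally oracle: 4 of (3,5,ga,gb) vs 1 of (5,3,g2,g3)
        assert e.weight == 4 and (e.side_a, e.side_b) == (3, 5)
        assert minority == 1 and ties == 0
        assert len(e.pairs) == 4

    def test_exact_tie_drops_candidate(self):
        pairs = [self._mk("x1", 3, 5), self._mk("x2", 3, 5),
                 self._mk("y1", 5, 3), self._mk("y2", 5, 3)]
        edges, minority, ties = build_edge_candidates(pairs)
        assert edges == [] and ties == 4 and minority == 0

    def test_simple_count(self):
        pairs = [self._mk(f"p{i}", 3, 5) for i in range(5)]
        edges, _, _ = build_edge_candidates(pairs)
        assert edges[0].weight == 5

    def test_unordered_contig_key(self):
        # same physical edge reported with contigs in either order
        p1 = self._mk("p1", 3, 5)
        p2 = _pair(
            _end("b", 0, 10, "R", label=5, gene="gb"),
            _end("a", 0, 10, "F", label=3, gene="ga"),
            rid="p2",
        )
        edges, _, _ = build_edge_candidates([p1, p2])
        assert len(edges) == 1 and edges[0].weight == 2


def test_denoise_accounting_identity(annotations, registry):
    pairs = [
        _pair(_end("c1", 850, 900, "F"), _end("c2", 60, 110, "R"), "good1"),
        _pair(_end("c1", 850, 900, "F"), _end("c2", 60, 110, "R"), "good2"),
        _pair(_end("c1", 300, 350, "F"), _end("c2", 60, 110, "R"), "between"),
        _pair(_end("c1", 100, 150, "F"), _end("c2", 60, 110, "R"), "bad_orient"),
    ]
    res = denoise(pairs, annotations, {"c1": 1000, "c2": 1000})
    assert res.rejected_assign + res.rejected_orientation + len(res.retained) == len(pairs)
    assert res.rejected_assign == 1 and res.rejected_orientation == 1
    assert {r[0] for r in res.rejections} == {"between", "bad_orient"}
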