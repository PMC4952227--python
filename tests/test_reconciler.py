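import pytest

from rnascaf.annotation_io import ContigAnnotation, GeneModel
from rnascaf.denoiser import EdgeCandidate
from rnascaf.reconciler import commit_paths, reconcile, select_best
from rnascaf.scaffold_graph import CandidatePath, build_graph, enumerate_candidates


def edge(u, v, w, su=3, sv=5):
    a, b = sorted((u, v))
    sa, sb = (su, sv) if a == u else (sv, su)
    return EdgeCandidate(
        contig_a=a, contig_b=b, side_a=sa, side_b=sb,
        gene_a=f"{a}_{sa}", gene_b=f"{b}_{sb}", weight=w,
    )


def annotations_for(vertices):
    """Each contig gets one gene per end, named <contig>_5 and <contig>_3,
    matching the gene ids the edge helper assigns."""
    out = {}
    for v in vertices:
        out[v] = ContigAnnotation(v, [
            GeneModel(f"{v}_5", v, 0, 10, "+"),
            GeneModel(f"{v}_3", v, 90, 100, "+"),
        ])
        out[v].sort()
    return out


def path_of(vertices, edges):
    return CandidatePath(vertices=vertices, edges=edges, start_vertex=vertices[0])


TRIANGLE = [edge("A", "B", 3), edge("A", "C", 4), edge("B", "C", 5)]


class TestReconcile:
    def test_two_contig_path_intact(self):
        e = edge("A", "B", 5)
        rec = reconcile(path_of(["A", "B"], [e]), annotations_for("AB"))
        assert rec.entries == [("A", "+"), ("B", "+")]
        assert rec.junctions[0].gene_left == "A_3"

    def test_triangle_truncation_and_reordering(self):
        """Greedy order A,C,B re-uses C's entry end and truncates to two
        contigs; the walk from C yields the full, correctly ordered path."""
        ann = annotations_for("ABC")
        eAB, eAC, eBC = TRIANGLE
        bad = reconcile(path_of(["A", "C", "B"], [eAC, eBC]), ann)
        assert bad.contigs == ["A", "C"]  # C->B would re-consume C's 5' end
        good = reconcile(path_of(["C", "B", "A"], [eBC, eAB]), ann)
        assert len(good) == 3
        # canonical flip: whole path reverse-complemented so it starts '+'
        assert good.entries == [("A", "+"), ("B", "+"), ("C", "+")]

    def test_truncation_of_longer_greedy_path(self):
        # A-B fine; the B->C step wants B's 5' end, already consumed on entry
        ann = annotations_for("ABCD")
        e1 = edge("A", "B", 9)             # A:3 - B:5
        e2 = edge("B", "C", 8, su=5, sv=5)  # would need B's 5' end again
        e3 = edge("C", "D", 7)
        rec = reconcile(path_of(["A", "B", "C", "D"], [e1, e2, e3]), ann)
        assert rec.contigs == ["A", "B"]

    def test_gene_mismatch_truncates(self):
        ann = annotations_for("AB")
        e = edge("A", "B", 5)
        e.gene_a = "not_a_terminal_gene"
        rec = reconcile(path_of(["A", "B"], [e]), ann)
        assert rec.contigs == ["A"]

    def test_enforce_off_keeps_raw_greedy_order(self):
        ann = annotations_for("ABC")
        eAB, eAC, eBC = TRIANGLE
        raw = reconcile(path_of(["A", "C", "B"], [eAC, eBC]), ann, enforce=False)
        assert raw.contigs == ["A", "C", "B"]


class TestSelectBest:
    def test_full_coverage_wins_immediately(self):
        ann = annotations_for("ABC")
        eAB, eAC, eBC = TRIANGLE
        group = [
            path_of(["C", "B", "A"], [eBC, eAB]),  # reconciles to all 3
            path_of(["A", "C", "B"], [eAC, eBC]),  # would truncate
        ]
        best = select_best(group, ann)
        assert len(best) == 3

    def test_most_vertices_then_weight_then_order(self):
        ann = annotations_for("ABCDEF")
        two = path_of(["A", "B"], [edge("A", "B", 9)])
        three = path_of(["C", "D", "E"], [edge("C", "D", 2), edge("D", "E", 2)])
        # group vertices = union, so nothing covers everything
        best = select_best([two, three], ann)
        assert best.contigs == ["C", "D", "E"]  # max vertex count
        w10 = path_of(["A", "B"], [edge("A", "B", 10)])
        w12 = path_of(["C", "D"], [edge("C", "D", 12)])
        assert select_best([w10, w12], ann).contigs == ["C", "D"]  # weight tie-break
        same1 = path_of(["A", "B"], [edge("A", "B", 7)])
        same2 = path_of(["C", "D"], [edge("C", "D", 7)])
        assert select_best([same1, same2], ann).contigs == ["A", "B"]  # first in list


class TestCommitPaths:
    def test_disjoint_groups_committed_unchanged(self):
        ann = annotations_for("ABXY")
        g = build_graph([edge("A", "B", 5), edge("X", "Y", 6)], K=5)
        paths = commit_paths(g, ann)
        assert sorted(p.contigs for p in paths) == [["A", "B"], ["X", "Y"]]

    def test_no_contig_placed_twice(self):
        # star: B and C both want A; only one junction can use each end of A
        ann = annotations_for("ABC")
        g = build_graph(
            [edge("B", "A", 9, su=3, sv=5), edge("C", "A", 8, su=3, sv=5)], K=2
        )
        paths = commit_paths(g, ann)
        placed = [c for p in paths for c in p.contigs]
        assert len(placed) == len(set(placed))

    def test_remainder_rewalked_after_commit(self):
        # chain A-B-C-D where the best first path covers only part of the
        # component; the leftover pair must still be joined in a later round
        ann = annotations_for("ABCD")
        e1 = edge("A", "B", 9)
        e2 = edge("B", "C", 8)
        e2.gene_a = e2.gene_b = "bogus"  # B-C illegal from either direction
        e3 = edge("C", "D", 7)
        g = build_graph([e1, e2, e3], K=2)
        paths = commit_paths(g, ann)
        committed = sorted(p.contigs for p in paths)
        assert committed == [["A", "B"], ["C", "D"]]

    def test_junctions_use_opposite_ends(self, ):
        ann = annotations_for("ABCD")
        g = build_graph(
            [edge("A", "B", 5), edge("B", "C", 5), edge("C", "D", 5)], K=2
        )
        (path,) = commit_paths(g, ann)
        assert len(path) == 4
        for j1, j2 in zip(path.junctions, path.junctions[1:]):
            assert j1.side_right != j2.side_left  # shared contig, opposite ends
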