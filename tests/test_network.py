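import itertools

import networkx as nx
import numpy as np
import pytest

from gcpnet.network import (
    EdgeParseError,
    ReferencedEdge,
    build_background,
    extract_subnetwork,
    filter_by_reference,
    intermediate_zscore,
    merge_edges,
    read_edge_lists,
    score_intermediates,
    scores_to_frame,
    write_subnetwork,
    SCORE_COLUMNS,
)
from gcpnet.table4 import load_table4


def edge(a, b, refs, source="db"):
    return ReferencedEdge(a, b, frozenset(refs), frozenset([source]))


class TestReadEdgeLists:
    def test_basic_record(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("a\tb\tr1;r2\tdbX\n")
        edges = read_edge_lists([p])
        assert len(edges) == 1
        assert edges[0].key == ("A", "B")
        assert edges[0].references == {"r1", "r2"}

    def test_reversed_duplicate_merges_with_union(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\tr1\tdb1\nB\tA\tr2\tdb2\n")
        edges = read_edge_lists([p])
        assert len(edges) == 1
        assert edges[0].references == {"r1", "r2"}
        assert edges[0].sources == {"db1", "db2"}

    def test_self_loop_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tA\tr1\tdb\nA\tB\tr2\tdb\n")
        with caplog.at_level("WARNING"):
            edges = read_edge_lists([p])
        assert len(edges) == 1
        assert "self-loop" in caplog.text

    def test_missing_columns_raise_with_location(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\tr1\tdb\nA\n")
        with pytest.raises(EdgeParseError, match=r":2:"):
            read_edge_lists([p])

    def test_header_line_tolerated(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("proteinA\tproteinB\trefs\tsource\na\tb\tr1\tdb\n")
        assert len(read_edge_lists([p])) == 1


class TestFilterByReference:
    def test_overloaded_sole_reference_removes_all_its_edges(self):
        edges = [edge("A", f"B{i}", ["rbig"]) for i in range(5)]
        assert filter_by_reference(edges, max_links_per_reference=4) == []

    def test_edge_with_one_small_reference_survives(self):
        edges = [edge("A", f"B{i}", ["rbig"]) for i in range(10)]
        edges.append(edge("X", "Y", ["rbig", "rsmall"]))
        kept = filter_by_reference(edges)
        assert [e.key for e in kept] == [("X", "Y")]
        assert kept[0].references == {"rsmall"}

    def test_at_cap_reference_is_valid(self):
        edges = [edge("A", f"B{i}", ["r"]) for i in range(4)]
        assert len(filter_by_reference(edges, max_links_per_reference=4)) == 4

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_two_pass_counting_oracle(self, seed):
        """Surviving edges equal an independent recount of per-reference
        support on random referenced edge sets."""
        rng = np.random.default_rng(seed)
        nodes = [f"N{i}" for i in range(20)]
        refs = [f"r{i}" for i in range(12)]
        edges = []
        seen = set()
        for _ in range(60):
            i, j = rng.choice(20, size=2, replace=False)
            a, b = sorted((nodes[i], nodes[j]))
            if (a, b) in seen:
                continue
            seen.add((a, b))
            k = rng.integers(1, 4)
            edges.append(edge(a, b, list(rng.choice(refs, size=k, replace=False))))
        cap = 4
        # oracle pass 1: count support per reference over merged edges
        support = {}
        for e in edges:
            for r in e.references:
                support[r] = support.get(r, 0) + 1
        # oracle pass 2: keep edges retaining any reference within the cap
        expected = {e.key for e in edges if any(support[r] <= cap for r in e.references)}
        kept = {e.key for e in filter_by_reference(edges, cap)}
        assert kept == expected

    @pytest.mark.parametrize("seed", [0, 1])
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        edges = [
            edge(f"A{i}", f"B{rng.integers(8)}", [f"r{rng.integers(6)}"])
            for i in range(30)
        ]
        once = filter_by_reference(edges)
        twice = filter_by_reference(once)
        assert [e.key for e in once] == [e.key for e in twice]
        assert [e.references for e in once] == [e.references for e in twice]


class TestBuildBackground:
    def test_triangle(self):
        G = build_background([edge("A", "B", ["r1"]), edge("B", "C", ["r2"]),
                              edge("C", "A", ["r3"])])
        assert G.graph["N"] == 3
        assert all(G.degree(v) == 2 for v in "ABC")

    def test_merged_duplicates_counted_once(self):
        G = build_background([edge("A", "B", ["r1"]), edge("B", "A", ["r2"])])
        assert G.graph["N"] == 1

    def test_empty_edge_set_rejected(self):
        with pytest.raises(ValueError):
            build_background([])

    def test_simulated_count_matches_generator_bookkeeping(self, small_network_sim):
        sim = small_network_sim
        kept = filter_by_reference(sim.edges)
        G = build_background(kept)
        assert G.graph["N"] == len(sim.edges) - len(sim.truth.purged_edges)


class TestExtractSubnetwork:
    def background(self, *pairs):
        return build_background([edge(a, b, [f"r{i}"]) for i, (a, b) in enumerate(pairs)])

    def test_direct_seed_edge_only(self):
        G = self.background(("A", "B"))
        sub = extract_subnetwork(G, ["A", "B"])
        assert sub.intermediates == []
        assert sub.K == 1

    def test_intermediate_needs_two_distinct_seeds(self):
        G = self.background(("A", "X"), ("X", "B"), ("A", "C"))
        sub = extract_subnetwork(G, ["A", "B"])
        assert sub.intermediates == ["X"]
        assert sub.seed_links == {"X": 2}
        assert "C" not in sub.graph
        # brute-force check: X is on a length-2 A..B path, C is not
        paths = list(nx.all_simple_paths(G, "A", "B", cutoff=2))
        on_path = {n for p in paths for n in p} - {"A", "B"}
        assert set(sub.intermediates) == on_path

    def test_parallel_records_to_one_seed_do_not_count(self):
        edges = [edge("A", "X", ["r1"]), edge("X", "A", ["r2"]),
                 edge("A", "B", ["r3"])]
        G = build_background(edges)
        sub = extract_subnetwork(G, ["A", "B"])
        assert sub.intermediates == []

    def test_missing_seeds_reported(self):
        G = self.background(("A", "B"))
        sub = extract_subnetwork(G, ["A", "B", "GHOST"])
        assert sub.missing_seeds == ["GHOST"]

    def test_fewer_than_two_seeds_rejected(self):
        G = self.background(("A", "B"))
        with pytest.raises(ValueError):
            extract_subnetwork(G, ["A", "GHOST"])

    def test_seed_order_and_edge_order_invariance(self):
        pairs = [("A", "X"), ("X", "B"), ("B", "Y"), ("Y", "C"), ("A", "C")]
        G1 = self.background(*pairs)
        G2 = self.background(*reversed(pairs))
        s1 = extract_subnetwork(G1, ["A", "B", "C"])
        s2 = extract_subnetwork(G2, ["C", "B", "A"])
        assert s1.intermediates == s2.intermediates
        assert s1.K == s2.K
        assert set(s1.graph.edges) == set(s2.graph.edges)

    def test_intermediate_edges_can_be_excluded_from_K(self):
        pairs = [("A", "X"), ("X", "B"), ("A", "Y"), ("Y", "B"), ("X", "Y")]
        G = self.background(*pairs)
        with_ii = extract_subnetwork(G, ["A", "B"], include_intermediate_edges=True)
        without = extract_subnetwork(G, ["A", "B"], include_intermediate_edges=False)
        assert with_ii.K == 5
        assert without.K == 4


class TestIntermediateZscore:
    @pytest.mark.parametrize(
        "gene, n, k, z_printed",
        [(r.gene, r.n, r.k, r.z_printed) for r in load_table4()],
    )
    def test_reproduces_published_values(self, gene, n, k, z_printed):
        z = intermediate_zscore(n, k, 60, 11429)
        assert z == pytest.approx(z_printed, abs=0.005)

    def test_null_proportion_scores_zero(self):
        # k/n == K/N exactly
        assert intermediate_zscore(100, 2, 2, 100) == pytest.approx(0.0)

    def test_strictly_increasing_in_k(self):
        zs = [intermediate_zscore(20, k, 60, 11429) for k in range(0, 21)]
        assert all(b > a for a, b in zip(zs, zs[1:]))

    def test_agrees_with_statsmodels_proportion_test(self):
        sm = pytest.importorskip("statsmodels.stats.proportion")
        for n, k in [(3, 2), (67, 6), (153, 3)]:
            expected, _ = sm.proportions_ztest(k, n, value=60 / 11429,
                                               prop_var=60 / 11429)
            assert intermediate_zscore(n, k, 60, 11429) == pytest.approx(expected)

    @pytest.mark.parametrize("n, k, K, N", [(0, 0, 1, 2), (3, 4, 1, 2), (3, 2, 0, 5), (3, 2, 5, 5)])
    def test_invalid_counts_rejected(self, n, k, K, N):
        with pytest.raises(ValueError):
            intermediate_zscore(n, k, K, N)


class TestScoreIntermediates:
    def build_case(self):
        # seeds S1..S3; X adjacent to 3 seeds, Y to 2 seeds + 2 others
        pairs = [("S1", "X"), ("S2", "X"), ("S3", "X"),
                 ("S1", "Y"), ("S2", "Y"), ("Y", "O1"), ("Y", "O2"),
                 ("S1", "S2"), ("O1", "O2"), ("O2", "O3")]
        G = build_background([edge(a, b, [f"r{i}"]) for i, (a, b) in enumerate(pairs)])
        sub = extract_subnetwork(G, ["S1", "S2", "S3"])
        return G, sub

    def test_sorted_by_z_descending(self):
        G, sub = self.build_case()
        scores = score_intermediates(sub, G)
        assert [s.node for s in scores] == ["X", "Y"]
        assert scores[0].z >= scores[1].z
        assert scores[0].k == 3 and scores[0].n == 3
        assert scores[1].k == 2 and scores[1].n == 4

    def test_cutoff_above_max_z_leaves_none_significant(self):
        G, sub = self.build_case()
        scores = score_intermediates(sub, G, cutoff=1e6)
        assert not any(s.significant for s in scores)

    def test_counts_match_by_hand_enumeration(self):
        G, sub = self.build_case()
        scores = {s.node: s for s in score_intermediates(sub, G)}
        assert scores["X"].N == G.graph["N"] == 10
        # subnetwork nodes {S1,S2,S3,X,Y}: edges S1-X,S2-X,S3-X,S1-Y,S2-Y,S1-S2
        assert scores["X"].K == 6


class TestWriteSubnetwork:
    def test_graphml_round_trip_and_columns(self, tmp_path):
        pairs = [("S1", "X"), ("S2", "X"), ("S1", "S2"), ("X", "O")]
        G = build_background([edge(a, b, [f"r{i}"]) for i, (a, b) in enumerate(pairs)])
        sub = extract_subnetwork(G, ["S1", "S2"])
        scores = score_intermediates(sub, G)
        gml = tmp_path / "net.graphml"
        tsv = tmp_path / "scores.tsv"
        write_subnetwork(sub, scores, gml, tsv)
        back = nx.read_graphml(gml)
        assert set(back.nodes) == set(sub.graph.nodes)
        assert {frozenset(e) for e in back.edges} == {
            frozenset(e) for e in sub.graph.edges
        }
        assert back.nodes["X"]["role"] == "intermediate"
        header = tsv.read_text().splitlines()[0].split("\t")
        assert header == SCORE_COLUMNS

    def test_empty_intermediate_set_writes_valid_files(self, tmp_path):
        G = build_background([edge("A", "B", ["r1"])])
        sub = extract_subnetwork(G, ["A", "B"])
        write_subnetwork(sub, [], tmp_path / "n.graphml", tmp_path / "s.tsv")
        back = nx.read_graphml(tmp_path / "n.graphml")
        assert set(back.nodes) == {"A", "B"}
        assert (tmp_path / "s.tsv").read_text().splitlines()[0].split("\t") == SCORE_COLUMNS
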