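"""Target merging, STRING loading, centralities (incl. MCC) and enrichment."""

import itertools
import math
from collections import deque

import networkx as nx
import numpy as np
import pytest

from cardiosig import datasets
from cardiosig import network_pharm as npharm
from cardiosig.network_pharm import ScoredTargetList


# ---------------------------------------------------------------------------
# independent oracles

def oracle_maximal_cliques(nodes, edges):
    """Subset-enumeration maximal-clique finder (graphs <= ~12 nodes)."""
    nodes = list(nodes)
    eset = {frozenset(e) for e in edges}

    def is_clique(sub):
        return all(frozenset(p) in eset for p in itertools.combinations(sub, 2))

    cliques = [set(sub) for r in range(1, len(nodes) + 1)
               for sub in itertools.combinations(nodes, r) if is_clique(sub)]
    return [c for c in cliques
            if not any(c < other for other in cliques)]


def oracle_mcc(nodes, edges):
    return {
        v: sum(math.factorial(len(c) - 1)
               for c in oracle_maximal_cliques(nodes, edges) if v in c)
        for v in nodes
    }


def oracle_betweenness(adj):
    """Brandes-free betweenness: BFS distances plus path-count DP."""
    nodes = list(adj)

    def bfs(src):
        dist = {src: 0}
        order = [src]
        q = deque([src])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    order.append(w)
                    q.append(w)
        npaths = {v: 0 for v in dist}
        npaths[src] = 1
        for v in order[1:]:
            npaths[v] = sum(npaths[u] for u in adj[v]
                            if u in dist and dist[u] == dist[v] - 1)
        return dist, npaths

    info = {s: bfs(s) for s in nodes}
    btw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist_s, np_s = info[s]
        if t not in dist_s:
            continue
        d = dist_s[t]
        dist_t, np_t = info[t]
        for v in nodes:
            if v in (s, t) or v not in dist_s or v not in dist_t:
                continue
            if dist_s[v] + dist_t[v] == d:
                btw[v] += np_s[v] * np_t[v] / np_s[t]
    return btw


# ---------------------------------------------------------------------------

class TestMergeDiseaseTargets:
    def test_all_equal_scores_retained(self):
        lst = ScoredTargetList("a", {"X": 15.0, "Y": 15.0, "Z": 15.0})
        merged = npharm.merge_disease_targets([lst])
        assert merged.symbols() == {"X", "Y", "Z"}

    def test_hand_worked_example(self):
        l1 = ScoredTargetList("a", {"A": 12.0, "B": 11.0})
        l2 = ScoredTargetList("b", {"B": 20.0, "C": 9.0})
        merged = npharm.merge_disease_targets([l1, l2])
        assert merged.entries == {"A": 12.0, "B": 20.0}

    def test_all_below_floor_empty(self):
        lst = ScoredTargetList("a", {"X": 3.0, "Y": 9.9})
        with pytest.warns(UserWarning):
            merged = npharm.merge_disease_targets([lst])
        assert len(merged) == 0

    def test_duplicates_keep_max_score(self):
        l1 = ScoredTargetList("a", {"X": 30.0})
        l2 = ScoredTargetList("b", {"X": 50.0, "Y": 40.0})
        merged = npharm.merge_disease_targets([l1, l2])
        assert merged.entries["X"] == 50.0


class TestIntersectTargets:
    def test_disjoint(self):
        shared, (ao, i, bo) = npharm.intersect_targets({"A"}, {"B"})
        assert shared == [] and i == 0 and ao == 1 and bo == 1

    def test_identical(self):
        shared, counts = npharm.intersect_targets({"a", "b"}, {"B", "A"})
        assert shared == ["A", "B"] and counts == (0, 2, 0)

    def test_planted_published_sizes(self):
        drug, disease, planted = datasets.make_target_lists(
            n_drug=359, n_disease=1097, n_shared=74, seed=1
        )
        shared, (a_only, n_shared, b_only) = npharm.intersect_targets(drug, disease)
        assert n_shared == 74
        assert set(shared) == planted
        assert a_only == 359 - 74 and b_only == 1097 - 74


class TestLoadStringTsv:
    def _write(self, tmp_path, rows):
        p = tmp_path / "edges.tsv"
        p.write_text("node1\tnode2\tcombined_score\n" +
                     "\n".join("\t".join(map(str, r)) for r in rows) + "\n")
        return p

    def test_threshold_boundary(self, tmp_path):
        g = npharm.load_string_tsv(
            self._write(tmp_path, [("A", "B", 899), ("A", "C", 900)])
        )
        assert not g.has_edge("A", "B") and g.has_edge("A", "C")

    def test_bidirectional_duplicates_collapse(self, tmp_path):
        g = npharm.load_string_tsv(
            self._write(tmp_path, [("A", "B", 950), ("B", "A", 970)])
        )
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["score"] == 970

    def test_self_loops_dropped_and_counted(self, tmp_path):
        g = npharm.load_string_tsv(
            self._write(tmp_path, [("A", "A", 990), ("A", "B", 950)])
        )
        assert g.graph["n_self_loops"] == 1
        assert list(g.edges) == [("A", "B")]

    def test_fixture_edge_count(self, tmp_path):
        rows = [(f"N{i}", f"N{i+1}", 880 + 10 * i) for i in range(20)]
        # scores 880..1070 would overflow the scale; clamp to spec range
        rows = [(u, v, min(s, 1000)) for u, v, s in rows]
        kept = sum(1 for _, _, s in rows if s >= 900)
        g = npharm.load_string_tsv(self._write(tmp_path, rows))
        assert g.number_of_edges() == kept

    def test_malformed_score_fatal_with_line(self, tmp_path):
        p = self._write(tmp_path, [("A", "B", "high")])
        with pytest.raises(ValueError, match=":2:"):
            npharm.load_string_tsv(p)


class TestCentralities:
    def test_star_graph_closed_forms(self):
        g = nx.star_graph(5)  # center 0, leaves 1..5
        c = npharm.centralities(g)
        assert c.loc[0, "degree"] == 5
        assert all(c.loc[i, "betweenness"] == 0 for i in range(1, 6))
        assert c.loc[0, "betweenness"] == 10  # all 10 leaf pairs route via center
        assert c.loc[0, "closeness"] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "edges,expected",
        [
            ([("A", "B"), ("B", "C"), ("A", "C")], {"A": 2, "B": 2, "C": 2}),
            ([("A", "B"), ("B", "C")], {"A": 1, "B": 2, "C": 1}),
            (
                [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"),
                 ("B", "D"), ("C", "D")],
                {"A": 6, "B": 6, "C": 6, "D": 6},
            ),
        ],
        ids=["triangle", "path", "K4"],
    )
    def test_mcc_small_closed_forms(self, edges, expected):
        g = nx.Graph(edges)
        assert npharm.mcc_scores(g) == expected

    def test_mcc_isolated_node_scores_one(self):
        g = nx.Graph([("A", "B")])
        g.add_node("LONER")
        assert npharm.mcc_scores(g)["LONER"] == 1

    def test_mcc_matches_enumeration_oracle_random_graphs(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            n = int(rng.integers(3, 11))
            p = float(rng.uniform(0.2, 0.8))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
            assert npharm.mcc_scores(g) == oracle_mcc(g.nodes, g.edges), trial

    def test_betweenness_matches_bfs_oracle(self):
        g = nx.gnp_random_graph(12, 0.3, seed=11)
        adj = {v: set(g.neighbors(v)) for v in g.nodes}
        expected = oracle_betweenness(adj)
        got = npharm.centralities(g)["betweenness"]
        for v in g.nodes:
            assert got[v] == pytest.approx(expected[v])

    def test_degree_sum_equals_twice_edges(self):
        g = nx.gnp_random_graph(30, 0.2, seed=3)
        g.add_node("ISO")
        c = npharm.centralities(g)
        assert c["degree"].sum() == 2 * g.number_of_edges()
        assert c.loc["ISO", "closeness"] == 0.0


class TestTopHubs:
    def test_k_exceeding_nodes_returns_all(self):
        g = nx.path_graph(3)
        assert len(npharm.top_hubs(npharm.centralities(g), "degree", k=10)) == 3

    def test_planted_hub_ranks_first_on_all_metrics(self, tmp_path):
        path = tmp_path / "edges.tsv"
        datasets.make_string_edges(path, seed=2)
        g = npharm.load_string_tsv(path, min_score=900)
        scores = npharm.centralities(g)
        for metric in npharm.CENTRALITY_METRICS:
            assert npharm.top_hubs(scores, metric, k=1) == ["AKT1"], metric

    def test_unknown_metric_fatal(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError, match="unknown metric"):
            npharm.top_hubs(npharm.centralities(g), "pagerank")

    def test_ties_break_by_symbol(self):
        g = nx.Graph([("B", "C"), ("A", "C")])  # A and B both degree 1
        hubs = npharm.top_hubs(npharm.centralities(g), "degree", k=3)
        assert hubs == ["C", "A", "B"]


class TestEnrich:
    def test_degenerate_full_overlap(self):
        uni = {"A", "B", "C"}
        res = npharm.enrich(uni, {"t": ("d", set(uni))}, uni)
        assert res[0].p_value == pytest.approx(1.0)

    def test_exact_tail_example(self):
        # M=20, K=5, n=5, k=4 -> P(X>=4) = 76/15504
        uni = [f"G{i}" for i in range(20)]
        term = set(uni[:5])
        query = set(uni[:4]) | {uni[10]}
        res = npharm.enrich(query, {"t": ("d", term)}, uni)
        assert res[0].k == 4
        assert res[0].p_value == pytest.approx(76 / 15504, rel=1e-12)

    def test_disjoint_term_p_one(self):
        uni = [f"G{i}" for i in range(20)]
        res = npharm.enrich(set(uni[:5]), {"t": ("d", set(uni[10:13]))}, uni)
        assert res[0].k == 0 and res[0].p_value == pytest.approx(1.0)

    def test_out_of_universe_query_dropped_with_warning(self):
        uni = ["A", "B", "C", "D"]
        with pytest.warns(UserWarning, match="outside universe"):
            res = npharm.enrich({"A", "ZZZ"}, {"t": ("d", {"A", "B"})}, uni)
        assert res[0].n == 1

    def test_symbol_renaming_invariance(self):
        uni = [f"G{i}" for i in range(15)]
        term = set(uni[:6])
        query = set(uni[:4]) | set(uni[8:10])
        p1 = npharm.enrich(query, {"t": ("d", term)}, uni)[0].p_value
        ren = {g: f"X{g}" for g in uni}
        p2 = npharm.enrich(
            {ren[g] for g in query},
            {"t": ("d", {ren[g] for g in term})},
            [ren[g] for g in uni],
        )[0].p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_bh_qvalues_monotone_in_p_rank(self, tmp_path):
        uni = [f"G{i}" for i in range(40)]
        gmt_path = tmp_path / "sets.gmt"
        datasets.make_gmt(gmt_path, uni, seed=3, n_terms=10)
        sets = npharm.read_gmt(gmt_path)
        res = npharm.enrich(set(uni[:8]), sets, uni)
        ps = [r.p_value for r in res]
        qs = [r.q_value for r in res]
        assert ps == sorted(ps)
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))

    def test_planted_term_detected(self, tmp_path):
        uni = sorted(set([f"G{i}" for i in range(60)]) | set(datasets.HUB_TARGETS))
        gmt_path = tmp_path / "sets.gmt"
        planted = datasets.make_gmt(gmt_path, uni, seed=4)
        res = npharm.enrich(set(datasets.HUB_TARGETS), npharm.read_gmt(gmt_path), uni)
        assert res[0].term == planted and res[0].significant

    def test_empty_universe_fatal(self):
        with pytest.raises(ValueError, match="universe"):
            npharm.enrich({"A"}, {}, [])
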