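"""Topology statistics against closed forms and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from bpgrn import (
    CommunityPartition,
    InvalidInputError,
    UndefinedStatisticError,
    average_clustering_coefficient,
    average_degree,
    average_path_length,
    compare_stats,
    compute_stats,
    detect_communities,
    graph_density,
    modularity,
)
from conftest import make_network, make_undirected


# ---------------------------------------------------------------------------
# brute-force oracles (independent of networkx)
# ---------------------------------------------------------------------------

def adj_from_net(net):
    nodes = list(net.gene_ids)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [set() for _ in nodes]
    for e in net.edges:
        adj[index[e.source]].add(index[e.target])
        adj[index[e.target]].add(index[e.source])
    return adj


def oracle_path_length(net):
    adj = adj_from_net(net)
    n = len(adj)
    total, pairs = 0, 0
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for v, d in dist.items():
            if v > s:
                total += d
                pairs += 1
    return total / pairs if pairs else None


def oracle_clustering(net):
    adj = adj_from_net(net)
    cs = []
    for i, nbrs in enumerate(adj):
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2)
                    if b in adj[a])
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def oracle_degree(net):
    adj = adj_from_net(net)
    return float(np.mean([len(a) for a in adj]))


def oracle_modularity(net, partition):
    """Direct Newman-Girvan e-matrix computation."""
    adj = adj_from_net(net)
    nodes = list(net.gene_ids)
    comm = [partition.assignment[v] - 1 for v in nodes]
    edges = [(i, j) for i in range(len(nodes)) for j in adj[i] if j > i]
    m = len(edges)
    k = partition.k
    e = np.zeros((k, k))
    for i, j in edges:
        e[comm[i], comm[j]] += 1
        e[comm[j], comm[i]] += 1
    e /= 2.0 * m
    a = e.sum(axis=1)
    return float(np.trace(e) - np.sum(a**2))


def set_partitions(items):
    """All set partitions (restricted-growth strings)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def random_net(seed, max_nodes=8):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_nodes + 1))
    p = rng.uniform(0.2, 0.8)
    genes = [f"n{i}" for i in range(n)]
    pairs = [(genes[i], genes[j]) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return make_undirected(genes, pairs)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

TRIANGLE = make_undirected("abc", [("a", "b"), ("b", "c"), ("a", "c")])
PATH3 = make_undirected("abc", [("a", "b"), ("b", "c")])
STAR4 = make_undirected("abcd", [("a", "b"), ("a", "c"), ("a", "d")])
K4_MINUS_E = make_undirected("abcd", [("a", "b"), ("a", "c"), ("a", "d"),
                                      ("b", "c"), ("b", "d")])
TWO_EDGES = make_undirected("abcd", [("a", "b"), ("c", "d")])
TWO_TRIANGLES = make_undirected("abcdef", [("a", "b"), ("b", "c"), ("a", "c"),
                                           ("d", "e"), ("e", "f"), ("d", "f")])


class TestClosedForms:
    def test_triangle_bundle(self):
        st = compute_stats(TRIANGLE, seed=0)
        assert (st.L, st.C, st.K, st.Q, st.D) == (1.0, 1.0, 2.0, 0.0, 1.0)

    def test_three_node_path_length(self):
        assert average_path_length(PATH3) == pytest.approx(4 / 3)

    def test_single_edge_components_have_unit_path_length(self):
        assert average_path_length(TWO_EDGES) == 1.0

    def test_star_has_zero_clustering(self):
        assert average_clustering_coefficient(STAR4) == 0.0

    def test_k4_minus_edge_clustering(self):
        assert average_clustering_coefficient(K4_MINUS_E) == pytest.approx(5 / 6)

    def test_degree_counting(self):
        assert average_degree(TRIANGLE) == 2.0
        empty = make_undirected("abc", [])
        assert average_degree(empty) == 0.0
        assert average_degree(TWO_EDGES) == 1.0  # 2 edges over 4 nodes

    def test_density(self):
        assert graph_density(TRIANGLE) == 1.0
        assert graph_density(make_undirected("abc", [])) == 0.0

    def test_edgeless_path_length_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            average_path_length(make_undirected("ab", []))

    def test_triangle_is_one_community_with_zero_modularity(self):
        part = detect_communities(TRIANGLE, seed=0)
        assert part.k == 1
        assert modularity(TRIANGLE, part) == 0.0

    def test_disconnected_triangles_split_into_two_communities(self):
        part = detect_communities(TWO_TRIANGLES, seed=0)
        assert part.k == 2
        assert modularity(TWO_TRIANGLES, part) == pytest.approx(0.5)

    def test_uncovered_node_rejected(self):
        part = CommunityPartition(assignment={"a": 1, "b": 1}, k=1)
        with pytest.raises(InvalidInputError):
            modularity(PATH3, part)


class TestOracles:
    @pytest.mark.parametrize("seed", range(12))
    def test_l_c_k_d_match_bruteforce(self, seed):
        net = random_net(seed)
        if any(len(a) for a in adj_from_net(net)):
            expected_L = oracle_path_length(net)
            if expected_L is not None:
                assert average_path_length(net) == pytest.approx(expected_L)
        assert average_clustering_coefficient(net) == pytest.approx(
            oracle_clustering(net))
        assert average_degree(net) == pytest.approx(oracle_degree(net))
        assert graph_density(net) == pytest.approx(
            oracle_degree(net) / (net.n_nodes - 1))

    @pytest.mark.parametrize("seed", range(6))
    def test_modularity_matches_e_matrix_oracle_and_networkx(self, seed):
        net = random_net(seed)
        g = net.to_undirected()
        if g.number_of_edges() == 0:
            return
        part = detect_communities(net, seed=seed)
        q = modularity(net, part)
        assert q == pytest.approx(oracle_modularity(net, part))
        comms = {}
        for gene, c in part.assignment.items():
            comms.setdefault(c, set()).add(gene)
        assert q == pytest.approx(
            nx.community.modularity(g, list(comms.values())))

    def test_bridged_triangles_modularity(self):
        net = make_undirected("abcdef", [("a", "b"), ("b", "c"), ("a", "c"),
                                         ("d", "e"), ("e", "f"), ("d", "f"),
                                         ("c", "d")])
        part = CommunityPartition(
            assignment={"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2}, k=2)
        assert modularity(net, part) == pytest.approx(
            oracle_modularity(net, part))

    @pytest.mark.parametrize("seed", range(4))
    def test_louvain_beats_most_exhaustive_partitions(self, seed):
        net = random_net(seed, max_nodes=6)
        if net.to_undirected().number_of_edges() == 0:
            return
        part = detect_communities(net, seed=seed)
        q = modularity(net, part)
        qs = []
        for blocks in set_partitions(net.gene_ids):
            assignment = {}
            for ci, block in enumerate(blocks, start=1):
                for v in block:
                    assignment[v] = ci
            p = CommunityPartition(assignment=assignment, k=len(blocks))
            qs.append(modularity(net, p))
        assert q >= np.quantile(qs, 0.95) - 1e-12

    def test_relabel_invariance(self):
        net = random_net(3)
        mapping = {g: f"x_{g}" for g in net.gene_ids}
        relabeled = make_network(
            [mapping[g] for g in net.gene_ids],
            [(mapping[e.source], mapping[e.target]) for e in net.edges])
        for fn in (average_clustering_coefficient, average_degree):
            assert fn(net) == pytest.approx(fn(relabeled))
        s1, s2 = compute_stats(net, seed=0), compute_stats(relabeled, seed=0)
        assert (s1.L, s1.C, s1.K, s1.D) == (s2.L, s2.C, s2.K, s2.D)


class TestBundlesAndComparison:
    def test_bundle_reports_undefined_parts_with_reasons(self):
        empty = make_undirected("abcd", [])
        st = compute_stats(empty, seed=0)
        assert st.L is None and st.Q is None
        assert "L" in st.undefined and "Q" in st.undefined
        assert st.C == 0.0 and st.K == 0.0 and st.D == 0.0

    def test_bundle_is_deterministic_given_seed(self):
        net = random_net(5)
        a = compute_stats(net, seed=9)
        b = compute_stats(net, seed=9)
        assert a.as_dict() == b.as_dict()

    def test_density_degree_identity_holds_in_every_bundle(self):
        for seed in range(8):
            st = compute_stats(random_net(seed), seed=0)
            assert st.D == pytest.approx(st.K / (st.n_nodes - 1))

    def test_identical_networks_give_zero_differences(self):
        st = compute_stats(TRIANGLE, seed=0)
        table = compare_stats({"ref": [(0.5, st)], "alt": [(0.5, st)]},
                              reference="ref")
        assert len(table) == 5
        assert (table["difference"].fillna(0) == 0).all()

    def test_differences_are_antisymmetric(self):
        s1 = compute_stats(TRIANGLE, seed=0)
        s2 = compute_stats(K4_MINUS_E, seed=0)
        t_ab = compare_stats({"a": [(0.5, s1)], "b": [(0.5, s2)]},
                             reference="a")
        t_ba = compare_stats({"a": [(0.5, s1)], "b": [(0.5, s2)]},
                             reference="b")
        merged = t_ab.merge(t_ba, on=["threshold", "parameter"])
        np.testing.assert_allclose(merged["difference_x"],
                                   -merged["difference_y"])

    def test_mismatched_grids_rejected(self):
        st = compute_stats(TRIANGLE, seed=0)
        with pytest.raises(InvalidInputError):
            compare_stats({"a": [(0.5, st)], "b": [(0.6, st)]}, reference="a")
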