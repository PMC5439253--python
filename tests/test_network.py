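"""Coexpression adjacency, thresholding, components (BFS oracle) and hubs."""

import numpy as np
import pandas as pd
import pytest

from comira.network import (
    AdjacencySpec,
    CoexpressionGraph,
    build_network,
    connected_components,
    export_edge_list,
    gene_gene_adjacency,
    hub_genes,
    read_edge_list_tsv,
    threshold_edges,
)
from conftest import make_matrix

import networkx as nx


def corr_frame(r, genes=None):
    r = np.asarray(r, dtype=float)
    genes = genes or [f"G{i}" for i in range(r.shape[0])]
    return pd.DataFrame(r, index=genes, columns=genes)


def bfs_components(nodes, edges):
    """Independent breadth-first-search component oracle."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            n = queue.pop()
            if n in comp:
                continue
            comp.add(n)
            queue.extend(adj[n] - comp)
        seen |= comp
        comps.append(comp)
    return comps


class TestAdjacency:
    def test_power_formula(self, rng):
        # two genes with known correlation via direct construction
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        m = make_matrix([x, y], scale="log2")
        r = float(np.corrcoef(x, y)[0, 1])
        a1 = gene_gene_adjacency(m, AdjacencySpec(beta=1.0))
        a2 = gene_gene_adjacency(m, AdjacencySpec(beta=2.0))
        assert a1.iloc[0, 1] == pytest.approx(abs(r))
        assert a2.iloc[0, 1] == pytest.approx(r**2)

    def test_negative_correlation_unsigned(self):
        x = np.linspace(0, 1, 10)
        m = make_matrix([x, -x + 2], scale="log2")
        a = gene_gene_adjacency(m, AdjacencySpec(beta=2.0))
        assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_signed_variant(self):
        x = np.linspace(0, 1, 10)
        m = make_matrix([x, -x + 2], scale="log2")
        a = gene_gene_adjacency(m, AdjacencySpec(beta=1.0, signed=True))
        assert a.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)  # (1 + (-1))/2

    def test_matches_pairwise_loop_oracle(self, rng):
        vals = rng.normal(size=(10, 25))
        m = make_matrix(vals, scale="log2")
        a = gene_gene_adjacency(m, AdjacencySpec(beta=1.5)).to_numpy()
        for i in range(10):
            for j in range(10):
                expected = (
                    0.0 if i == j else abs(np.corrcoef(vals[i], vals[j])[0, 1]) ** 1.5
                )
                assert a[i, j] == pytest.approx(expected, abs=1e-12)

    def test_diagonal_zero_and_symmetric(self, rng):
        m = make_matrix(rng.normal(size=(6, 12)), scale="log2")
        a = gene_gene_adjacency(m, AdjacencySpec()).to_numpy()
        assert np.all(np.diag(a) == 0)
        np.testing.assert_allclose(a, a.T)

    def test_invariant_to_affine_rescaling_and_sample_permutation(self, rng):
        vals = rng.normal(size=(5, 20))
        a0 = gene_gene_adjacency(make_matrix(vals, scale="log2"), AdjacencySpec())
        scaled = vals.copy()
        scaled[2] = 3.0 * scaled[2] + 7.0
        perm = rng.permutation(20)
        a1 = gene_gene_adjacency(make_matrix(scaled[:, perm], scale="log2"), AdjacencySpec())
        np.testing.assert_allclose(a0.to_numpy(), a1.to_numpy(), atol=1e-12)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            AdjacencySpec(beta=0)
        with pytest.raises(ValueError):
            AdjacencySpec(edge_threshold=1.5)


class TestThreshold:
    def test_boundary_inclusive(self):
        r = corr_frame([[1, 0.70], [0.70, 1]])
        g = threshold_edges(r, threshold=0.7)
        assert g.edges == [("G0", "G1")]

    def test_just_below_boundary_excluded(self):
        r = corr_frame([[1, 0.6999999], [0.6999999, 1]])
        assert threshold_edges(r, threshold=0.7).edges == []

    def test_negative_correlation_counts(self):
        r = corr_frame([[1, -0.75], [-0.75, 1]])
        g = threshold_edges(r, threshold=0.7, on="correlation")
        assert g.edges == [("G0", "G1")]
        assert g.graph.edges["G0", "G1"]["r"] == pytest.approx(-0.75)

    def test_matches_double_loop_filter(self, rng):
        r = rng.uniform(-1, 1, size=(30, 30))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        g = threshold_edges(corr_frame(r), threshold=0.5)
        expected = {
            tuple(sorted((f"G{i}", f"G{j}")))
            for i in range(30)
            for j in range(i + 1, 30)
            if abs(r[i, j]) >= 0.5
        }
        assert set(g.edges) == expected

    def test_isolated_nodes_dropped(self):
        r = corr_frame(np.eye(3))
        g = threshold_edges(r, threshold=0.7)
        assert g.nodes == []

    def test_edge_set_shrinks_as_threshold_rises(self, rng):
        r = rng.uniform(-1, 1, size=(20, 20))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        prev = None
        for t in (0.3, 0.5, 0.7, 0.9):
            edges = set(threshold_edges(corr_frame(r), threshold=t).edges)
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_beta_one_correlation_and_adjacency_agree(self, rng):
        m = make_matrix(rng.normal(size=(12, 30)), scale="log2")
        adj = gene_gene_adjacency(m, AdjacencySpec(beta=1.0))
        from comira.network import gene_gene_correlation

        genes, r = gene_gene_correlation(m)
        g_corr = threshold_edges(
            pd.DataFrame(r, index=genes, columns=genes), threshold=0.4, on="correlation"
        )
        g_adj = threshold_edges(adj, threshold=0.4, on="adjacency")
        assert g_corr.edges == g_adj.edges


class TestComponents:
    def test_two_triangles(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")])
        comps = connected_components(CoexpressionGraph(g))
        assert comps == [{"a", "b", "c"}, {"x", "y", "z"}]  # tie -> smallest member

    def test_path_plus_edge(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("d", "e")])
        comps = connected_components(CoexpressionGraph(g))
        assert comps == [{"a", "b", "c"}, {"d", "e"}]

    def test_matches_bfs_oracle_on_random_graph(self, rng):
        nodes = [f"n{i}" for i in range(50)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(50)
            for j in range(i + 1, 50)
            if rng.random() < 0.05
        ]
        g = nx.Graph(edges)
        comps = connected_components(CoexpressionGraph(g))
        oracle = bfs_components(sorted(g.nodes), edges)
        assert set(map(frozenset, comps)) == set(map(frozenset, oracle))
        sizes = [len(c) for c in comps]
        assert sizes == sorted(sizes, reverse=True)
        assert sum(sizes) == g.number_of_nodes()

    def test_empty_graph(self):
        assert connected_components(CoexpressionGraph(nx.Graph())) == []


class TestHubs:
    def test_degree_boundary(self):
        g = nx.Graph()
        for k in range(21):
            g.add_edge("hub", f"leaf{k}")  # degree 21
        for k in range(20):
            g.add_edge("sub", f"other{k}")  # degree 20
        hubs = hub_genes(CoexpressionGraph(g))
        assert [h for h, _ in hubs] == ["hub"]

    def test_star_graph_center_only(self):
        g = nx.star_graph(25)
        g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
        hubs = hub_genes(CoexpressionGraph(g), min_degree_exclusive=20)
        assert hubs == [("n0", 25)]

    def test_dense_module_all_hubs(self, rng):
        # 30 genes sharing one latent factor at rho ~ 0.9: complete subgraph
        factor = rng.normal(size=80)
        vals = np.sqrt(0.9) * factor + np.sqrt(0.1) * rng.normal(size=(30, 80))
        g = build_network(make_matrix(vals, scale="log2"), AdjacencySpec(edge_threshold=0.7))
        hubs = hub_genes(g, min_degree_exclusive=20)
        assert len(hubs) == 30
        degrees = g.degree
        assert all(d == 29 for d in degrees.values())

    def test_hub_set_shrinks_with_degree(self, rng):
        g = nx.gnp_random_graph(40, 0.4, seed=3)
        g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
        cg = CoexpressionGraph(g)
        prev = None
        for d in (5, 10, 15):
            hubs = {h for h, _ in hub_genes(cg, min_degree_exclusive=d)}
            if prev is not None:
                assert hubs <= prev
            prev = hubs


class TestExport:
    def _graph(self):
        g = nx.Graph()
        g.add_edge("G2", "G1", r=0.8, weight=0.8)
        return CoexpressionGraph(g)

    def test_sif_canonical_ordering(self, tmp_path):
        path = tmp_path / "e.sif"
        export_edge_list(self._graph(), path, format="sif")
        assert path.read_text() == "G1\tco\tG2\n"

    def test_empty_graph_outputs(self, tmp_path):
        empty = CoexpressionGraph(nx.Graph())
        sif = tmp_path / "e.sif"
        tsv = tmp_path / "e.tsv"
        export_edge_list(empty, sif, format="sif")
        export_edge_list(empty, tsv, format="tsv")
        assert sif.read_text() == ""
        assert tsv.read_text().splitlines() == ["source\ttarget\tr\tweight"]

    def test_tsv_round_trip(self, tmp_path, rng):
        vals = rng.normal(size=(8, 40))
        vals[1] = vals[0] + 0.1 * rng.normal(size=40)
        vals[3] = -vals[2] + 0.1 * rng.normal(size=40)
        g = build_network(make_matrix(vals, scale="log2"), AdjacencySpec(edge_threshold=0.7))
        path = tmp_path / "edges.tsv"
        export_edge_list(g, path, format="tsv")
        back = read_edge_list_tsv(path)
        assert back.edges == g.edges
        for a, b in g.edges:
            assert back.graph.edges[a, b]["r"] == pytest.approx(g.graph.edges[a, b]["r"])
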