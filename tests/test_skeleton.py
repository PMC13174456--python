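"""Skeleton graph construction, midline extraction and ridge validation."""

import itertools

import networkx as nx
import numpy as np
import pytest

from dermatomics import skeleton
from dermatomics.skeleton import (
    BoundaryIndex,
    Branch,
    RidgeStatus,
    SkeletonNode,
    build_graph_and_mst,
    classify_and_validate,
    detect_nodes_and_branches,
    longest_path,
    skeletonize_component,
)


def graph_from_edges(edges):
    """Build an EpidermisGraph from (u, v, weight) triples for algorithm tests."""
    node_ids = sorted({u for u, v, _ in edges} | {v for _, v, _ in edges})
    nodes = [
        SkeletonNode(i, "junction", np.array([[i, 0]])) for i in node_ids
    ]
    branches = [
        Branch(bid, np.zeros((w, 2), int), (u, v))
        for bid, (u, v, w) in enumerate(edges)
    ]
    return build_graph_and_mst(nodes, branches)


class TestSkeletonize:
    def test_horizontal_band(self):
        m = np.zeros((20, 110), bool)
        m[8:13, 5:105] = True
        sk = skeletonize_component(m)
        n = sk.mask.sum()
        assert abs(n - 100) <= 5

    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        sk = skeletonize_component(m)
        assert sk.mask.sum() == 1 and sk.mask[2, 2]

    def test_disk_collapses(self):
        yy, xx = np.mgrid[:41, :41]
        m = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        assert skeletonize_component(m).mask.sum() <= 5


class TestNodesAndBranches:
    def test_straight_path(self):
        m = np.zeros((5, 14), bool)
        m[2, 2:12] = True  # 10 pixels
        nodes, branches = detect_nodes_and_branches(skeleton.Skeleton(m))
        kinds = sorted(n.kind for n in nodes)
        assert kinds == ["endpoint", "endpoint"]
        assert len(branches) == 1 and branches[0].length == 8

    def test_plus_shape(self):
        m = np.zeros((11, 11), bool)
        m[5, 1:10] = True
        m[1:10, 5] = True
        nodes, branches = detect_nodes_and_branches(skeleton.Skeleton(m))
        assert sum(n.kind == "junction" for n in nodes) == 1
        assert sum(n.kind == "endpoint" for n in nodes) == 4
        assert len(branches) == 4

    def test_two_pixel_segment(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[1, 2] = True
        nodes, branches = detect_nodes_and_branches(skeleton.Skeleton(m))
        assert sorted(n.kind for n in nodes) == ["endpoint", "endpoint"]
        assert branches == []


class TestGraphAndMST:
    def test_triangle(self):
        eg = graph_from_edges([(0, 1, 1), (1, 2, 2), (0, 2, 3)])
        weights = sorted(
            eg.graph.edges[e]["weight"] for e in eg.mst_edges
        )
        assert weights == [1, 2]

    def test_tree_input_keeps_all_edges(self):
        eg = graph_from_edges([(0, 1, 5), (1, 2, 3), (1, 3, 7)])
        assert len(eg.mst_edges) == 3

    def test_parallel_edges_keep_lighter(self):
        eg = graph_from_edges([(0, 1, 7), (0, 1, 4)])
        assert eg.graph.edges[0, 1]["weight"] == 4

    @pytest.mark.parametrize("seed", range(10))
    def test_mst_weight_matches_networkx(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        g = nx.gnp_random_graph(n, 0.4, seed=seed)
        edges = [
            (u, v, int(rng.integers(1, 50))) for u, v in g.edges
        ]
        if not edges:
            pytest.skip("empty random graph")
        eg = graph_from_edges(edges)
        mine = sum(eg.graph.edges[e]["weight"] for e in eg.mst_edges)
        ref_g = nx.Graph()
        ref_g.add_nodes_from(range(n))
        for u, v, w in edges:
            if not ref_g.has_edge(u, v) or ref_g.edges[u, v]["weight"] > w:
                ref_g.add_edge(u, v, weight=w)
        ref = nx.minimum_spanning_tree(ref_g).size(weight="weight")
        assert mine == ref


def brute_force_diameter(eg):
    """Oracle: max over all vertex pairs of tree path length."""
    t = nx.Graph()
    t.add_nodes_from(eg.graph.nodes)
    for u, v in eg.mst_edges:
        t.add_edge(u, v, weight=eg.graph.edges[u, v]["weight"])
    best = 0
    for a, b in itertools.combinations(t.nodes, 2):
        if nx.has_path(t, a, b):
            best = max(best, nx.dijkstra_path_length(t, a, b))
    return best


class TestLongestPath:
    def test_path_graph(self):
        eg = graph_from_edges([(0, 1, 3), (1, 2, 5), (2, 3, 2)])
        path, length = longest_path(eg)
        assert length == 10 and path == [0, 1, 2, 3]

    def test_star(self):
        eg = graph_from_edges([(0, 1, 10), (0, 2, 20), (0, 3, 30)])
        _, length = longest_path(eg)
        assert length == 50

    def test_single_vertex(self):
        eg = build_graph_and_mst(
            [SkeletonNode(0, "endpoint", np.array([[0, 0]]))], []
        )
        path, length = longest_path(eg)
        assert length == 0

    def test_random_trees_match_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            tree = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
            edges = [(u, v, int(rng.integers(1, 30))) for u, v in tree.edges]
            eg = graph_from_edges(edges)
            _, length = longest_path(eg)
            assert length == brute_force_diameter(eg)


def band_with_ridges(n_down=4, up_spur=True):
    """Tissue + epidermis masks: a band with downward ridges and optionally
    one upward spur toward the outer (top) surface."""
    H, W = 240, 1200
    tissue = np.zeros((H, W), bool)
    tissue[40:, :] = True  # top surface at row 40
    epi = np.zeros((H, W), bool)
    epi[40:60, :] = True
    for i in range(n_down):
        xc = 200 + i * 250
        epi[60:120, xc - 8 : xc + 8] = True
    if up_spur:
        # spur erupting above the band would pierce the surface; model it as
        # a thin protrusion hugging the top boundary
        tissue[20:40, 596:604] = True
        epi[20:40, 596:604] = True
    return tissue, epi


class TestClassifyAndValidate:
    def test_midline_length_rule_rejects_short(self):
        for n_px, accepted in ((501, False), (503, True)):
            m = np.zeros((5, n_px + 4), bool)
            m[2, 2 : 2 + n_px] = True  # branch weight = n_px - 2
            tissue = np.ones_like(m)
            g = skeleton.analyze_component(m, BoundaryIndex(tissue), 500)
            assert g.accepted is accepted
            assert g.midline_length == n_px - 2

    def test_directional_ridge_filter(self):
        tissue, epi = band_with_ridges(n_down=4, up_spur=True)
        g = skeleton.analyze_component(epi, BoundaryIndex(tissue), 500)
        assert g.accepted
        assert len(g.valid_ridges) == 4
        rejected = [r for r in g.ridges if r.status is RidgeStatus.REJECTED]
        assert len(rejected) == 1
        assert "closer to boundary" in rejected[0].reason

    def test_tie_is_valid(self):
        # equal tip and base boundary distance must NOT discard the ridge
        eg = graph_from_edges([(0, 1, 600), (1, 2, 600), (1, 3, 40)])
        eg.nodes[1].member_pixels = np.array([[50, 50]])
        eg.nodes[1].__post_init__()
        eg.nodes[3].member_pixels = np.array([[50, 90]])
        eg.nodes[3].__post_init__()
        boundary = BoundaryIndex(np.ones((120, 120), bool))
        # interior mask: no boundary pixels -> distances equal (inf)
        g = classify_and_validate(eg, boundary, 500)
        ridge = [r for r in g.ridges][0]
        assert ridge.status is RidgeStatus.VALID

    def test_determinism(self, he_phantom):
        _, truth = he_phantom
        tb = BoundaryIndex(truth.tissue_mask)
        g1 = skeleton.analyze_component(truth.epidermis_mask, tb, 500)
        g2 = skeleton.analyze_component(truth.epidermis_mask, tb, 500)
        s1 = [(r.edge, r.status.value, r.branch.length) for r in g1.ridges]
        s2 = [(r.edge, r.status.value, r.branch.length) for r in g2.ridges]
        assert s1 == s2 and g1.midline_length == g2.midline_length
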