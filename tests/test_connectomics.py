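"""Mask-to-graph conversion, skeleton geometry and network metrics."""

import math

import numpy as np
import pytest
from skimage.morphology import skeletonize

from conftest import as_mask, flood_fill_components

from osteograph.connectomics import (
    CROSS_2x2,
    ELLIPSE_4x4,
    build_graph,
    components,
    compute_metrics,
    dilate_classes,
    measure_diameter,
    measure_length,
    shortest_path_length,
)
from osteograph.errors import ValidationError
from osteograph.synth import make_scene, recovery_params

PX = 150.0  # nm


def blob(mask, y, x, h=3, w=3, label=1):
    mask[y : y + h, x : x + w] = label


class TestStructuringElements:
    def test_frozen_footprints(self):
        np.testing.assert_array_equal(
            ELLIPSE_4x4,
            [[0, 1, 1, 0], [1, 1, 1, 1], [1, 1, 1, 1], [0, 1, 1, 0]],
        )
        np.testing.assert_array_equal(CROSS_2x2, [[1, 1], [1, 0]])

    def test_single_dendrite_pixel_cross_footprint(self):
        m = np.zeros((7, 7), np.uint8)
        m[3, 3] = 2
        _, dend = dilate_classes(as_mask(m))
        assert dend.sum() == CROSS_2x2.sum()

    def test_nearby_osteocyte_blobs_merge(self):
        """Two blobs separated by a 2 px gap become one component after the
        4x4 ellipse dilation (flood-fill oracle count)."""
        m = np.zeros((16, 16), np.uint8)
        blob(m, 4, 2)
        blob(m, 4, 7)  # gap columns 5-6
        osteo, _ = dilate_classes(as_mask(m))
        assert flood_fill_components(osteo).max() == 1
        # undilated they are two components
        assert flood_fill_components(m == 1).max() == 2


class TestComponents:
    def test_empty(self):
        lbl, n = components(np.zeros((5, 5), bool))
        assert n == 0 and not lbl.any()

    def test_diagonal_connectivity_rule(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[2, 2] = True
        assert components(m, 8)[1] == 1
        assert components(m, 4)[1] == 2

    def test_matches_flood_fill_partition(self, rng):
        for _ in range(10):
            m = rng.random((32, 32)) < 0.3
            lbl, n = components(m, 8)
            oracle = flood_fill_components(m, 8)
            assert n == oracle.max()
            # identical partition: label maps are a relabelling of each other
            pairs = {(a, b) for a, b in zip(lbl[m], oracle[m])}
            assert len(pairs) == n


class TestBuildGraph:
    def test_two_blobs_one_line(self):
        m = np.zeros((20, 30), np.uint8)
        blob(m, 8, 2, 4, 4)
        blob(m, 8, 24, 4, 4)
        m[9, 6:24] = 2
        g = build_graph(as_mask(m), PX)
        assert g.n_nodes == 2 and g.n_edges == 1
        assert sum(g.deadend_counts.values()) == 0

    def test_protruding_line_is_deadend(self):
        m = np.zeros((20, 30), np.uint8)
        blob(m, 8, 2, 4, 4)
        m[9, 6:20] = 2
        g = build_graph(as_mask(m), PX)
        assert g.n_nodes == 1 and g.n_edges == 0
        assert g.deadend_counts[0] == 1

    def test_no_transitive_edges_in_chain(self):
        """A-B-C via two separate dendrites: edges {A,B}, {B,C}, never {A,C}."""
        m = np.zeros((20, 60), np.uint8)
        blob(m, 8, 2, 4, 4)
        blob(m, 8, 28, 4, 4)
        blob(m, 8, 54, 4, 4)
        m[9, 6:28] = 2
        m[10, 32:54] = 2
        g = build_graph(as_mask(m), PX)
        assert g.n_nodes == 3 and g.n_edges == 2
        edges = {tuple(sorted(e[:2])) for e in g.graph.edges()}
        nodes_by_x = sorted(g.nodes, key=lambda n: n.centroid[1])
        a, b, c = (n.id for n in nodes_by_x)
        assert edges == {tuple(sorted((a, b))), tuple(sorted((b, c)))}

    def test_orphan_component_recorded_without_edges(self):
        m = np.zeros((20, 20), np.uint8)
        m[10, 2:18] = 2
        g = build_graph(as_mask(m), PX)
        assert g.n_nodes == 0 and g.n_edges == 0
        assert len(g.dendrite_components) == 1
        assert g.dendrite_components[0].kind == "orphan"

    def test_multi_contact_component_forms_clique(self):
        """A dendrite component touching three osteocytes yields all three
        pairwise connections (no osteocyte lies on the shared route)."""
        m = np.zeros((40, 40), np.uint8)
        blob(m, 2, 18, 4, 4)
        blob(m, 30, 2, 4, 4)
        blob(m, 30, 34, 4, 4)
        m[6:30, 19] = 2          # vertical stem
        m[29, 5:20] = 2          # left arm
        m[29, 19:34] = 2         # right arm
        g = build_graph(as_mask(m), PX)
        assert g.n_nodes == 3
        assert g.n_edges == 3


class TestGeometry:
    def test_straight_line_length(self):
        comp = np.zeros((5, 14), bool)
        comp[2, 2:12] = True  # 10 px
        # 9 inter-pixel steps x 150 nm = 1.35 um
        assert measure_length(comp, PX) == pytest.approx(1.35, abs=1e-9)

    def test_diagonal_line_length(self):
        comp = np.eye(10, dtype=bool)
        expected = 9 * math.sqrt(2) * PX / 1000.0
        assert measure_length(comp, PX) == pytest.approx(expected, rel=1e-9)

    def test_curved_dendrite_close_to_true_arc(self):
        sc = make_scene(recovery_params(seed=1))
        from osteograph.connectomics import build_graph

        g = build_graph(sc.mask)
        meas = sorted(d["length_um"] for _, _, d in g.graph.edges(data=True))
        true = sorted(e.length_um for e in sc.graph.edges)
        assert len(meas) == len(true)
        for t, m in zip(true, meas):
            assert abs(m - t) / t < 0.10

    def test_ribbon_diameter_three_px(self):
        comp = np.zeros((10, 30), bool)
        comp[4:7, 3:27] = True
        # 3 px x 150 nm = 0.45 um
        assert measure_diameter(comp, PX) == pytest.approx(0.45, rel=0.15)

    def test_single_pixel_line_diameter(self):
        comp = np.zeros((6, 20), bool)
        comp[3, 2:18] = True
        assert measure_diameter(comp, PX) == pytest.approx(0.15, rel=0.2)

    def test_diameter_monotone_in_width(self):
        narrow = np.zeros((12, 30), bool)
        narrow[5:7, 3:27] = True
        wide = np.zeros((12, 30), bool)
        wide[4:8, 3:27] = True
        assert measure_diameter(narrow, PX) < measure_diameter(wide, PX)

    def test_skeleton_backend_golden(self):
        """Frozen medial-axis output of an L-shaped ribbon guards against
        thinning-backend drift."""
        L = np.zeros((12, 12), bool)
        L[2:5, 2:10] = True
        L[2:10, 2:5] = True
        expected = {(2, 8), (3, 4), (3, 5), (3, 6), (3, 7), (4, 3),
                    (5, 3), (6, 3), (7, 3)}
        assert set(map(tuple, np.argwhere(skeletonize(L)))) == expected

    def test_empty_component_rejected(self):
        with pytest.raises(ValidationError):
            measure_length(np.zeros((4, 4), bool), PX)


class TestMetricsAndPaths:
    def _simple_graph(self):
        m = np.zeros((20, 30), np.uint8)
        blob(m, 8, 2, 4, 4)
        blob(m, 8, 24, 4, 4)
        m[9, 6:24] = 2
        return build_graph(as_mask(m), PX)

    def test_connections_per_node_identity(self):
        g = self._simple_graph()
        cm = compute_metrics(g)
        assert cm.connections_per_node == pytest.approx(2 * g.n_edges / g.n_nodes)
        assert cm.connections_per_node == pytest.approx(1.0)

    def test_deadends_per_node(self):
        m = np.zeros((24, 24), np.uint8)
        blob(m, 10, 10, 4, 4)
        m[11, 14:22] = 2
        m[4:10, 11] = 2
        g = build_graph(as_mask(m), PX)
        assert compute_metrics(g).deadends_per_node == pytest.approx(2.0)

    def test_zero_node_graph_warns_and_zeroes(self):
        g = build_graph(as_mask(np.zeros((8, 8))), PX)
        with pytest.warns(UserWarning):
            cm = compute_metrics(g)
        assert cm.n_nodes == 0 and cm.connections_per_node == 0.0

    def test_hop_counts_and_unreachable(self):
        m = np.zeros((20, 60), np.uint8)
        blob(m, 8, 2, 4, 4)
        blob(m, 8, 28, 4, 4)
        blob(m, 8, 54, 4, 4)
        m[9, 6:28] = 2
        m[10, 32:54] = 2
        g = build_graph(as_mask(m), PX)
        nodes_by_x = sorted(g.nodes, key=lambda n: n.centroid[1])
        a, b, c = (n.id for n in nodes_by_x)
        assert shortest_path_length(g, a, b) == 1
        assert shortest_path_length(g, a, c) == 2
        with pytest.raises(ValidationError):
            shortest_path_length(g, a, 99)

    def test_disconnected_pair_is_unreachable(self):
        m = np.zeros((20, 40), np.uint8)
        blob(m, 8, 2, 4, 4)
        blob(m, 8, 34, 4, 4)
        g = build_graph(as_mask(m), PX)
        assert shortest_path_length(g, 0, 1) == math.inf

    def test_metrics_invariant_to_relabelling(self):
        m = np.zeros((30, 30), np.uint8)
        blob(m, 4, 4, 4, 4)
        blob(m, 20, 20, 4, 4)
        m[6, 8:21] = 2
        m[8:20, 21] = 2
        g1 = build_graph(as_mask(m), PX)
        g2 = build_graph(as_mask(np.rot90(m, 2).copy()), PX)  # relabels nodes
        c1, c2 = compute_metrics(g1), compute_metrics(g2)
        assert c1.n_nodes == c2.n_nodes
        assert c1.connections_per_node == pytest.approx(c2.connections_per_node)

    def test_dilation_never_increases_component_count(self, rng):
        for _ in range(10):
            labels = (rng.random((32, 32)) < 0.25).astype(np.uint8) * 2
            mask = as_mask(labels)
            _, dend = dilate_classes(mask)
            assert components(dend, 8)[1] <= components(labels == 2, 8)[1]

    def test_parallel_routes_counted_and_collapsible(self):
        m = np.zeros((22, 30), np.uint8)
        blob(m, 4, 2, 14, 4)
        blob(m, 4, 24, 14, 4)
        m[6, 6:24] = 2
        m[15, 6:24] = 2
        dual = build_graph(as_mask(m), PX)
        assert dual.n_edges == 2  # two independent routes
        single = build_graph(as_mask(m), PX, unique_partners=True)
        assert single.n_edges == 1
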