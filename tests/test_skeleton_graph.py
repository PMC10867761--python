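"""Skeletonization, graph construction, disc exclusion and segment tracing."""

import math

import networkx as nx
import numpy as np
import pytest

from vasctort import (
    BinaryMask,
    DiscCenter,
    SkeletonMask,
    build_vessel_graph,
    chain_arc_length,
    exclude_disc_region,
    extract_segments,
    skeletonize_mask,
)

SQRT2 = math.sqrt(2.0)


def brute_force_degrees(pix: np.ndarray) -> dict:
    """Independent oracle: count true 8-neighbors of every true pixel."""
    degs = {}
    rows, cols = pix.shape
    for r, c in zip(*np.nonzero(pix)):
        d = 0
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and pix[rr, cc]:
                    d += 1
        degs[(int(r), int(c))] = d
    return degs


class TestSkeletonize:
    def test_solid_bar_thins_to_path(self, straight_bar_mask):
        skel = skeletonize_mask(straight_bar_mask)
        g = build_vessel_graph(skel)
        assert nx.number_connected_components(g.graph) == 1
        assert len(g.nodes_of_class("endpoint")) == 2
        assert len(g.nodes_of_class("branch")) == 0

    def test_plus_sign_one_junction_region_four_endpoints(self, plus_sign_mask):
        skel = skeletonize_mask(plus_sign_mask)
        degs = brute_force_degrees(skel.pixels)
        endpoints = [n for n, d in degs.items() if d == 1]
        branch = [n for n, d in degs.items() if d >= 3]
        assert len(endpoints) == 4
        # branch pixels may form a small cluster, but exactly one region
        sub = nx.Graph()
        sub.add_nodes_from(branch)
        for a in branch:
            for b in branch:
                if a < b and max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1:
                    sub.add_edge(a, b)
        assert nx.number_connected_components(sub) == 1

    def test_empty_mask_legal(self):
        skel = skeletonize_mask(BinaryMask(np.zeros((32, 32), dtype=bool), "e"))
        assert skel.pixels.sum() == 0

    def test_thinning_idempotent(self, plus_sign_mask):
        once = skeletonize_mask(plus_sign_mask)
        twice = skeletonize_mask(once)
        np.testing.assert_array_equal(once.pixels, twice.pixels)


class TestVesselGraph:
    def test_straight_path_counts(self):
        pix = np.zeros((5, 14), dtype=bool)
        pix[2, 2:12] = True  # 10-px path
        g = build_vessel_graph(SkeletonMask(pix))
        assert g.n_nodes == 10
        assert g.n_edges == 9
        assert len(g.nodes_of_class("endpoint")) == 2
        assert len(g.nodes_of_class("slab")) == 8

    def test_y_shape_degrees_match_brute_force(self, y_skeleton_pixels):
        g = build_vessel_graph(SkeletonMask(y_skeleton_pixels))
        oracle = brute_force_degrees(y_skeleton_pixels)
        assert {n: g.degree(n) for n in g.graph.nodes} == oracle
        assert len(g.nodes_of_class("endpoint")) == 3
        assert len(g.nodes_of_class("branch")) == 1

    def test_isolated_pixel(self):
        pix = np.zeros((3, 3), dtype=bool)
        pix[1, 1] = True
        g = build_vessel_graph(SkeletonMask(pix))
        assert g.n_nodes == 1 and g.n_edges == 0
        assert g.node_class((1, 1)) == "isolated"


class TestDiscExclusion:
    def test_radius_zero_is_identity(self, y_skeleton_pixels):
        g = build_vessel_graph(SkeletonMask(y_skeleton_pixels))
        g2 = exclude_disc_region(g, DiscCenter(20, 20, "y"), 0.0)
        assert set(g2.graph.nodes) == set(g.graph.nodes)

    def test_path_through_disc_splits_in_two(self):
        pix = np.zeros((5, 61), dtype=bool)
        pix[2, :] = True
        g = build_vessel_graph(SkeletonMask(pix))
        g2 = exclude_disc_region(g, DiscCenter(2, 30, "p"), 5.0)
        comps = g2.components()
        assert len(comps) == 2  # flood-fill oracle: two sides of the cut
        removed = set(g.graph.nodes) - set(g2.graph.nodes)
        assert all(abs(c - 30) <= 5 for _, c in removed)

    def test_disc_outside_content_unchanged(self, y_skeleton_pixels):
        g = build_vessel_graph(SkeletonMask(y_skeleton_pixels))
        g2 = exclude_disc_region(g, DiscCenter(0, 39, "y"), 3.0)
        assert g2.n_nodes == g.n_nodes


class TestExtractSegments:
    def test_straight_50px_path(self):
        pix = np.zeros((5, 60), dtype=bool)
        pix[2, 5:55] = True
        g = build_vessel_graph(SkeletonMask(pix))
        segs = extract_segments(g, DiscCenter(2, 0, "p"))
        assert len(segs) == 1
        assert segs[0].arc_length_px == pytest.approx(49.0)
        assert segs[0].n_points == 50

    def test_y_shape_three_segments(self):
        pix = np.zeros((80, 80), dtype=bool)
        c = (40, 40)
        pix[c] = True
        for k in range(1, 31):  # arms of 30 px
            pix[40 - k, 40] = True
            pix[40 + k, 40 - k] = True
            pix[40 + k, 40 + k] = True
        g = build_vessel_graph(SkeletonMask(pix))
        segs = extract_segments(g, DiscCenter(0, 40, "y"))
        assert len(segs) == 3
        # all three share the junction pixel as a terminal
        terminals = {s.chain[0] for s in segs} | {s.chain[-1] for s in segs}
        assert c in terminals

    def test_short_spur_pruned(self):
        pix = np.zeros((20, 60), dtype=bool)
        pix[10, 5:55] = True  # 50-px path
        for k in range(1, 6):
            pix[10 - k, 30] = True  # 5-px side spur
        g = build_vessel_graph(SkeletonMask(pix))
        segs = extract_segments(g, DiscCenter(10, 0, "s"), spur_length_px=10.0)
        assert len(segs) == 1
        assert segs[0].arc_length_px == pytest.approx(49.0)
        # no branch nodes remain anywhere in the chain
        interior = segs[0].chain[1:-1]
        assert (10, 30) in set(segs[0].chain)
        assert len(interior) == 48

    def test_min_length_filter(self):
        pix = np.zeros((5, 20), dtype=bool)
        pix[2, 2:12] = True  # 10-px path, arc 9
        g = build_vessel_graph(SkeletonMask(pix))
        assert extract_segments(g, DiscCenter(2, 0, "m"), min_length_px=20) == []
        assert len(extract_segments(g, DiscCenter(2, 0, "m"), min_length_px=5)) == 1

    def test_orientation_proximal_first(self):
        pix = np.zeros((5, 60), dtype=bool)
        pix[2, 5:55] = True
        g = build_vessel_graph(SkeletonMask(pix))
        for disc_col, first_col in ((0, 5), (59, 54)):
            (seg,) = extract_segments(g, DiscCenter(2, disc_col, "o"))
            assert seg.chain[0][1] == first_col

    def test_empty_graph_empty_list(self):
        g = build_vessel_graph(SkeletonMask(np.zeros((4, 4), dtype=bool)))
        assert extract_segments(g, DiscCenter(0, 0, "e")) == []

    def test_arc_length_matches_step_oracle(self, y_skeleton_pixels):
        g = build_vessel_graph(SkeletonMask(y_skeleton_pixels))
        for seg in extract_segments(g, DiscCenter(0, 20, "y"), min_length_px=5):
            oracle = sum(
                SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0
                for a, b in zip(seg.chain, seg.chain[1:])
            )
            assert seg.arc_length_px == pytest.approx(oracle)
            assert seg.arc_length_px >= seg.chord_length_px


def test_segment_cover_of_synthetic_retina(small_synth_config):
    """Union of chains covers all surviving non-branch skeleton nodes."""
    from vasctort import generate_retina

    mask, disc, _ = generate_retina(small_synth_config)
    g = build_vessel_graph(skeletonize_mask(mask))
    g = exclude_disc_region(g, disc, 30.0)
    segs = extract_segments(g, disc, min_length_px=0.0, spur_length_px=0.0)
    covered = set()
    for s in segs:
        covered |= set(s.chain)
    non_branch = {n for n in g.graph.nodes if g.degree(n) < 3}
    # without pruning or min-length losses every non-branch node is covered
    uncovered = non_branch - covered
    assert len(uncovered) == 0
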