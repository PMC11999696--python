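import math

import numpy as np
import pytest

from pcmorph import synth
from pcmorph.arbor import (
    arbor_extent_and_shape, assign_region, branch_eccentricity,
    branch_height_profile, decompose_branches, diameter_profile,
    segment_eccentricity, sholl_profile, summarize, thin_caliber_threshold,
    total_length,
)

from conftest import build_arbor


def chain_arbor(points, radius=0.5):
    """Soma at the first point, dendrite chain through the rest."""
    nodes = [(1, "soma", *points[0], radius, -1)]
    for i, p in enumerate(points[1:], start=2):
        nodes.append((i, "dendrite", *p, radius, i - 1))
    return build_arbor(nodes)


def y_tree(limb1=5.0, limb2=2.0, limb3=2.0):
    """Trunk of length limb1 up the radial axis, then two daughters."""
    return build_arbor([
        (1, "soma", 0, 0, 0, 1.0, -1),
        (2, "dendrite", 0, limb1, 0, 0.5, 1),
        (3, "dendrite", limb2, limb1, 0, 0.5, 2),
        (4, "dendrite", -limb3, limb1, 0, 0.5, 2),
    ])


class TestBranchDecomposition:
    def test_y_tree_three_segments_orders_1_2_2(self):
        segs = decompose_branches(y_tree())
        assert len(segs) == 3
        assert sorted(s.order for s in segs) == [1, 2, 2]
        assert sum(s.is_terminal for s in segs) == 2
        assert total_length(y_tree()) == pytest.approx(9.0)

    def test_unbranched_chain_is_one_terminal_order1_segment(self):
        arb = chain_arbor([(0, 0, 0), (3, 0, 0), (3, 4, 0)])
        segs = decompose_branches(arb)
        assert len(segs) == 1 and segs[0].order == 1 and segs[0].is_terminal
        assert segs[0].length == pytest.approx(7.0)  # 3-4-5 triangle legs

    def test_random_binary_trees_have_2k_plus_trunks_segments(self, rng):
        # induction oracle: every bifurcation adds exactly 2 segments
        for _ in range(20):
            nodes = [(1, "soma", 0.0, 0.0, 0.0, 1.0, -1),
                     (2, "dendrite", 0.0, 1.0, 0.0, 0.5, 1)]
            tips = [2]
            k = 0
            for _ in range(int(rng.integers(1, 15))):
                tip = int(rng.choice(tips))
                tips.remove(tip)
                for _ in range(2):
                    nid = len(nodes) + 1
                    x, y, z = rng.normal(size=3)
                    nodes.append((nid, "dendrite", x, y + len(nodes), z, 0.5, tip))
                    tips.append(nid)
                k += 1
            segs = decompose_branches(build_arbor(nodes))
            assert len(segs) == 2 * k + 1

    def test_segment_lengths_partition_total_length(self, rng):
        arb, _ = synth.simulate_arbor(synth.mouse_arbor_config(seed=11), rng)
        segs = decompose_branches(arb)
        assert sum(s.length for s in segs) == pytest.approx(total_length(arb), rel=1e-12)

    def test_child_order_is_parent_order_plus_one(self, rng):
        arb, _ = synth.simulate_arbor(synth.mouse_arbor_config(seed=12), rng)
        segs = decompose_branches(arb)
        by_start = {s.rows[-1]: s for s in segs}
        for s in segs:
            parent = by_start.get(s.rows[0])
            if parent is not None:
                assert s.order == parent.order + 1

    def test_bookkeeping_matches_metrics_exactly(self, rng):
        arb, book = synth.simulate_arbor(synth.mouse_arbor_config(seed=13), rng)
        assert total_length(arb) == pytest.approx(book["total_length"], rel=1e-12)
        assert len(decompose_branches(arb)) == book["n_branches"]


class TestExtentAndShape:
    @pytest.mark.parametrize("w,h,expected", [
        (644.0, 366.0, 100 * (644 / 366 - 1)),   # ≈ +76: wider than tall
        (150.0, 150.0, 0.0),
        (143.0, 158.0, -100 * (158 / 143 - 1)),  # ≈ −10.5: taller than wide
    ])
    def test_shape_index_formula(self, w, h, expected):
        arb = build_arbor([
            (1, "soma", 0, 0, 0, 1.0, -1),
            (2, "dendrite", -w / 2, 0.0, 0, 0.5, 1),
            (3, "dendrite", w / 2, h, 0, 0.5, 2),
        ])
        width, height, shape = arbor_extent_and_shape(arb)
        assert (width, height) == (pytest.approx(w), pytest.approx(h))
        assert shape == pytest.approx(expected, abs=0.01)

    def test_single_point_arbor_raises_zero_extent(self):
        arb = chain_arbor([(0, 0, 0), (0, 0, 0)])
        with pytest.raises(ValueError, match="zero extent"):
            arbor_extent_and_shape(arb)


class TestEccentricity:
    @pytest.mark.parametrize("verts,expected", [
        ([(0, 0), (5, 0)], 0.0),                     # horizontal
        ([(0, 0), (1, 1)], 45.0),
        ([(0, 0), (-1, -1)], 45.0),                  # mirrored twin
        ([(0, 0), (2, 0), (2, 2)], math.degrees(math.atan(0.5))),  # Σxy/Σx² = 4/8
        ([(0, 0), (0, 3)], 90.0),                    # vertical
    ])
    def test_through_origin_fit(self, verts, expected):
        assert branch_eccentricity(np.array(verts, float)) == pytest.approx(expected)

    def test_invariant_under_global_mirroring(self, rng):
        for _ in range(50):
            v = rng.normal(size=(6, 2)) * 10
            e = branch_eccentricity(v)
            assert branch_eccentricity(-v) == pytest.approx(e)
            flipped = v * np.array([1.0, -1.0])
            assert branch_eccentricity(flipped) == pytest.approx(e)
            assert 0.0 <= e <= 90.0

    def test_degenerate_identical_vertices_flagged(self):
        assert branch_eccentricity(np.zeros((3, 2))) is None


class TestRegionAssignment:
    @pytest.mark.parametrize("tip_y,expected", [
        (60.0, "proximal"),        # midpoint at 0.1·H
        (300.0, "intermediate"),   # midpoint at 0.5·H
        (200.0, "proximal"),       # midpoint exactly at H/3: closed-left bin
        (580.0, "distal"),
    ])
    def test_thirds_of_molecular_layer(self, tip_y, expected):
        arb = build_arbor([
            (1, "soma", 0, 0, 0, 1.0, -1),
            (2, "dendrite", 0, tip_y, 0, 0.5, 1),
        ], ml=300.0)
        (seg,) = decompose_branches(arb)
        assert assign_region(seg, arb) == expected

    def test_midpoint_above_thickness_clamps_to_distal(self):
        arb = build_arbor([
            (1, "soma", 0, 0, 0, 1.0, -1),
            (2, "dendrite", 0, 800.0, 0, 0.5, 1),
        ], ml=300.0)
        (seg,) = decompose_branches(arb)
        with pytest.warns(UserWarning, match="clamped"):
            assert assign_region(seg, arb) == "distal"


class TestDiameters:
    def test_uniform_diameters_give_flat_profile_and_no_thin_cable(self):
        arb = y_tree()
        maxp, normalized, thin, thr = diameter_profile(arb)
        assert maxp == pytest.approx(1.0)  # all radii 0.5 on dendrites
        assert np.allclose(normalized.to_numpy(), 1.0)
        assert thin == 0.0
        assert thr == pytest.approx(1.0)   # sd(ln d) = 0 -> threshold = d

    def test_lognormal_threshold_closed_form(self, rng):
        mu, sigma = math.log(1.0), 0.35
        d = rng.lognormal(mu, sigma, size=20_000)
        assert thin_caliber_threshold(d) == pytest.approx(
            math.exp(mu + sigma), rel=0.02)

    def test_thin_fraction_by_length_weighting(self):
        # 95 µm of 0.8 µm cable + 5 µm of thick cable, threshold 1.31 µm
        arb = build_arbor([
            (1, "soma", 0, 0, 0, 1.0, -1),
            (2, "dendrite", 0, 95.0, 0, 0.4, 1),
            (3, "dendrite", 0, 100.0, 0, 2.5, 2),
            (4, "dendrite", 3.0, 95.0, 0, 2.5, 2),
        ])
        _, _, thin, _ = diameter_profile(arb, threshold=1.31)
        assert thin == pytest.approx(100.0 * 95.0 / 103.0, abs=0.01)

    def test_nonpositive_diameters_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="non-positive"):
            thr = thin_caliber_threshold(np.array([1.0, 1.0, 0.0]))
        assert thr == pytest.approx(1.0)


class TestSholl:
    def test_straight_radial_chain_spreads_1um_per_shell(self):
        arb = chain_arbor([(0, 0, 0), (0, 10, 0)])
        prof = sholl_profile(arb)
        assert len(prof.radii) == 10
        assert np.allclose(prof.length_per_shell, 1.0)

    def test_length_conservation_and_monotone_cumulative(self, rng):
        arb, _ = synth.simulate_arbor(synth.mouse_arbor_config(seed=21), rng)
        prof = sholl_profile(arb)
        assert prof.length_per_shell.sum() == pytest.approx(
            total_length(arb), rel=5e-3)
        cum = prof.cumulative_normalized
        assert np.all(np.diff(cum) >= -1e-12)
        assert cum[-1] == pytest.approx(1.0)

    def test_circle_arc_falls_in_single_shell(self):
        r = 2.5
        angles = np.linspace(0, np.pi / 2, 200)
        pts = [(r * math.cos(a), r * math.sin(a), 0.0) for a in angles]
        arb = chain_arbor([(0.0, 0.0, 0.0)] + pts)
        prof = sholl_profile(arb)
        # ignore the radial spoke from the soma out to the arc start
        spoke = r
        arc_lengths = prof.length_per_shell.copy()
        arc_lengths[:3] -= np.array([1.0, 1.0, 0.5])  # spoke spans shells 1..3
        k = math.ceil(r) - 1
        assert arc_lengths[k] == pytest.approx(prof.length_per_shell.sum() - spoke,
                                               rel=1e-3)

    def test_branch_counted_in_every_shell_it_crosses(self):
        arb = chain_arbor([(0, 0, 0), (0, 3.5, 0)])
        prof = sholl_profile(arb)
        assert list(prof.branch_count_per_shell) == [1, 1, 1, 1]


class TestBranchHeights:
    def test_unbranched_arbor_gives_empty_histogram(self):
        arb = chain_arbor([(0, 0, 0), (0, 10, 0)])
        assert branch_height_profile(arb).sum() == 0

    def test_single_midheight_bifurcation_hits_middle_bin(self):
        arb = build_arbor([
            (1, "soma", 0, 0, 0, 1.0, -1),
            (2, "dendrite", 0, 50.0, 0, 0.5, 1),
            (3, "dendrite", -10.0, 100.0, 0, 0.5, 2),
            (4, "dendrite", 10.0, 100.0, 0, 0.5, 2),
        ])
        hist = branch_height_profile(arb, n_bins=5)
        assert hist[2] == 1 and hist.sum() == 1


class TestSummary:
    def test_summary_is_internally_consistent(self, rng):
        arb, _ = synth.simulate_arbor(synth.mouse_arbor_config(seed=31), rng)
        s = summarize(arb)
        assert s.n_terminal_branches <= s.n_branches
        assert 0.0 <= s.thin_fraction <= 100.0
        assert s.max_order >= 1 and s.mean_order <= s.max_order
        assert s.n_primary_dendrites >= 1
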