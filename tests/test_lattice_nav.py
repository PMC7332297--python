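import math

import numpy as np
import pytest

from antmaze import lattice_nav as ln
from antmaze import synthetic_env as se


def full_lattice(nx=40, ny=24):
    return se.generate_bond_lattice(nx, ny, 1.0, seed=0)


def mid_strip(lat, width=8):
    lo = lat.ny // 2 - width // 2
    return ln.StripSpec(nx=lat.nx, ny=lat.ny, row_lo=lo, row_hi=lo + width)


class TestComponents:
    def test_full_lattice_single_component(self):
        lat = full_lattice()
        assert ln.giant_component(lat).all()

    def test_empty_lattice_components_are_singletons(self):
        lat = se.generate_bond_lattice(10, 10, 0.0, seed=0)
        giant = ln.giant_component(lat)
        assert giant.sum() == 1

    def test_supercritical_spans(self):
        spans = [
            ln.spans_left_right(se.generate_bond_lattice(80, 80, 0.7, seed=s))
            for s in range(5)
        ]
        assert np.mean(spans) == 1.0

    def test_subcritical_does_not_span(self):
        spans = [
            ln.spans_left_right(se.generate_bond_lattice(80, 80, 0.3, seed=s))
            for s in range(5)
        ]
        assert np.mean(spans) == 0.0


class TestStartNode:
    def test_full_lattice_exact_center(self):
        lat = full_lattice()
        strip = mid_strip(lat)
        assert ln.start_node(lat, strip) == (strip.center_row, 0)

    def test_isolated_center_falls_back_to_neighbor(self):
        lat = full_lattice(12, 12)
        strip = mid_strip(lat, 4)
        rc = strip.center_row
        h = lat.horizontal_edges.copy()
        v = lat.vertical_edges.copy()
        # disconnect the center node of column 0
        h[rc, 0] = False
        v[rc, 0] = False
        v[rc - 1, 0] = False
        cut = se.BondLattice(nx=12, ny=12, horizontal_edges=h, vertical_edges=v,
                             p=1.0)
        r, c = ln.start_node(cut, strip)
        assert (r, c) != (rc, 0)
        assert abs(r - rc) <= 1 and c <= 1

    def test_deterministic(self):
        lat = se.generate_bond_lattice(60, 40, 0.55, seed=5)
        strip = mid_strip(lat, 10)
        assert ln.start_node(lat, strip) == ln.start_node(lat, strip)


class TestBiasedWalk:
    def test_unbiased_walk_no_drift(self):
        lat = full_lattice(200, 60)
        strip = mid_strip(lat, 20)
        drifts = [
            ln.biased_rw_lattice(
                lat, ln.LatticeRWParams(B=0.0, max_steps=4000), seed=s, strip=strip
            )[1]
            for s in range(5)
        ]
        assert abs(np.mean(drifts)) < 0.02

    def test_maximal_bias_is_deterministic_rightward(self):
        lat = full_lattice(50, 10)
        strip = mid_strip(lat, 4)
        rec, drift = ln.biased_rw_lattice(
            lat, ln.LatticeRWParams(B=0.75, max_steps=1000), seed=0, strip=strip
        )
        assert drift == 1.0 and rec["reached"]

    def test_walk_stays_on_open_edges(self):
        # a closed vertical wall cannot be crossed
        lat = full_lattice(30, 10)
        h = lat.horizontal_edges.copy()
        h[:, 14] = False
        walled = se.BondLattice(nx=30, ny=10, horizontal_edges=h,
                                vertical_edges=lat.vertical_edges, p=1.0)
        strip = mid_strip(walled, 4)
        rec, _ = ln.biased_rw_lattice(
            walled, ln.LatticeRWParams(B=0.5, max_steps=3000), seed=1, strip=strip
        )
        assert rec["end"][1] <= 14


class TestShortestPaths:
    def test_full_lattice_equals_span(self):
        lat = full_lattice()
        strip = mid_strip(lat)
        pair = ln.shortest_paths(lat, strip)
        assert pair.D == pair.D_tilde == lat.nx - 1

    def test_single_row_strip_on_full_lattice(self):
        lat = full_lattice()
        strip = ln.StripSpec(nx=lat.nx, ny=lat.ny, row_lo=12, row_hi=13)
        pair = ln.shortest_paths(lat, strip)
        assert pair.D_tilde == lat.nx - 1

    def test_constrained_never_shorter(self):
        for s in range(8):
            lat = se.generate_bond_lattice(120, 60, 0.55, seed=s)
            pair = ln.shortest_paths(lat, mid_strip(lat, 16))
            if pair.feasible:
                assert pair.D_tilde >= pair.D

    def test_matches_dijkstra_oracle(self):
        """BFS engine equals networkx shortest path on small instances."""
        import networkx as nx

        for s in range(3):
            lat = se.generate_bond_lattice(30, 30, 0.6, seed=s)
            strip = mid_strip(lat, 10)
            pair = ln.shortest_paths(lat, strip)
            g = nx.Graph()
            for r in range(30):
                for c in range(29):
                    if lat.horizontal_edges[r, c]:
                        g.add_edge((r, c), (r, c + 1))
            for r in range(29):
                for c in range(30):
                    if lat.vertical_edges[r, c]:
                        g.add_edge((r, c), (r + 1, c))
            best = math.inf
            for r0 in range(strip.row_lo, strip.row_hi):
                if (r0, 0) not in g:
                    continue
                lengths = nx.single_source_shortest_path_length(g, (r0, 0))
                for r1 in range(strip.row_lo, strip.row_hi):
                    best = min(best, lengths.get((r1, 29), math.inf))
            if math.isinf(best):
                assert not pair.feasible
            else:
                assert pair.D == best

    def test_infeasible_flagged(self):
        lat = se.generate_bond_lattice(20, 10, 0.0, seed=0)
        pair = ln.shortest_paths(lat, mid_strip(lat, 4))
        assert not pair.feasible


class TestVisionWalk:
    def test_full_lattice_walks_the_aerial_line(self):
        lat = full_lattice(100, 30)
        strip = mid_strip(lat, 10)
        length = ln.extended_vision_walk(lat, strip, ln.VisionParams(gamma=2))
        assert length == lat.nx - 1

    def test_detour_matches_shortest_path(self):
        # single blocked column segment inside the window
        lat = full_lattice(60, 30)
        h = lat.horizontal_edges.copy()
        h[10:20, 29] = False
        blocked = se.BondLattice(nx=60, ny=30, horizontal_edges=h,
                                 vertical_edges=lat.vertical_edges, p=1.0)
        strip = ln.StripSpec(nx=60, ny=30, row_lo=12, row_hi=18)
        pair = ln.shortest_paths(blocked, strip)
        length = ln.extended_vision_walk(blocked, strip, ln.VisionParams(gamma=6))
        assert length >= pair.D
        assert length <= pair.D + 8  # detour resolved within one window

    def test_length_never_below_free_path(self):
        for s in range(5):
            lat = se.generate_bond_lattice(200, 80, 0.6, seed=s)
            strip = mid_strip(lat, 20)
            pair = ln.shortest_paths(lat, strip)
            length = ln.extended_vision_walk(lat, strip, ln.VisionParams(gamma=3))
            assert length >= pair.D

    def test_wider_vision_never_hurts_on_average(self):
        lens = {g: [] for g in (2, 5)}
        for s in range(6):
            lat = se.generate_bond_lattice(150, 60, 0.6, seed=s)
            strip = mid_strip(lat, 16)
            for g in lens:
                lens[g].append(
                    ln.extended_vision_walk(lat, strip, ln.VisionParams(gamma=g))
                )
        assert np.mean(lens[5]) <= np.mean(lens[2])


class TestScaling:
    def test_scaled_shape_formula(self):
        nx, ny = ln.scaled_lattice_shape(2000)
        assert nx == 2000
        assert ny == round(120 * math.log2(2000))

    def test_strip_width_formula(self):
        lat = se.generate_bond_lattice(*ln.scaled_lattice_shape(1000), 0.55, seed=0)
        strip = ln.StripSpec.for_lattice(lat)
        assert strip.width == round(20 * math.log2(1000))

    def test_sensing_scale_ratio_prints_1_6(self):
        assert round(ln.sensing_scale_ratio(1000, 70), 1) == 1.6

    def test_path_pair_validation(self):
        with pytest.raises(ValueError):
            ln.PathPair(D=10.0, D_tilde=9.0)


class TestThresholdEstimate:
    def test_monotone_crossing_helper(self):
        p = np.array([0.4, 0.45, 0.5, 0.55, 0.6])
        frac = np.array([0.0, 0.2, 0.5, 0.9, 1.0])
        assert ln._crossing_increasing(p, frac) == pytest.approx(0.5, abs=0.02)

    def test_small_sweep_brackets_half(self):
        table, threshold = ln.bond_threshold_estimate(
            size=80, p_grid=[0.40, 0.45, 0.50, 0.55, 0.60], reps=10, seed=1
        )
        assert table["spanning_probability"].iloc[0] < 0.5
        assert table["spanning_probability"].iloc[-1] > 0.5
        assert 0.42 <= threshold <= 0.58
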