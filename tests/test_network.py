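"""Link graph and survey-consistency metric, checked against independent oracles."""

import math

import networkx as nx
import numpy as np
import pytest

import spiralsurvey as ss
from spiralsurvey.simulate import CameraPose


def make_pose(x, y, heading=0.0, altitude=2.0):
    return CameraPose(t=0.0, x=x, y=y, altitude=altitude, heading=heading)


def square_camera(side=1.0, altitude=1.0):
    """Camera whose footprint at the given altitude is a side x side square."""
    beta = 2.0 * math.atan(side / (2.0 * altitude))
    return ss.CameraModel(beta_across=beta, beta_along=beta, frame_period=0.5)


class TestFootprintPolygon:
    def test_reference_rectangle_dimensions_and_area(self, camera):
        poly = ss.footprint_polygon(make_pose(0.0, 0.0), camera)
        xs, ys = poly.exterior.xy
        assert max(xs) - min(xs) == pytest.approx(1.22, abs=0.01)  # along x (heading 0)
        assert max(ys) - min(ys) == pytest.approx(1.54, abs=0.01)  # across
        assert poly.area == pytest.approx(1.54 * 1.22, abs=0.03)
        assert poly.area < 2.0

    def test_area_equals_footprint_product_exactly(self, camera):
        poly = ss.footprint_polygon(make_pose(3.0, -2.0, heading=0.7), camera)
        expected = ss.footprint(2.0, camera.beta_across) * ss.footprint(
            2.0, camera.beta_along
        )
        assert poly.area == pytest.approx(expected, abs=1e-9)

    def test_heading_pi_rotation_leaves_rectangle_unchanged(self, camera):
        a = ss.footprint_polygon(make_pose(1.0, 2.0, heading=0.3), camera)
        b = ss.footprint_polygon(make_pose(1.0, 2.0, heading=0.3 + math.pi), camera)
        assert a.symmetric_difference(b).area == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_altitude_rejected(self, camera):
        with pytest.raises(ValueError):
            ss.footprint_polygon(
                CameraPose(t=0, x=0, y=0, altitude=-1.0, heading=0.0), camera
            )


class TestOverlapFraction:
    def test_identical_and_disjoint(self, camera):
        a = ss.footprint_polygon(make_pose(0, 0), camera)
        b = ss.footprint_polygon(make_pose(50, 0), camera)
        assert ss.overlap_fraction(a, a) == pytest.approx(1.0)
        assert ss.overlap_fraction(b, a) == 0.0

    def test_half_offset_unit_squares(self):
        cam = square_camera()
        a = ss.footprint_polygon(make_pose(0.0, 0.0, altitude=1.0), cam)
        b = ss.footprint_polygon(make_pose(0.5, 0.0, altitude=1.0), cam)
        assert ss.overlap_fraction(a, b) == pytest.approx(0.5, abs=1e-9)
        assert ss.overlap_fraction(b, a) == pytest.approx(0.5, abs=1e-9)

    def test_matches_monte_carlo_oracle_on_random_rectangle_pairs(self, camera):
        # Oracle: sample points uniformly in the smaller rectangle and count
        # the fraction that fall inside the other (done in the other
        # rectangle's own frame, independent of shapely)
        rng = np.random.default_rng(2024)
        n_samples = 100_000
        for _ in range(5):
            p1 = make_pose(*rng.uniform(-1, 1, 2), heading=rng.uniform(0, 2 * math.pi))
            p2 = make_pose(*rng.uniform(-1, 1, 2), heading=rng.uniform(0, 2 * math.pi))
            a = ss.footprint_polygon(p1, camera)
            b = ss.footprint_polygon(p2, camera)

            hal = ss.footprint(2.0, camera.beta_along) / 2.0
            hac = ss.footprint(2.0, camera.beta_across) / 2.0
            # uniform points in rectangle 1 (the smaller = either, equal areas)
            u = rng.uniform(-hal, hal, n_samples)
            v = rng.uniform(-hac, hac, n_samples)
            c1, s1 = math.cos(p1.heading), math.sin(p1.heading)
            px = p1.x + u * c1 - v * s1
            py = p1.y + u * s1 + v * c1
            # into rectangle 2's frame
            c2, s2 = math.cos(p2.heading), math.sin(p2.heading)
            qx = (px - p2.x) * c2 + (py - p2.y) * s2
            qy = -(px - p2.x) * s2 + (py - p2.y) * c2
            oracle = float(np.mean((np.abs(qx) <= hal) & (np.abs(qy) <= hac)))
            assert ss.overlap_fraction(a, b) == pytest.approx(oracle, abs=0.01)

    def test_degenerate_polygon_rejected(self):
        from shapely.geometry import Polygon

        line = Polygon([(0, 0), (1, 0), (1, 0)])
        square = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        with pytest.raises(ValueError):
            ss.overlap_fraction(line, square)


class TestBuildLinkGraph:
    def test_distant_poses_are_unlinked(self, camera):
        traj = ss.spoke_passes((0.0, 0.0), 1, 6.0, camera, speed=8.0, altitude=2.0)
        graph = ss.build_link_graph(traj, camera)
        assert graph.number_of_edges() == 0

    def test_consecutive_spiral_poses_always_linked(self, camera, drum, fixture_set):
        traj = fixture_set["spiral_ideal"]
        graph = ss.build_link_graph(traj, camera)
        for i in range(len(traj) - 1):
            assert graph.has_edge(i, i + 1)
        # spacing 0.15 m against a 1.22 m along-track footprint: ~0.88 overlap
        # away from the pole (near the pole the frame-to-frame rotation is
        # large, reducing the intersection somewhat)
        assert graph.edges[1000, 1001]["overlap"] > 0.85
        assert graph.edges[0, 1]["overlap"] >= 0.15

    def test_pruning_does_not_change_the_graph(self, camera, drum):
        small = ss.DrumLine(0.08, 1.2)
        traj = ss.spiral_trajectory(small, camera, speed=0.3, altitude=2.0)
        assert len(traj) <= 200
        pruned = ss.build_link_graph(traj, camera)
        # brute-force oracle: all pairs, no k-d tree
        brute = nx.Graph()
        polys = [ss.footprint_polygon(traj[i], camera) for i in range(len(traj))]
        for i in range(len(traj)):
            brute.add_node(i)
        for i in range(len(traj)):
            for j in range(i + 1, len(traj)):
                if ss.overlap_fraction(polys[i], polys[j]) >= 0.15:
                    brute.add_edge(i, j)
        assert set(pruned.edges) == set(brute.edges)

    def test_threshold_validation_and_empty_input(self, camera, drum):
        traj = ss.spiral_trajectory(drum, camera, speed=0.3, altitude=2.0)
        with pytest.raises(ValueError):
            ss.build_link_graph(traj, camera, link_threshold=0.0)
        with pytest.raises(ValueError):
            ss.build_link_graph(traj, camera, include_flags={"nonexistent"})


def metric_oracle(graph):
    """Exhaustive reference metric: sorted-median + networkx BFS, all pairs."""
    lengths = sorted(d["length"] for _, _, d in graph.edges(data=True))
    m = len(lengths)
    median = (
        lengths[m // 2] if m % 2 == 1 else 0.5 * (lengths[m // 2 - 1] + lengths[m // 2])
    )
    radius = 2.0 * median
    nodes = list(graph.nodes)
    counts, unreachable = {}, 0
    for i in nodes:
        hops = nx.single_source_shortest_path_length(graph, i)
        xi, yi = graph.nodes[i]["pos"]
        for j in nodes:
            if i == j:
                continue
            xj, yj = graph.nodes[j]["pos"]
            if math.hypot(xi - xj, yi - yj) <= radius:
                if j in hops:
                    counts[hops[j]] = counts.get(hops[j], 0) + 1
                else:
                    unreachable += 1
    total = sum(counts.values())
    hist = {k: v / total for k, v in counts.items()}
    return median, counts, hist, unreachable


class TestCoverageMetric:
    def test_two_linked_cameras(self):
        g = nx.Graph()
        g.add_node(0, pos=(0.0, 0.0))
        g.add_node(1, pos=(0.5, 0.0))
        g.add_edge(0, 1, length=0.5, overlap=0.9)
        rep = ss.coverage_metric(g)
        assert rep.median_link_length == 0.5
        assert rep.neighborhood_radius == 1.0
        assert rep.normalized_histogram == {1: 1.0}
        assert rep.unreachable_pairs == 0

    def test_five_node_path_graph_by_hand(self):
        # nodes at unit spacing linked consecutively; median link 1 ->
        # radius 2 covers 1- and 2-hop neighbors:
        # 4 ordered pairs at distance 1 per inner adjacency (8 total) and
        # 6 ordered pairs at hop 2
        g = nx.Graph()
        for i in range(5):
            g.add_node(i, pos=(float(i), 0.0))
        for i in range(4):
            g.add_edge(i, i + 1, length=1.0, overlap=0.5)
        rep = ss.coverage_metric(g)
        assert rep.path_length_counts == {1: 8, 2: 6}
        assert rep.normalized_histogram[1] == pytest.approx(8 / 14)
        assert rep.mass([1, 2]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_bfs_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        pos = rng.uniform(0, 5, size=(n, 2))
        g = nx.Graph()
        for i in range(n):
            g.add_node(i, pos=tuple(pos[i]))
        for i in range(n):
            for j in range(i + 1, n):
                d = float(np.hypot(*(pos[i] - pos[j])))
                if d < 0.9 and rng.random() < 0.7:
                    g.add_edge(i, j, length=d, overlap=0.5)
        if g.number_of_edges() == 0:
            pytest.skip("degenerate draw")
        rep = ss.coverage_metric(g)
        median, counts, hist, unreachable = metric_oracle(g)
        assert rep.median_link_length == pytest.approx(median)
        assert rep.path_length_counts == counts
        assert rep.unreachable_pairs == unreachable
        for k, v in hist.items():
            assert rep.normalized_histogram[k] == pytest.approx(v)

    def test_edgeless_graph_rejected(self):
        g = nx.Graph()
        g.add_node(0, pos=(0.0, 0.0))
        g.add_node(1, pos=(10.0, 0.0))
        with pytest.raises(ValueError):
            ss.coverage_metric(g)

    def test_histogram_invariant_under_uniform_scaling(self, camera):
        # scaling planar geometry and altitude (hence footprints) by a
        # common factor must leave the normalized histogram unchanged
        small = ss.DrumLine(0.08, 2.0)
        traj = ss.spiral_trajectory(small, camera, speed=0.3, altitude=2.0)
        rep1 = ss.coverage_metric(ss.build_link_graph(traj, camera))
        factor = 2.0
        scaled = ss.Trajectory(
            t=traj.t.copy(),
            x=traj.x * factor,
            y=traj.y * factor,
            altitude=traj.altitude * factor,
            heading=traj.heading.copy(),
            flags=traj.flags.copy(),
            metadata=dict(traj.metadata),
        )
        rep2 = ss.coverage_metric(ss.build_link_graph(scaled, camera))
        assert rep2.neighborhood_radius == pytest.approx(
            factor * rep1.neighborhood_radius, rel=1e-12
        )
        assert set(rep1.normalized_histogram) == set(rep2.normalized_histogram)
        for k, v in rep1.normalized_histogram.items():
            assert rep2.normalized_histogram[k] == pytest.approx(v, abs=1e-9)

    def test_region_hole_strictly_increases_tail_mass(self, camera):
        # a frame-drop coverage hole wider than the along-track footprint in
        # both directions forces detours of three or more links
        base = ss.LawnSpec(leg_length=8.0, spacing=0.51, n_legs=10)
        holed = ss.LawnSpec(
            leg_length=8.0,
            spacing=0.51,
            n_legs=10,
            holes=(
                ss.LawnHole(leg_index=4, start=8.0 - 5.5, end=8.0 - 3.0),  # downward leg
                ss.LawnHole(leg_index=5, start=3.0, end=5.5),
            ),
        )
        tails = []
        for spec in (base, holed):
            traj = ss.lawn_trajectory(spec, camera, speed=0.3, altitude=2.0)
            rep = ss.coverage_metric(ss.build_link_graph(traj, camera))
            tails.append(1.0 - rep.mass([1, 2]))
        assert tails[0] == pytest.approx(0.0, abs=1e-12)
        assert tails[1] > tails[0]


class TestCompareSurveys:
    def test_identical_reports_have_zero_difference(self, spiral_report):
        out = ss.compare_surveys(spiral_report, spiral_report)
        assert out["difference"]["mass_1_2"] == 0.0
        assert out["difference"]["tail_mass"] == 0.0

    def test_mass_split_normalization(self, spiral_report, lawn_holes_report):
        out = ss.compare_surveys(spiral_report, lawn_holes_report)
        for key in ("a", "b"):
            assert out[key]["mass_1_2"] + out[key]["tail_mass"] == pytest.approx(1.0)

    def test_spiral_beats_holed_lawn(self, spiral_report, lawn_holes_report):
        out = ss.compare_surveys(spiral_report, lawn_holes_report)
        assert out["difference"]["mass_1_2"] > 0.0
        assert out["b"]["max_path_length"] >= 3
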