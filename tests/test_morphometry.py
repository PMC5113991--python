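"""Zigzag-index computation, window sampling, and label-mask boundary tracing."""

import math

import numpy as np
import pytest

from paracell import (
    ContactEdge,
    ContactGraph,
    sample_windows,
    trace_boundaries,
    zigzag_index,
    zigzag_per_sample,
)
from paracell.simulate import MeshSpec, generate_mesh


def straight_edge(v1, v2, p0, p1):
    return ContactEdge(v1, v2, np.array([p0, p1], float))


def sawtooth_edge(v1, v2, x0, length, amplitude, period):
    """Horizontal sawtooth between (x0, 0) and (x0+length, 0)."""
    n = max(2, 2 * round(length / period))
    xs = np.linspace(x0, x0 + length, n + 1)
    ys = np.where(np.arange(n + 1) % 2 == 1, amplitude, 0.0)
    return ContactEdge(v1, v2, np.column_stack([xs, ys]))


class TestZigzagIndex:
    def test_straight_edges_score_one(self):
        edges = [straight_edge(0, 1, (0, 0), (10, 0)),
                 straight_edge(1, 2, (10, 0), (10, 7))]
        res = zigzag_index(edges)
        assert res.index == 1.0
        assert res.n_sides == 2

    def test_single_sawtooth_analytic(self):
        # amplitude = half-period: arc/chord = sqrt(1 + (2a/p)^2) = sqrt(2)
        e = sawtooth_edge(0, 1, 0.0, 16.0, amplitude=1.0, period=2.0)
        assert zigzag_index([e]).index == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        """Unequal chords discriminate the pooled definition: a straight side of
        chord 10 pooled with a sqrt(2)-tortuous side of chord 20 gives
        (10 + 20*sqrt(2)) / 30, not the per-edge mean."""
        edges = [straight_edge(0, 1, (0, 0), (10, 0)),
                 sawtooth_edge(2, 3, 0.0, 20.0, amplitude=1.0, period=2.0)]
        res = zigzag_index(edges)
        ratio_of_sums = (10 + 20 * math.sqrt(2)) / 30
        mean_of_ratios = (1 + math.sqrt(2)) / 2
        assert res.index == pytest.approx(ratio_of_sums, rel=1e-12)
        assert abs(res.index - mean_of_ratios) > 1e-3

    def test_pooled_index_between_edge_extremes(self, rng):
        edges = []
        for i in range(20):
            length = rng.uniform(5, 30)
            amp = rng.uniform(0, 2)
            edges.append(sawtooth_edge(2 * i, 2 * i + 1, 0.0, length, amp, 3.0))
        res = zigzag_index(edges)
        ratios = [e.arc_length / e.chord_length for e in edges]
        assert min(ratios) <= res.index <= max(ratios)
        assert res.index >= 1.0

    def test_zero_chord_excluded_with_warning(self):
        loop = ContactEdge(0, 0, np.array([[0, 0], [1, 1], [0, 0]], float))
        good = straight_edge(1, 2, (0, 0), (5, 0))
        with pytest.warns(UserWarning, match="coincident"):
            res = zigzag_index([loop, good])
        assert res.n_sides == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            zigzag_index([])

    def test_invariant_under_rigid_motion_and_scaling(self, rng):
        edges = [sawtooth_edge(2 * i, 2 * i + 1, 0.0, 12.0, 0.8, 3.0) for i in range(5)]
        base = zigzag_index(edges).index
        theta, scale, shift = 0.7, 3.5, np.array([12.0, -4.0])
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        moved = [ContactEdge(e.v1, e.v2, scale * e.polyline @ rot.T + shift)
                 for e in edges]
        assert zigzag_index(moved).index == pytest.approx(base, rel=1e-12)


class TestWindowSampling:
    @pytest.fixture()
    def mesh(self):
        return generate_mesh(MeshSpec(n_cells=400, field=(150.0, 150.0),
                                      jag_amplitude=0.5, jag_period=2.5, seed=3))

    def test_whole_field_window_returns_everything(self, mesh):
        (edges,) = sample_windows(mesh, n_windows=1,
                                  window_area=150.0 * 150.0, seed=0)
        assert len(edges) == len(mesh.edges)

    def test_seeded_determinism(self, mesh):
        a = sample_windows(mesh, seed=11)
        b = sample_windows(mesh, seed=11)
        assert [[id(e) for e in w] for w in a] == [[id(e) for e in w] for w in b]

    def test_oversized_window_rejected(self, mesh):
        with pytest.raises(ValueError, match="window side"):
            sample_windows(mesh, window_area=200.0 * 200.0, seed=0)

    def test_capture_rate_matches_exact_probability(self, mesh):
        """Monte-Carlo oracle: over many seeded windows the mean number of
        captured edges matches the exactly integrated capture probability
        (product of 1-D overlap fractions of each edge's endpoint bounding box)."""
        side = math.sqrt(815.0)
        xmin, ymin, xmax, ymax = mesh.field_extent
        span_x, span_y = xmax - xmin - side, ymax - ymin - side

        def capture_probability(e):
            (ax, ay), (bx, by) = mesh.vertices[e.v1], mesh.vertices[e.v2]
            # admissible window-origin interval per axis:
            lo_x, hi_x = max(ax, bx) - side, min(ax, bx)
            lo_y, hi_y = max(ay, by) - side, min(ay, by)
            wx = max(0.0, min(hi_x, xmin + span_x) - max(lo_x, xmin))
            wy = max(0.0, min(hi_y, ymin + span_y) - max(lo_y, ymin))
            return (wx / span_x) * (wy / span_y)

        expected = sum(capture_probability(e) for e in mesh.edges)
        counts = [len(w) for s in range(100)
                  for w in sample_windows(mesh, n_windows=1, window_area=815.0, seed=s)]
        mean = np.mean(counts)
        sem = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(mean - expected) < 4 * sem


class TestZigzagPerSample:
    def test_straight_mesh_scores_one_any_seed(self):
        mesh = generate_mesh(MeshSpec(n_cells=400, field=(150, 150),
                                      jag_amplitude=0.0, seed=5))
        for seed in (0, 1, 2):
            assert zigzag_per_sample(mesh, seed=seed).index == pytest.approx(1.0)

    def test_recovers_generator_jaggedness(self):
        spec = MeshSpec(n_cells=600, field=(200, 200),
                        jag_amplitude=1.25, jag_period=5.0, seed=9)
        mesh = generate_mesh(spec)
        res = zigzag_per_sample(mesh, seed=1)
        assert res.n_sides >= 80
        assert res.index == pytest.approx(spec.expected_index, rel=0.02)

    def test_jagged_vs_linear_ordering(self):
        """A jagged (wild-type-like) mesh scores above a linearized
        (stimulus-relaxed) mesh, which scores above a straight mesh."""
        jagged = generate_mesh(MeshSpec(n_cells=500, field=(180, 180),
                                        jag_amplitude=1.0, jag_period=3.0, seed=2))
        relaxed = generate_mesh(MeshSpec(n_cells=500, field=(180, 180),
                                         jag_amplitude=0.3, jag_period=3.0, seed=2))
        straight = generate_mesh(MeshSpec(n_cells=500, field=(180, 180),
                                          jag_amplitude=0.0, seed=2))
        zi = [zigzag_per_sample(m, seed=4).index for m in (jagged, relaxed, straight)]
        assert zi[0] > zi[1] > zi[2] == pytest.approx(1.0)

    def test_protocol_warning_below_80_sides(self):
        mesh = generate_mesh(MeshSpec(n_cells=80, field=(120, 120),
                                      jag_amplitude=0.5, jag_period=2.0, seed=7))
        with pytest.warns(UserWarning, match="80"):
            zigzag_per_sample(mesh, n_windows=1, window_area=100.0, seed=3)


class TestTraceBoundaries:
    def test_two_half_planes_one_straight_edge(self):
        mask = np.ones((12, 12), int)
        mask[:, 6:] = 2
        graph = trace_boundaries(mask)
        assert len(graph.edges) == 1
        assert zigzag_index(graph.edges).index == pytest.approx(1.0)

    def test_checkerboard_junction_vertex(self):
        mask = np.zeros((10, 10), int)
        mask[:5, :5], mask[:5, 5:], mask[5:, :5], mask[5:, 5:] = 1, 2, 3, 4
        graph = trace_boundaries(mask)
        assert len(graph.edges) == 4
        # the four edges share one central junction vertex at (5, 5)
        counts = {}
        for e in graph.edges:
            for v in (e.v1, e.v2):
                counts[v] = counts.get(v, 0) + 1
        (center,) = [v for v, c in counts.items() if c == 4]
        assert graph.vertices[center] == (5.0, 5.0)

    def test_rasterized_sawtooth_close_to_analytic(self):
        a, p, px = 4.0, 16.0, 0.2
        nx, ny = int(64 / px), int(24 / px)
        xs = (np.arange(nx) + 0.5) * px
        ys = (np.arange(ny) + 0.5) * px
        frac = (xs % p) / p
        boundary = 10.0 + np.where(frac < 0.5, 2 * a * frac, 2 * a * (1 - frac))
        mask = np.where(ys[:, None] < boundary[None, :], 1, 2).astype(int)
        graph = trace_boundaries(mask, pixel_size=px)
        analytic = math.sqrt(1 + (2 * a / p) ** 2)
        assert zigzag_index(graph.edges).index == pytest.approx(analytic, rel=0.05)

    def test_pixel_size_scales_coordinates_not_index(self):
        mask = np.ones((12, 12), int)
        mask[:, 6:] = 2
        g1 = trace_boundaries(mask, pixel_size=1.0)
        g2 = trace_boundaries(mask, pixel_size=0.3)
        assert g2.field_extent[2] == pytest.approx(0.3 * g1.field_extent[2])
        assert zigzag_index(g2.edges).index == pytest.approx(1.0)

    def test_single_label_mask_empty_graph(self):
        graph = trace_boundaries(np.ones((8, 8), int))
        assert graph.edges == []

    def test_background_boundaries_excluded(self):
        mask = np.zeros((10, 10), int)
        mask[2:8, 2:5] = 1
        mask[2:8, 5:8] = 2
        graph = trace_boundaries(mask)
        # only the 1|2 contact remains, not the outlines against background
        assert len(graph.edges) == 1
        assert graph.edges[0].chord_length == pytest.approx(6.0)

    def test_non_integer_mask_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            trace_boundaries(np.ones((4, 4), float))


class TestContactGraphValidation:
    def test_endpoint_vertex_mismatch_rejected(self):
        edge = straight_edge(0, 1, (0, 0), (5, 0))
        with pytest.raises(ValueError, match="does not"):
            ContactGraph(vertices={0: (0.0, 0.0), 1: (9.0, 9.0)},
                         edges=[edge], field_extent=(0, 0, 10, 10))

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            ContactGraph(vertices={}, edges=[], field_extent=(0, 0, 0, 10))
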