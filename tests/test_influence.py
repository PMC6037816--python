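"""Cumulative influence traces, switch detection, ordering and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from switchlead import (
    TimeSeriesSet,
    WeightedAdjacency,
    WindowedInfluence,
    clustering_coefficient,
    cumulative_trace,
    detect_clusters,
    detect_switches,
    net_adjacency,
    order_leadership,
    shortlist_leaders,
    window_divergence,
)


def influence_from_divergence(div, win=1000):
    """Assemble a WindowedInfluence directly from per-window divergences."""
    div = np.asarray(div, dtype=float)
    return WindowedInfluence(window_length=win, adjacency_per_window=[], divergence=div)


def tent_trace(up, down, scale=1.0, win=1000, noise=0.0, seed=0):
    r = np.random.default_rng(seed)
    div = np.concatenate([np.full(up, scale), np.full(down, -scale)])
    div = div + noise * r.normal(size=div.size)
    return cumulative_trace(influence_from_divergence(np.stack([div, -div]), win))


class TestWindowDivergence:
    def test_triplet_case_study_arithmetic(self):
        """A -> B -> C with weights 0.5 / 0.2: divergences are +0.5, -0.3, -0.2."""
        raw = np.zeros((3, 3))
        raw[0, 1], raw[1, 2] = 0.5, 0.2
        adj = net_adjacency(raw, 0.0)
        np.testing.assert_allclose(adj.divergence(), [0.5, -0.3, -0.2])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_divergence_conserved(self, seed):
        """Every edge appears once positive and once negative: divergences sum to 0."""
        r = np.random.default_rng(seed)
        adj = net_adjacency(r.uniform(size=(6, 6)), 0.05)
        assert adj.divergence().sum() == pytest.approx(0.0, abs=1e-12)

    def test_windows_conserve_and_drop_partial(self, rng):
        ts = TimeSeriesSet(rng.normal(size=(3, 2_550)))
        wi = window_divergence(ts, 500, "te", 0.0, n_bins=4)
        assert wi.n_windows == 5  # trailing 50 samples dropped
        np.testing.assert_allclose(wi.divergence.sum(axis=0), 0.0, atol=1e-12)

    def test_window_longer_than_series_rejected(self, rng):
        ts = TimeSeriesSet(rng.normal(size=(2, 100)))
        with pytest.raises(ValueError):
            window_divergence(ts, 200, "te")


class TestCumulativeTrace:
    def test_sustained_triplet_monotonicity(self):
        """Sustained A->B->C influence: S_A rises, S_B and S_C fall."""
        div = np.tile(np.array([[0.5], [-0.3], [-0.2]]), (1, 6))
        trace = cumulative_trace(influence_from_divergence(div))
        assert np.all(np.diff(trace.cumulative[0]) > 0)
        assert np.all(np.diff(trace.cumulative[1]) < 0)
        assert np.all(np.diff(trace.cumulative[2]) < 0)
        assert np.allclose(trace.cumulative.sum(axis=0), 0.0)

    def test_zero_divergence_flat_no_switches(self):
        trace = cumulative_trace(influence_from_divergence(np.zeros((2, 8))))
        assert np.all(trace.cumulative == 0)
        assert detect_switches(trace) == []

    def test_tent_has_single_interior_maximum(self):
        """+1 for 5 windows then -1 for 5: the piecewise-linear apex is at
        window 5, and the smooth interpolant peaks within a window of it."""
        trace = tent_trace(5, 5)
        grid = np.linspace(0, 10_000, 2001)
        smooth = trace.smooth(0, grid)
        apex = grid[np.argmax(smooth)]
        assert abs(apex - 5_000) < 1_000

    def test_normalized_in_unit_interval(self):
        trace = tent_trace(5, 5, scale=3.7)
        norm = trace.normalized(trace.times)
        assert np.abs(norm).max() <= 1.0 + 1e-9

    def test_interpolant_tracks_filtered_steps(self, rng):
        div = rng.normal(size=(2, 20))
        div[1] = -div[0]
        trace = cumulative_trace(influence_from_divergence(div))
        at_knots = np.array([trace.smooth(i, trace.times) for i in range(2)])
        scale = np.abs(np.diff(trace.filtered, axis=1)).max()
        assert np.abs(at_knots - trace.filtered).max() < 2 * scale

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            cumulative_trace(influence_from_divergence(np.ones((2, 2))))


class TestDetectSwitches:
    def test_monotonic_trace_reports_constant_leadership(self):
        div = np.stack([np.full(10, 0.4), np.full(10, -0.4)])
        trace = cumulative_trace(influence_from_divergence(div))
        assert detect_switches(trace) == []

    def test_tent_yields_leader_to_follower_at_peak(self):
        trace = tent_trace(10, 10, noise=0.05, seed=3)
        events = detect_switches(trace)
        by_ind = {e.individual: e for e in events}
        assert by_ind[0].direction == "leader_to_follower"
        assert by_ind[1].direction == "follower_to_leader"
        assert abs(by_ind[0].corrected_time - 10_000) <= 1_000

    def test_single_sign_change_gives_single_event_per_individual(self):
        trace = tent_trace(8, 12, noise=0.1, seed=11)
        events = detect_switches(trace)
        assert sum(e.individual == 0 for e in events) == 1
        assert sum(e.individual == 1 for e in events) == 1

    def test_edge_guard_suppresses_boundary_extrema(self):
        # apex in the very first interior window: guarded away
        trace = tent_trace(1, 11)
        assert detect_switches(trace, edge_guard=1) == []

    def test_slope_mode_flags_slope_break(self):
        div = np.concatenate([np.full(8, 1.0), np.full(8, 0.2)])
        trace = cumulative_trace(influence_from_divergence(np.stack([div, -div])))
        events = detect_switches(trace, slope_mode=True)
        assert any(
            e.individual == 0 and e.direction == "leader_to_follower" for e in events
        )


class TestShortlist:
    def test_dominant_individual_shortlisted(self, rng):
        div = -0.1 + 0.01 * rng.normal(size=(10, 8))
        div[3] = 0.9
        trace = cumulative_trace(influence_from_divergence(div))
        short = shortlist_leaders(trace)
        assert 3 in short and len(short) <= 3

    def test_all_equal_all_returned(self):
        trace = cumulative_trace(influence_from_divergence(np.zeros((5, 6))))
        assert shortlist_leaders(trace) == {0, 1, 2, 3, 4}

    def test_pair_returns_both(self):
        trace = tent_trace(4, 4)
        assert shortlist_leaders(trace) == {0, 1}


class TestOrderLeadership:
    @staticmethod
    def chain_series(rng, n=3, T=6_000, fidelity=0.95):
        """A drives B drives C: each series copies its parent one step back
        with high probability, else fresh noise (strong lag-1 TE chain)."""
        x = np.empty((n, T))
        x[0] = rng.integers(0, 4, size=T)
        for i in range(1, n):
            fresh = rng.integers(0, 4, size=T)
            keep = rng.uniform(size=T) < fidelity
            x[i] = np.where(keep, np.roll(x[i - 1], 1), fresh)
        return TimeSeriesSet(x.astype(float))

    def test_chain_recovered(self, rng):
        ts = self.chain_series(rng)
        result = order_leadership(ts, {0, 1, 2}, measure="te", threshold=0.01, n_bins=4)
        assert result.ordered
        assert result.order == [0, 1, 2]

    def test_pair_reduces_to_net_sign(self, rng):
        ts = self.chain_series(rng, n=2)
        result = order_leadership(ts, {0, 1}, measure="te", threshold=0.01, n_bins=4)
        assert result.ordered and result.order == [0, 1]

    def test_independent_series_unordered(self, rng):
        ts = TimeSeriesSet(rng.integers(0, 4, size=(3, 4_000)).astype(float))
        result = order_leadership(ts, {0, 1, 2}, measure="te", threshold=0.05, n_bins=4)
        assert not result.ordered


class TestClustering:
    @staticmethod
    def adjacency(matrix):
        return WeightedAdjacency(np.asarray(matrix, dtype=float), "te", 0.0)

    def test_complete_graph_all_one(self):
        m = np.ones((4, 4)) - np.eye(4)
        np.testing.assert_allclose(clustering_coefficient(self.adjacency(m)), 1.0)

    def test_star_graph_zero(self):
        m = np.zeros((5, 5))
        m[0, 1:] = 1  # directed hub
        np.testing.assert_allclose(clustering_coefficient(self.adjacency(m)), 0.0)

    def test_triangle_with_pendant_hand_count(self):
        # nodes 0-1-2 form a triangle, node 3 hangs off node 0:
        # C0 = 2*1/(3*2) = 1/3, C1 = C2 = 1, C3 = 0
        m = np.zeros((4, 4))
        for a, b in [(0, 1), (1, 2), (2, 0), (0, 3)]:
            m[a, b] = 1
        np.testing.assert_allclose(
            clustering_coefficient(self.adjacency(m)), [1 / 3, 1, 1, 0]
        )

    def test_empty_graph_zero(self):
        np.testing.assert_allclose(
            clustering_coefficient(self.adjacency(np.zeros((3, 3)))), 0.0
        )

    def test_kmeans_separated_groups(self, rng):
        states = np.concatenate([rng.normal(0, 0.1, (5, 2)), rng.normal(5, 0.1, (5, 2))])
        labels = detect_clusters(states, k=2, seed=1)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_kmeans_degenerate_k(self, rng):
        states = rng.normal(size=(6, 2))
        assert len(set(detect_clusters(states, k=1))) == 1
        assert len(set(detect_clusters(states, k=6))) == 6
        with pytest.raises(ValueError):
            detect_clusters(states, k=7)
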