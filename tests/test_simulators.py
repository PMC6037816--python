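"""Particle and fish-shoal generators: physics, invariants, determinism."""

import numpy as np
import pytest

from switchlead import (
    FishParams,
    SwitchSchedule,
    VicsekParams,
    polarization,
    radius_for_neighbors,
    simulate_fish,
    simulate_independent_pairs,
    simulate_vicsek,
    transfer_entropy,
    wrap_angle,
)

CONST = SwitchSchedule([(0, [0])])


def lagged_corr(x, y, lag):
    """Correlation of x(t) with y(t + lag); independent brute-force oracle."""
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    if lag >= 0:
        return float(np.mean(x[: x.size - lag] * y[lag:]))
    return float(np.mean(y[: y.size + lag] * x[-lag:]))


class TestWrapAngle:
    def test_interval(self):
        x = np.linspace(-10, 10, 1001)
        w = wrap_angle(x)
        assert np.all(w > -np.pi) and np.all(w <= np.pi)
        np.testing.assert_allclose(np.cos(w), np.cos(x), atol=1e-12)
        np.testing.assert_allclose(np.sin(w), np.sin(x), atol=1e-12)


class TestVicsek:
    def test_noiseless_pair_reaches_consensus(self):
        """With zero noise the follower locks onto the leader's heading and
        both turn-rate series vanish."""
        p = VicsekParams(noise=0.0, n_steps=2_000, transient=1_000, seed=3)
        ts = simulate_vicsek(p, CONST)
        assert np.abs(ts.values).max() < 1e-12

    def test_positions_in_box_and_turns_wrapped(self, vicsek_pair_constant):
        ts = vicsek_pair_constant
        assert np.all(ts.positions >= 0) and np.all(ts.positions < 1.0)
        assert np.abs(ts.values).max() <= np.pi

    def test_single_particle_turns_are_noise_only(self):
        """A lone follower has no neighbours: its turn rate is pure angular noise."""
        p = VicsekParams(n_particles=1, noise=0.3, n_steps=3_000, transient=500, seed=9)
        ts = simulate_vicsek(p, SwitchSchedule([(0, [])]))
        # eta * (zeta_{t+1} - zeta_t): zero-mean, bounded by 2*pi*eta
        assert abs(ts.values.mean()) < 0.05
        assert np.abs(ts.values).max() <= 2 * np.pi * 0.3 + 1e-12

    def test_same_seed_bit_identical(self):
        p = VicsekParams(n_steps=2_000, transient=100, seed=77)
        a = simulate_vicsek(p, CONST)
        b = simulate_vicsek(p, CONST)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_schedule_id_out_of_range(self):
        with pytest.raises(ValueError):
            simulate_vicsek(VicsekParams(), SwitchSchedule([(0, [5])]))

    def test_follower_turns_lag_leaders(self, vicsek_pair_constant):
        """Brute-force lagged cross-correlation: the follower's turn rate
        correlates with the leader's at a positive lag, stronger than at the
        mirrored negative lag."""
        leader, follower = vicsek_pair_constant.values
        pos = max(lagged_corr(leader, follower, lag) for lag in (1, 2, 3))
        neg = max(lagged_corr(leader, follower, -lag) for lag in (1, 2, 3))
        assert pos > 0.05
        assert pos > neg + 0.02

    def test_radius_helper(self):
        r = radius_for_neighbors(1, 2, 1.0)
        assert np.pi * r**2 * 1 == pytest.approx(1.0)


class TestIndependentPairs:
    def test_distinct_seeds_and_no_coupling(self):
        pairs = simulate_independent_pairs(
            "vicsek", 2, VicsekParams(n_steps=12_000, transient=2_000), seed=5
        )
        assert not np.array_equal(pairs[0].values, pairs[1].values)
        for ts in pairs:
            a, b = ts.values
            net = transfer_entropy(a, b, n_bins=18) - transfer_entropy(b, a, n_bins=18)
            assert abs(net) < 0.05  # estimator noise only

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError):
            simulate_independent_pairs("vicsek", 1, VicsekParams(), seed=0)


class TestPolarization:
    def test_aligned_and_opposed(self):
        from switchlead import TimeSeriesSet

        aligned = TimeSeriesSet(np.zeros((3, 4)), headings=np.full((3, 4), 0.7))
        np.testing.assert_allclose(polarization(aligned), 1.0)
        opposed = TimeSeriesSet(
            np.zeros((2, 4)), headings=np.stack([np.zeros(4), np.full(4, np.pi)])
        )
        np.testing.assert_allclose(polarization(opposed), 0.0, atol=1e-12)

    def test_order_disorder_trend(self):
        """Mean polarization drops from near-order at low noise toward
        disorder at full noise."""
        low = simulate_vicsek(
            VicsekParams(noise=0.2, n_steps=6_000, transient=2_000, seed=8), CONST
        )
        high = simulate_vicsek(
            VicsekParams(noise=1.0, n_steps=6_000, transient=2_000, seed=8), CONST
        )
        assert polarization(low).mean() > polarization(high).mean() + 0.2


class TestFish:
    def test_ou_stationary_variance(self):
        """With all gains zero the turn rate is an Ornstein-Uhlenbeck process
        with stationary variance v * sigma^2 / (2 * alpha) (closed form)."""
        p = FishParams(
            n_fish=1, speed=1.0, relax_rate=2.0, noise_scale=1.0, wall_gain=0.0,
            align_gain=0.0, attract_gain=0.0, arena_diameter=1e6, dt=0.005,
            duration=400.0, seed=7,
        )
        ts = simulate_fish(p, CONST)
        expected = p.speed * p.noise_scale**2 / (2 * p.relax_rate)
        assert ts.values[0, 2000:].var() == pytest.approx(expected, rel=0.15)

    def test_deterministic_decay_matches_ode(self):
        """sigma = 0, no couplings: omega decays exponentially at rate v*alpha."""
        p = FishParams(
            n_fish=1, speed=0.1, relax_rate=20.0, noise_scale=0.0, wall_gain=0.0,
            align_gain=0.0, attract_gain=0.0, arena_diameter=1e6, dt=0.01,
            duration=3.0, seed=1,
        )
        ts = simulate_fish(p, CONST, initial_turn_rates=[1.0])
        t = np.arange(1, ts.n_samples + 1) * p.dt
        np.testing.assert_allclose(ts.values[0], np.exp(-p.speed * p.relax_rate * t), atol=0.01)

    def test_outside_arena_rejected(self):
        with pytest.raises(ValueError):
            simulate_fish(
                FishParams(duration=1.0), CONST, initial_positions=[[5.0, 0.0], [0.0, 0.0]]
            )

    def test_stays_in_arena_and_deterministic(self):
        p = FishParams(duration=30.0, seed=21)
        a = simulate_fish(p, CONST)
        b = simulate_fish(p, CONST)
        np.testing.assert_array_equal(a.values, b.values)
        radii = np.hypot(a.positions[..., 0], a.positions[..., 1])
        assert radii.max() < 1.2 * p.arena_diameter / 2  # wall term keeps fish in

    def test_follower_lags_leader_and_direction_reverses_at_switch(self):
        """Signed turn-rate cross-correlation is maximal at a positive lag
        before the switch and at a negative lag after, i.e. the follower's
        turns echo the leader's and the echo direction flips."""
        sched = SwitchSchedule([(0, [0]), (6_000, [1])])
        p = FishParams(seed=203, duration=130.0, discard=10.0)
        ts = simulate_fish(p, sched)
        pre = ts.values[:, :5_000]
        post = ts.values[:, 6_000:]
        lags = range(1, 40)

        def asym(block):
            fwd = max(lagged_corr(block[0], block[1], l) for l in lags)
            rev = max(lagged_corr(block[1], block[0], l) for l in lags)
            return fwd - rev

        assert asym(pre) > 0.05
        assert asym(post) < -0.05
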