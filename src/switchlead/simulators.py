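"""Synthetic generators with scheduled, controllable leadership.

Two models are provided:

* a leader-augmented self-propelled particle (Vicsek-type) model on the
  periodic unit square, where followers align with neighbours within a
  radius ``R`` under uniform angular noise while leaders hold a fixed goal
  heading; and
* a stochastic fish-shoal model where each fish's turn rate follows a
  mean-reverting (Ornstein-Uhlenbeck-type) process whose set point couples
  the fish to its neighbours (alignment + attraction) and to the circular
  arena wall.

Leadership is scheduled deterministically through a
:class:`~switchlead.types.SwitchSchedule`; non-interacting pair surrogates
for threshold calibration are generated by disabling all coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .types import SwitchSchedule, TimeSeriesSet

__all__ = [
    "VicsekParams",
    "FishParams",
    "wrap_angle",
    "radius_for_neighbors",
    "simulate_vicsek",
    "simulate_fish",
    "simulate_independent_pairs",
    "polarization",
]

TWO_PI = 2.0 * math.pi


def wrap_angle(x):
    """Wrap angle(s) to the interval (-pi, pi]."""
    return math.pi - (math.pi - np.asarray(x)) % TWO_PI


def radius_for_neighbors(n_neighbors: float, n_particles: int, box_length: float = 1.0) -> float:
    """Interaction radius giving an expected ``n_neighbors`` *other* particles
    within range, for uniformly distributed positions on the periodic square:
    ``pi R^2 / L^2 * (N - 1) = n_neighbors``.
    """
    if n_particles < 2:
        raise ValueError("need at least two particles")
    return box_length * math.sqrt(n_neighbors / (math.pi * (n_particles - 1)))


@dataclass(frozen=True)
class VicsekParams:
    """Parameters of the leader-augmented self-propelled particle model.

    ``noise`` is the angular noise intensity eta in [0, 1]: every particle's
    updated heading receives ``eta * zeta`` with ``zeta ~ U[-pi, pi)``.
    ``expected_neighbors`` (derived) is the mean number of other particles
    within the interaction radius for uniform positions.
    """

    n_particles: int = 2
    speed: float = 0.05
    radius: float = radius_for_neighbors(1, 2)
    box_length: float = 1.0
    noise: float = 0.2
    n_steps: int = 30_000
    transient: int = 10_000
    seed: int = 0
    leader_heading: float | None = None  # drawn from the run RNG when None
    redraw_goal: bool = True  # new goal heading at each leadership change

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.speed <= 0 or self.radius <= 0 or self.box_length <= 0:
            raise ValueError("speed, radius and box_length must be positive")
        if self.noise < 0:
            raise ValueError("noise must be nonnegative")
        if not 0 <= self.transient < self.n_steps:
            raise ValueError("transient must satisfy 0 <= transient < n_steps")

    @property
    def expected_neighbors(self) -> float:
        return math.pi * self.radius**2 / self.box_length**2 * (self.n_particles - 1)


def simulate_vicsek(params: VicsekParams, schedule: SwitchSchedule) -> TimeSeriesSet:
    """Simulate the particle model and return post-transient turn-rate series.

    Followers average the velocity vectors of all particles (self included)
    within the interaction radius under periodic minimal-image distances;
    leaders hold the constant goal velocity.  Both receive uniform angular
    noise on every update.  By default the goal heading is redrawn uniformly
    at every scheduled leadership change, so a switch changes the group's
    goal direction; with ``redraw_goal=False`` the incoming leader adopts
    the current goal, and a switch is observable only through the noise-driven
    fluctuations (the convention for noise-sweep experiments, where a
    noiseless switch must be undetectable in principle).  The returned
    observable is the wrapped
    first difference of the heading angle (one sample per simulated step
    after the transient).
    """
    n, L, v, R = params.n_particles, params.box_length, params.speed, params.radius
    schedule.validate_ids(n)
    for start, _ in schedule.assignments:
        if start >= params.n_steps:
            raise ValueError("schedule start steps must be < n_steps")

    rng = np.random.default_rng(params.seed)
    pos = rng.uniform(0.0, L, size=(n, 2))
    theta = rng.uniform(-math.pi, math.pi, size=n)
    goal = params.leader_heading
    if goal is None:
        goal = float(rng.uniform(-math.pi, math.pi))

    steps = params.n_steps
    zeta = rng.uniform(-math.pi, math.pi, size=(steps, n))
    change_at = {start: leaders for start, leaders in schedule.assignments}

    headings = np.empty((n, steps + 1))
    positions = np.empty((n, steps + 1, 2))
    headings[:, 0] = theta
    positions[:, 0] = pos

    leaders: frozenset[int] = schedule.assignments[0][1]
    is_leader = np.zeros(n, dtype=bool)
    r2 = R * R
    # complex-valued state keeps the update loop lean
    zpos = pos[:, 0] + 1j * pos[:, 1]
    for t in range(steps):
        if t in change_at:
            new = change_at[t]
            if t > 0 and new != leaders and params.redraw_goal:
                goal = float(rng.uniform(-math.pi, math.pi))
            leaders = new
            is_leader[:] = False
            is_leader[list(leaders)] = True

        heading_vec = np.exp(1j * theta)
        if n > 1:
            delta = zpos[:, None] - zpos[None, :]
            dx = np.abs(delta.real) % L
            dy = np.abs(delta.imag) % L
            dx = np.minimum(dx, L - dx)  # minimal image on the torus
            dy = np.minimum(dy, L - dy)
            within = dx * dx + dy * dy <= r2
            mean_vel = within @ heading_vec  # row i: sum of neighbour velocities
            new_theta = np.angle(mean_vel)
        else:
            new_theta = theta.copy()
        new_theta[is_leader] = goal
        theta = wrap_angle(new_theta + params.noise * zeta[t])
        zpos = zpos + v * np.exp(1j * theta)
        zpos = zpos.real % L + 1j * (zpos.imag % L)
        headings[:, t + 1] = theta
        positions[:, t + 1, 0] = zpos.real
        positions[:, t + 1, 1] = zpos.imag

    turn = wrap_angle(np.diff(headings, axis=1))
    tr = params.transient
    return TimeSeriesSet(
        values=turn[:, tr:],
        dt=1.0,
        observable_name="turn_rate",
        positions=positions[:, tr + 1 :, :],
        headings=headings[:, tr + 1 :],
    )


@dataclass(frozen=True)
class FishParams:
    """Parameters of the stochastic fish-shoal model.

    The turn rate ``omega`` (rad/s) of each fish follows
    ``d omega = v [ -alpha (omega - omega*) dt + sigma dW ]``
    where ``omega*`` is a response set point combining wall avoidance
    (``wall_gain * sign(phi_W) / tau_W``, with ``tau_W`` the anticipated
    straight-line time to wall collision) with group-mean alignment and
    attraction terms.  Leaders have ``align_gain = attract_gain = 0``;
    followers have both positive.  Defaults are this package's own
    calibration, chosen so a follower measurably trails its leader's turns:
    relaxation rate ``v * alpha = 10 / s`` (a follower reacts within ~0.1 s,
    as fast-manoeuvring small fish do) and stationary turn-rate standard
    deviation ``sqrt(v sigma^2 / (2 alpha)) ~ 1.1 rad/s``.
    """

    n_fish: int = 2
    speed: float = 0.1  # m/s
    relax_rate: float = 100.0  # alpha, 1/m
    noise_scale: float = 50.0  # sigma, m^-1 rad s^-1/2
    wall_gain: float = 1.0
    align_gain: float = 100.0  # follower k_v
    attract_gain: float = 16.0  # follower k_p
    arena_diameter: float = 4.0  # m
    dt: float = 0.01  # s
    duration: float = 130.0  # s
    seed: int = 0
    tau_wall_max: float = 5.0  # s, cap on anticipated time to collision
    tau_wall_min: float = 0.1  # s, floor to keep the wall term bounded
    discard: float = 0.0  # s dropped from the start of the returned series

    def __post_init__(self) -> None:
        if self.relax_rate <= 0:
            raise ValueError("relax_rate (alpha) must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale (sigma) must be nonnegative")
        if self.dt <= 0 or self.arena_diameter <= 0 or self.speed <= 0:
            raise ValueError("dt, arena_diameter and speed must be positive")
        if self.discard >= self.duration:
            raise ValueError("discard must be shorter than duration")


def simulate_fish(
    params: FishParams,
    schedule: SwitchSchedule,
    *,
    initial_positions: np.ndarray | None = None,
    initial_headings: np.ndarray | None = None,
    initial_turn_rates: np.ndarray | None = None,
) -> TimeSeriesSet:
    """Simulate the fish-shoal model (Euler-Maruyama) and return turn rates.

    The turn rate integrates the stochastic mean-reverting process with step
    ``dt``; the heading follows by forward Euler and positions by forward
    integration at constant speed.  The wall term activates only when a fish
    is moving outward, steering it toward the inward wall normal at the
    anticipated crossing point with strength inversely proportional to the
    anticipated time to collision.
    """
    n = params.n_fish
    schedule.validate_ids(n)
    rng = np.random.default_rng(params.seed)
    a = params.arena_diameter / 2.0
    v, dt = params.speed, params.dt

    if initial_positions is None:
        # uniform over the disk
        r = a * np.sqrt(rng.uniform(0, 1, size=n)) * 0.9
        ang = rng.uniform(-math.pi, math.pi, size=n)
        pos = np.column_stack((r * np.cos(ang), r * np.sin(ang)))
    else:
        pos = np.array(initial_positions, dtype=float)
        if np.any(np.hypot(pos[:, 0], pos[:, 1]) > a):
            raise ValueError("fish initialized outside the arena")
    phi = (
        rng.uniform(-math.pi, math.pi, size=n)
        if initial_headings is None
        else np.array(initial_headings, dtype=float)
    )
    omega = (
        np.zeros(n) if initial_turn_rates is None else np.array(initial_turn_rates, dtype=float)
    )

    steps = int(round(params.duration / dt))
    sqdt = math.sqrt(dt)
    noise = rng.standard_normal(size=(steps, n))
    change_at = {start: leaders for start, leaders in schedule.assignments}

    k_v = np.full(n, params.align_gain)
    k_p = np.full(n, params.attract_gain)

    omegas = np.empty((n, steps))
    headings = np.empty((n, steps))
    positions = np.empty((n, steps, 2))

    for t in range(steps):
        if t in change_at:
            leaders = change_at[t]
            k_v[:] = params.align_gain
            k_p[:] = params.attract_gain
            for i in leaders:
                k_v[i] = 0.0
                k_p[i] = 0.0

        heading_vec = np.column_stack((np.cos(phi), np.sin(phi)))
        target = np.zeros(n)

        # wall avoidance: active when moving outward
        radial = (pos * heading_vec).sum(axis=1)
        outward = radial > 0.0
        if outward.any():
            p2 = (pos[outward] ** 2).sum(axis=1)
            pu = radial[outward]
            s = -pu + np.sqrt(np.maximum(pu**2 + a * a - p2, 0.0))
            tau = np.clip(s / v, params.tau_wall_min, params.tau_wall_max)
            q = pos[outward] + s[:, None] * heading_vec[outward]
            inward = np.arctan2(-q[:, 1], -q[:, 0])
            phi_w = wrap_angle(inward - phi[outward])
            target[outward] += params.wall_gain * np.sign(phi_w) / tau

        if n > 1:
            dphi = wrap_angle(phi[None, :] - phi[:, None])  # phi_j - phi_i
            dx = pos[None, :, :] - pos[:, None, :]
            dist = np.hypot(dx[:, :, 0], dx[:, :, 1])
            bearing = wrap_angle(np.arctan2(dx[:, :, 1], dx[:, :, 0]) - phi[:, None])
            social = k_v[:, None] * v * np.sin(dphi) + k_p[:, None] * dist * np.sin(bearing)
            target += social.sum(axis=1) / n

        omega = omega + v * (
            -params.relax_rate * (omega - target) * dt + params.noise_scale * sqdt * noise[t]
        )
        phi = wrap_angle(phi + omega * dt)
        pos = pos + v * dt * np.column_stack((np.cos(phi), np.sin(phi)))

        omegas[:, t] = omega
        headings[:, t] = phi
        positions[:, t] = pos

    skip = int(round(params.discard / dt))
    return TimeSeriesSet(
        values=omegas[:, skip:],
        dt=dt,
        observable_name="turn_rate",
        positions=positions[:, skip:, :],
        headings=headings[:, skip:],
    )


def simulate_independent_pairs(
    model: str,
    n_pairs: int,
    params: "VicsekParams | FishParams",
    seed: int = 0,
) -> list[TimeSeriesSet]:
    """Non-interacting pair surrogates for threshold calibration.

    Each pair is simulated with all coupling disabled: particle pairs get an
    interaction radius too small to ever contain the other particle, fish
    pairs get zero alignment and attraction gains for both fish.  Seeds for
    the individual pairs are spawned deterministically from ``seed``.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    seeds = np.random.SeedSequence(seed).generate_state(n_pairs) % (2**31)
    out: list[TimeSeriesSet] = []
    for k in range(n_pairs):
        if model == "vicsek":
            p = replace(params, n_particles=2, radius=1e-12, seed=int(seeds[k]))
            # with no neighbours in range both particles behave as leaders of
            # their own headings; schedule leaders are irrelevant but keep one
            out.append(simulate_vicsek(p, SwitchSchedule([(0, [0])])))
        elif model == "fish":
            p = replace(params, n_fish=2, align_gain=0.0, attract_gain=0.0, seed=int(seeds[k]))
            out.append(simulate_fish(p, SwitchSchedule([(0, [0])])))
        else:
            raise ValueError(f"unknown model {model!r}")
    return out


def polarization(series: TimeSeriesSet) -> np.ndarray:
    """Group polarization per step: magnitude of the mean unit-velocity vector.

    1 when all individuals share a heading, near 0 for fully disordered
    groups.  Requires heading angles on the series.
    """
    if series.headings is None:
        raise ValueError("polarization requires heading angles")
    z = np.exp(1j * series.headings)
    return np.abs(z.mean(axis=0))
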