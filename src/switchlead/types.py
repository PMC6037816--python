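"""Core containers shared across the package.

The library works on groups of ``N`` individuals observed through one scalar
observable each (turn rate or acceleration magnitude), sampled on a common
uniform grid.  Individuals are indexed ``0 .. N-1`` everywhere, including in
file formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeriesSet",
    "SwitchSchedule",
    "EventTrain",
    "WeightedAdjacency",
    "WindowedInfluence",
    "InfluenceTrace",
    "SwitchEvent",
]


@dataclass
class TimeSeriesSet:
    """``N`` aligned scalar observable series, one per individual.

    Parameters
    ----------
    values : ndarray, shape (N, T)
        One scalar observable per individual per sample (no missing values).
    dt : float
        Time per sample, in the native unit of the generating process
        (1 step for the discrete-time flocking model, seconds for the
        fish model and kinematics data).
    observable_name : str
        ``"turn_rate"``, ``"acceleration_magnitude"`` or a custom label.
    positions : ndarray, shape (N, T, d), optional
        Trajectory coordinates, when the generating simulator provides them.
    headings : ndarray, shape (N, T), optional
        Heading angles in radians; required by :func:`~switchlead.simulators.polarization`.
    """

    values: np.ndarray
    dt: float = 1.0
    observable_name: str = "turn_rate"
    positions: np.ndarray | None = None
    headings: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (N, T) array")
        if not np.isfinite(self.values).all():
            raise ValueError("values must contain no missing/non-finite samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape[:2] != self.values.shape:
                raise ValueError("positions must be (N, T, d)")
        if self.headings is not None:
            self.headings = np.asarray(self.headings, dtype=float)
            if self.headings.shape != self.values.shape:
                raise ValueError("headings must match values' shape")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, ids: Sequence[int]) -> "TimeSeriesSet":
        """Restrict to a subset of individuals (order preserved)."""
        ids = list(ids)
        return TimeSeriesSet(
            values=self.values[ids],
            dt=self.dt,
            observable_name=self.observable_name,
            positions=None if self.positions is None else self.positions[ids],
            headings=None if self.headings is None else self.headings[ids],
        )


@dataclass(frozen=True)
class SwitchSchedule:
    """Ground-truth leadership assignment over time.

    ``assignments`` is an ordered list of ``(start_step, leader_ids)`` pairs:
    from ``start_step`` (inclusive) until the next entry, exactly the listed
    individuals hold the leader role.  Steps are sample indices in the frame
    of the series the schedule is paired with.
    """

    assignments: tuple[tuple[int, frozenset[int]], ...]

    def __init__(self, assignments: Sequence[tuple[int, Sequence[int]]]):
        norm = tuple(
            (int(start), frozenset(int(i) for i in leaders))
            for start, leaders in assignments
        )
        if not norm:
            raise ValueError("schedule must have at least one assignment")
        if norm[0][0] != 0:
            raise ValueError("first assignment must start at step 0")
        starts = [s for s, _ in norm]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("start steps must be strictly increasing")
        object.__setattr__(self, "assignments", norm)

    def validate_ids(self, n_individuals: int) -> None:
        for _, leaders in self.assignments:
            bad = [i for i in leaders if not 0 <= i < n_individuals]
            if bad:
                raise ValueError(f"schedule names unknown individual(s) {bad}")

    def leaders_at(self, step: int) -> frozenset[int]:
        current = self.assignments[0][1]
        for start, leaders in self.assignments:
            if step >= start:
                current = leaders
            else:
                break
        return current

    def shift(self, offset: int) -> "SwitchSchedule":
        """Re-express the schedule after dropping ``offset`` leading samples.

        Assignments that start before the new origin collapse onto step 0
        (the latest one wins).
        """
        shifted: list[tuple[int, frozenset[int]]] = []
        for start, leaders in self.assignments:
            s = start - offset
            if s <= 0:
                if shifted and shifted[0][0] == 0:
                    shifted[0] = (0, leaders)
                else:
                    shifted.insert(0, (0, leaders))
            else:
                shifted.append((s, leaders))
        return SwitchSchedule(shifted)

    def switch_times(self) -> list[tuple[int, frozenset[int], frozenset[int]]]:
        """``(step, previous_leaders, new_leaders)`` for every actual change."""
        out = []
        for (s0, l0), (s1, l1) in zip(self.assignments, self.assignments[1:]):
            if l1 != l0:
                out.append((s1, l0, l1))
        return out


@dataclass
class EventTrain:
    """Ordered event (spike) times for one individual, with multiplicities.

    ``times`` are sample indices of the retained local maxima; ``weights``
    count how many raw threshold-crossing samples were merged into each event.
    """

    times: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.times.shape != self.weights.shape or self.times.ndim != 1:
            raise ValueError("times and weights must be matching 1-D arrays")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.weights < 1):
            raise ValueError("event weights must be >= 1")

    @property
    def n_events(self) -> int:
        return self.times.size


@dataclass
class WeightedAdjacency:
    """Thresholded net-influence adjacency: entry (i, j) = net influence of i on j.

    By construction at most one of (i, j)/(j, i) is nonzero and the diagonal
    is zero.
    """

    matrix: np.ndarray
    measure: str
    threshold: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("adjacency must be square")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def divergence(self) -> np.ndarray:
        """Network divergence per node: weighted out-degree minus in-degree."""
        return self.matrix.sum(axis=1) - self.matrix.sum(axis=0)


@dataclass
class WindowedInfluence:
    """Per-window thresholded adjacencies and the resulting divergence vectors."""

    window_length: int
    adjacency_per_window: list[WeightedAdjacency]
    divergence: np.ndarray  # (N, n_windows)
    dt: float = 1.0

    @property
    def n_windows(self) -> int:
        return self.divergence.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.divergence.shape[0]


@dataclass
class SwitchEvent:
    """A detected change of leadership status for one individual.

    ``time`` is the extremum of the smooth interpolant; ``corrected_time``
    snaps to the nearest extremum of the raw cumulative step function, both in
    sample units of the analysed series.  A maximum means the individual
    stops leading (``leader_to_follower``); a minimum means it takes over.
    """

    individual: int
    time: float
    direction: str  # "leader_to_follower" | "follower_to_leader"
    corrected_time: float


@dataclass
class InfluenceTrace:
    """Cumulative influence step functions and their smooth interpolants.

    ``times`` holds the window-boundary sample indices ``0, win, 2*win, ...``;
    ``cumulative[:, k]`` is the running sum of window divergences up to and
    including window ``k-1`` (so column 0 is the zero anchor).
    """

    times: np.ndarray  # (n_windows + 1,) window boundary sample indices
    cumulative: np.ndarray  # (N, n_windows + 1) raw step values
    filtered: np.ndarray  # (N, n_windows + 1) after the moving-average filter
    splines: list  # per-individual smooth interpolant S_hat(t)
    window_length: int
    dt: float = 1.0
    switches: list[SwitchEvent] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return self.cumulative.shape[0]

    @property
    def n_windows(self) -> int:
        return self.cumulative.shape[1] - 1

    def smooth(self, i: int, t: np.ndarray | float) -> np.ndarray:
        """Evaluate the smooth interpolant of individual ``i`` at time(s) ``t``."""
        return self.splines[i](np.clip(t, self.times[0], self.times[-1]))

    def normalized(self, t: np.ndarray | float) -> np.ndarray:
        """All interpolants evaluated at ``t`` and scaled into [-1, 1].

        The scale is the largest absolute smoothed value across the whole
        group, so the traces remain mutually comparable.
        """
        grid = np.linspace(self.times[0], self.times[-1], 512)
        peak = max(np.abs([self.smooth(i, grid) for i in range(self.n_individuals)]).max(), 1e-300)
        out = np.array([self.smooth(i, t) for i in range(self.n_individuals)]) / peak
        return np.clip(out, -1.0, 1.0)

    def final_values(self) -> np.ndarray:
        """Smoothed cumulative influence at the end of the observation."""
        return np.array([float(self.smooth(i, self.times[-1])) for i in range(self.n_individuals)])

    def slope_at(self, t: np.ndarray | float) -> np.ndarray:
        """Derivative of every interpolant at time(s) ``t`` (N, ...)."""
        tt = np.clip(t, self.times[0], self.times[-1])
        return np.array([self.splines[i].derivative()(tt) for i in range(self.n_individuals)])

    def role_timeline(self) -> np.ndarray:
        """Predicted per-window roles: True where the trace is increasing.

        The interpolant's slope is evaluated at each window's centre; an
        individual is called a leader in a window iff the slope is strictly
        positive there.
        """
        centers = (self.times[:-1] + self.times[1:]) / 2.0
        return self.slope_at(centers) > 0.0
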