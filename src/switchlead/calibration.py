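"""Threshold calibration from non-interacting surrogates and window selection.

The spurious-link threshold is the one-sided upper t-confidence bound on the
mean net measure computed over surrogate pairs with all coupling disabled;
the detection window length is chosen on training data with known switches
as the value maximizing detection success (ties broken by the smallest
spread of detected times).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .causality import pairwise_influence
from .evaluation import detect_run, match_switches
from .types import SwitchSchedule, TimeSeriesSet

__all__ = [
    "ThresholdReport",
    "WindowScan",
    "calibrate_threshold",
    "scan_window",
    "make_ground_truth_merge",
]


@dataclass
class ThresholdReport:
    """Outcome of surrogate calibration.

    ``upper_bound`` is the retained threshold: ``mean + t_{alpha, n-1} * s / sqrt(n)``
    over the pooled signed net values (never negative — the net construction
    only thresholds positive differences).  ``degenerate`` flags an
    all-identical sample (zero spread), where the bound collapses to the mean.
    """

    measure: str
    sample_values: np.ndarray
    mean: float
    std: float
    n: int
    confidence_level: float
    upper_bound: float
    degenerate: bool = False


def calibrate_threshold(
    surrogates: list[TimeSeriesSet],
    measure: str = "te",
    alpha: float = 0.05,
    **measure_params,
) -> ThresholdReport:
    """Spurious-link threshold from non-interacting pairs.

    For every surrogate pair the signed net measure (difference of the two
    directed values) is computed on the full record and pooled over both
    directions; the threshold is the one-sided upper bound of the
    t-confidence interval for the pooled mean at level ``1 - alpha``.
    """
    if len(surrogates) < 2:
        raise ValueError("need at least 2 surrogate pairs")
    values: list[float] = []
    for ts in surrogates:
        raw = pairwise_influence(ts.values, measure=measure, **measure_params)
        net = float(raw[0, 1] - raw[1, 0])
        values.extend([net, -net])
    sample = np.asarray(values)
    n = sample.size
    mean = float(sample.mean())
    s = float(sample.std(ddof=1))
    if s == 0.0:
        return ThresholdReport(measure, sample, mean, s, n, 1 - alpha, max(mean, 0.0), True)
    t_crit = float(stats.t.ppf(1.0 - alpha, df=n - 1))
    bound = mean + t_crit * s / np.sqrt(n)
    return ThresholdReport(measure, sample, mean, s, n, 1 - alpha, max(bound, 0.0))


@dataclass
class WindowScan:
    """Window-length scan summary: per-window success rate and switch-time
    statistics; ``selected`` maximizes the success rate with ties broken by
    the smallest std of detected times."""

    window_lengths: list[int]
    success_rate: list[float]
    mean_detected_time: list[float]
    std_detected_time: list[float]
    selected: int


def scan_window(
    training: list[tuple[TimeSeriesSet, SwitchSchedule]],
    win_grid: list[int],
    measure: str = "te",
    threshold: float = 0.0,
    **measure_params,
) -> WindowScan:
    """Select the detection window on training data with known switches.

    For each candidate window length the full detector runs on every
    training set; a run succeeds when every scheduled switch is matched by a
    correctly-directed detected event within the matching tolerance (two
    windows) and no extra events are reported.  Detected-time statistics
    pool the matched events.
    """
    if not win_grid:
        raise ValueError("empty window grid")
    rates, means, stds = [], [], []
    for win in win_grid:
        successes, times = 0, []
        for ts, schedule in training:
            result = detect_run(ts, win=win, measure=measure, threshold=threshold, **measure_params)
            ok, matched = match_switches(result.events, schedule, win, ts.n_individuals)
            successes += int(ok)
            times.extend(matched)
        rates.append(successes / len(training))
        means.append(float(np.mean(times)) if times else np.nan)
        stds.append(float(np.std(times)) if times else np.inf)
    order = sorted(
        range(len(win_grid)), key=lambda k: (-rates[k], stds[k] if np.isfinite(stds[k]) else np.inf)
    )
    return WindowScan(list(win_grid), rates, means, stds, selected=win_grid[order[0]])


def make_ground_truth_merge(base: TimeSeriesSet, blend: int = 5) -> tuple[TimeSeriesSet, SwitchSchedule]:
    """Merge-and-flip construction of a switching ground truth from a
    constant-leadership pair.

    The record is concatenated with its individual-swapped copy so the
    direction of information flow inverts exactly at the seam; ``blend``
    samples around the seam are smoothed with a moving average to avoid a
    spurious discontinuity.  The returned schedule places the switch at the
    seam (leader 0 before, leader 1 after).
    """
    if base.n_individuals != 2:
        raise ValueError("merge-and-flip needs a 2-individual record")
    T = base.n_samples
    merged = np.concatenate([base.values, base.values[::-1]], axis=1)
    if blend > 0:
        lo, hi = max(0, T - blend), min(2 * T, T + blend)
        width = 2 * blend + 1
        for i in range(2):
            seg = merged[i, max(0, lo - width) : min(2 * T, hi + width)].copy()
            kernel = np.ones(width) / width
            sm = np.convolve(seg, kernel, mode="same")
            off = max(0, lo - width)
            merged[i, lo:hi] = sm[lo - off : hi - off]
    out = TimeSeriesSet(values=merged, dt=base.dt, observable_name=base.observable_name)
    return out, SwitchSchedule([(0, [0]), (T, [1])])
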