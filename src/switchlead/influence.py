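"""Cumulative influence traces and leadership-switch detection.

The observation is decomposed into consecutive windows of ``win`` samples;
in each window a thresholded net-influence adjacency is built and every
individual's network divergence (out-strength minus in-strength) recorded.
The running sum of divergences over windows is the cumulative influence
function: monotonically increasing for a sustained leader, decreasing for a
follower.  A smooth interpolant is fit through the (filtered) step values
and its interior extrema are read as leadership switches — a maximum when a
leader steps down, a minimum when a follower takes over — with the reported
switch time snapped back to the nearest extremum of the raw step function to
undo interpolation bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline
from sklearn.cluster import KMeans

from .causality import net_adjacency, pairwise_influence
from .types import (
    InfluenceTrace,
    SwitchEvent,
    TimeSeriesSet,
    WeightedAdjacency,
    WindowedInfluence,
)

__all__ = [
    "window_divergence",
    "cumulative_trace",
    "detect_switches",
    "shortlist_leaders",
    "order_leadership",
    "LeadershipOrder",
    "clustering_coefficient",
    "detect_clusters",
]


def window_divergence(
    series: TimeSeriesSet,
    win: int,
    measure: str = "te",
    threshold: float = 0.0,
    **measure_params,
) -> WindowedInfluence:
    """Per-window thresholded adjacencies and network divergences.

    A trailing partial window is dropped.  In every window the divergences
    sum to zero: each retained edge is counted once positively (its source)
    and once negatively (its target).

    For ES, spike events are extracted once from the whole record (so the
    event definition is consistent across windows) and each pair's
    synchronization horizon is fixed from the whole-record trains; the
    per-window statistic then uses only the events falling in that window.
    """
    T = series.n_samples
    if win < 2:
        raise ValueError("win must be >= 2")
    if win > T:
        raise ValueError("win exceeds the series length")
    n_windows = T // win

    es_trains = es_tau = None
    if measure == "es":
        from .causality import default_tau_max, directed_event_sync, extract_events, slice_train

        c = measure_params.pop("spike_std", 1.0)
        sep = measure_params.pop("min_separation", 5)
        fixed_tau = measure_params.pop("tau_max", None)
        es_trains = [extract_events(v, c=c, min_separation=sep) for v in series.values]
        n = series.n_individuals
        es_tau = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                es_tau[i, j] = es_tau[j, i] = (
                    fixed_tau
                    if fixed_tau is not None
                    else default_tau_max(es_trains[i], es_trains[j])
                )

    adjacencies: list[WeightedAdjacency] = []
    div = np.empty((series.n_individuals, n_windows))
    for w in range(n_windows):
        if measure == "es":
            n = series.n_individuals
            raw = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    if i == j or es_tau[i, j] <= 0 or not np.isfinite(es_tau[i, j]):
                        continue
                    # source events inside the window; target events may echo
                    # up to tau past the window edge
                    src = slice_train(es_trains[i], w * win, (w + 1) * win)
                    tgt = slice_train(es_trains[j], w * win, (w + 1) * win + es_tau[i, j])
                    raw[i, j] = directed_event_sync(src, tgt, es_tau[i, j])
        else:
            chunk = series.values[:, w * win : (w + 1) * win]
            raw = pairwise_influence(chunk, measure=measure, **measure_params)
        adj = net_adjacency(raw, threshold)
        adj.measure = measure
        adjacencies.append(adj)
        div[:, w] = adj.divergence()
    return WindowedInfluence(
        window_length=win, adjacency_per_window=adjacencies, divergence=div, dt=series.dt
    )


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with shrinking edge windows."""
    if width <= 1:
        return y.copy()
    half = width // 2
    out = np.empty_like(y, dtype=float)
    for k in range(y.size):
        lo, hi = max(0, k - half), min(y.size, k + half + 1)
        out[k] = y[lo:hi].mean()
    return out


def cumulative_trace(
    wi: WindowedInfluence,
    filter_width: int = 3,
    smoothing: str = "gcv",
) -> InfluenceTrace:
    """Cumulative influence step functions with smooth interpolants.

    The step values (anchored at zero before the first window) are smoothed
    with a centered moving-average filter and then interpolated with a cubic
    smoothing spline whose penalty is selected by generalized
    cross-validation (``smoothing="gcv"``); ``smoothing="interp"`` fits an
    exact cubic spline instead.  Needs at least 3 windows.
    """
    if wi.n_windows < 3:
        raise ValueError("need at least 3 windows for an interpolant")
    win = wi.window_length
    times = np.arange(wi.n_windows + 1, dtype=float) * win
    cum = np.concatenate(
        [np.zeros((wi.n_individuals, 1)), np.cumsum(wi.divergence, axis=1)], axis=1
    )
    filt = np.array([_moving_average(row, filter_width) for row in cum])

    splines = []
    for row in filt:
        if smoothing == "gcv" and times.size >= 5 and np.ptp(row) > 0:
            splines.append(make_smoothing_spline(times, row))
        else:
            splines.append(CubicSpline(times, row))
    return InfluenceTrace(
        times=times,
        cumulative=cum,
        filtered=filt,
        splines=splines,
        window_length=win,
        dt=wi.dt,
    )


def _noise_scale(cum_row: np.ndarray) -> float:
    """Robust per-window noise scale of a cumulative influence row.

    Estimated from successive differences of the window steps, which are
    insensitive to the (rare) sign flips of the mean step at true switches:
    for steps with within-segment noise sd ``s``, successive differences
    have sd ``s * sqrt(2)``.
    """
    steps = np.diff(cum_row)
    if steps.size < 2:
        return 0.0
    return 1.4826 * float(np.median(np.abs(np.diff(steps)))) / np.sqrt(2.0)


def _flanked(values: np.ndarray, k: int, kind: str, flank: int, net_min: float) -> bool:
    """True when, near index ``k``, the filtered steps rise for ``flank``
    moves and then fall (or vice versa for a minimum).

    The check centres on the local extremum of the filtered values nearest
    ``k`` (the interpolated extremum can straddle two windows).  Moves must
    be non-opposing (monotone up to plateau jitter) with a net change of at
    least ``net_min`` on each side; isolated jitters are rejected.
    """
    sgn = 1.0 if kind == "max" else -1.0
    v = sgn * values
    n = v.size
    lo, hi = max(0, k - 1), min(n, k + 2)
    k = lo + int(np.argmax(v[lo:hi]))
    if k - flank < 0 or k + flank >= n:
        return False
    # plateau tolerance: small opposing moves are jitter
    tol = max(0.02 * float(np.ptp(v)), 0.5 * net_min)
    before = np.diff(v[k - flank : k + 1])
    after = np.diff(v[k : k + flank + 1])
    return bool(
        (before >= -tol).all()
        and before.sum() > max(net_min, 0.0)
        and (after <= tol).all()
        and after.sum() < -max(net_min, 0.0)
    )


def _raw_extrema(values: np.ndarray, kind: str) -> np.ndarray:
    """Indices of interior local maxima/minima of a step-value sequence."""
    s = values if kind == "max" else -values
    idx = np.arange(1, s.size - 1)
    return idx[(s[1:-1] >= s[:-2]) & (s[1:-1] >= s[2:])]


def _prune_extrema(
    cands: list[tuple[float, float, str]],
    bounds: tuple[tuple[float, float], tuple[float, float]],
    depth_thr: float,
) -> list[tuple[float, float, str, float, float]]:
    """Zigzag pruning of an alternating extremum sequence.

    An interior extremum whose excursion relative to both neighbours (previous
    and next extremum or boundary value) is below ``depth_thr`` is estimator
    noise, not a leadership change: the shallowest such extremum is removed
    and the two same-direction neighbours it separated are merged — the more
    extreme one survives, or the earlier one when they differ by less than
    ``depth_thr`` — until every remaining excursion clears the threshold.

    Survivors are returned as ``(t, value, kind, span_lo, span_hi)`` where
    the span covers every same-kind extremum merged into the survivor (a
    plateau top spans all of its micro-extrema).
    """
    (t0, v0), (t1, v1) = bounds
    seq: list[list] = (
        [[t0, v0, "", t0, t0]]
        + [[t, v, kind, t, t] for t, v, kind in cands]
        + [[t1, v1, "", t1, t1]]
    )
    while len(seq) > 2:
        lo_d = [abs(seq[k][1] - seq[k - 1][1]) for k in range(1, len(seq) - 1)]
        hi_d = [abs(seq[k][1] - seq[k + 1][1]) for k in range(1, len(seq) - 1)]
        shallow = [min(a, b) for a, b in zip(lo_d, hi_d)]
        if min(shallow) >= depth_thr:
            break
        # among the shallow extrema, remove the one that is shallow on BOTH
        # sides first (the wiggle itself, not the genuine peak sharing one of
        # its sides); ties resolve to the earliest
        cand_idx = [k for k, d in enumerate(shallow) if d < depth_thr]
        worst = min(cand_idx, key=lambda k: (max(lo_d[k], hi_d[k]), shallow[k], k))
        k = worst + 1
        left, right = seq[k - 1], seq[k + 1]
        del seq[k]
        if left[2] and right[2] and left[2] == right[2]:
            sgn = 1.0 if left[2] == "max" else -1.0
            if abs(left[1] - right[1]) < depth_thr:
                keep = left  # indistinguishable peaks: date at first occurrence
            else:
                keep = left if sgn * left[1] > sgn * right[1] else right
            keep = [keep[0], keep[1], keep[2], min(left[3], right[3]), max(left[4], right[4])]
            seq[k - 1 : k + 1] = [keep]
    return [tuple(p) for p in seq[1:-1]]


def detect_switches(
    trace: InfluenceTrace,
    *,
    edge_guard: int = 1,
    flank: int = 2,
    min_prominence: float = 2.0,
    flank_net: float = 0.0,
    slope_mode: bool = False,
    slope_span: int = 3,
    slope_ratio: float = 0.5,
    grid_per_window: int = 25,
) -> list[SwitchEvent]:
    """Detect leadership switches as admissible extrema of the interpolants.

    Extrema are located by sign changes of the interpolant's derivative on a
    dense grid.  An extremum is kept only when (a) its excursion survives
    zigzag pruning at a depth of ``min_prominence`` standard deviations of
    the individual's per-window divergence steps — a genuine leadership
    phase must accumulate influence for several windows, while shallow
    rebounds on the scale of one or two window steps are estimator noise —
    (b) the filtered step values show at least
    ``flank`` consecutive non-opposing moves with a strict net change on
    each side, and (c) it is more than ``edge_guard`` windows away from
    either end of the observation.  The reported ``corrected_time`` snaps to
    the raw step-function extremum nearest the interpolated one (earlier one
    on ties).  With ``slope_mode`` a switch is additionally flagged when the
    mean slope over ``slope_span`` windows changes magnitude by more than
    ``slope_ratio`` while keeping its sign (an opt-in, weaker criterion).

    An empty list means leadership was constant.
    """
    win = trace.window_length
    t0, t1 = trace.times[0], trace.times[-1]
    grid = np.linspace(t0, t1, grid_per_window * trace.n_windows + 1)
    lo_guard = t0 + edge_guard * win
    hi_guard = t1 - edge_guard * win

    events: list[SwitchEvent] = []
    for i in range(trace.n_individuals):
        spline = trace.splines[i]
        deriv = spline.derivative()(grid)
        sign = np.sign(deriv)
        flips = np.nonzero(np.diff(sign) != 0)[0]
        cands: list[tuple[float, float, str]] = []
        for f in flips:
            # refine the crossing by linear interpolation of the derivative
            g0, g1 = grid[f], grid[f + 1]
            d0, d1 = deriv[f], deriv[f + 1]
            t_star = g0 if d1 == d0 else g0 + (g1 - g0) * (-d0) / (d1 - d0)
            kind = "max" if d0 > 0 else "min"
            cands.append((float(t_star), float(spline(t_star)), kind))
        sigma = _noise_scale(trace.cumulative[i])
        depth_thr = min_prominence * sigma
        kept = _prune_extrema(
            cands,
            ((float(t0), float(spline(t0))), (float(t1), float(spline(t1)))),
            depth_thr,
        )
        for t_star, _, kind, span_lo, span_hi in kept:
            # date a (possibly plateau-merged) extremum at the best-supported
            # window: the extremum of the filtered steps over the merged span
            sgn = 1.0 if kind == "max" else -1.0
            k_lo = max(0, int(round(span_lo / win)) - 1)
            k_hi = min(trace.n_windows, int(round(span_hi / win)) + 1)
            k = k_lo + int(np.argmax(sgn * trace.filtered[i][k_lo : k_hi + 1]))
            t_ref = float(trace.times[k])
            if not (lo_guard < t_ref < hi_guard):
                continue
            if not _flanked(trace.filtered[i], k, kind, flank, flank_net * sigma):
                continue
            # snap to the peak of the raw step values near the interpolated
            # extremum (most extreme raw value within 2 windows; earlier on ties)
            near = np.flatnonzero(np.abs(trace.times - t_ref) <= 2 * win)
            raw_vals = sgn * trace.cumulative[i][near]
            corrected = float(trace.times[near[np.argmax(raw_vals)]])
            # report the interpolated extremum nearest the chosen window
            t_near = min(
                (c[0] for c in cands if c[2] == kind and span_lo <= c[0] <= span_hi),
                key=lambda t: abs(t - t_ref),
                default=t_star,
            )
            event = SwitchEvent(
                individual=i,
                time=float(t_near),
                direction="leader_to_follower" if kind == "max" else "follower_to_leader",
                corrected_time=corrected,
            )
            if not any(
                e.individual == i
                and e.direction == event.direction
                and e.corrected_time == corrected
                for e in events
            ):
                events.append(event)
        if slope_mode:
            events.extend(_slope_switches(trace, i, slope_span, slope_ratio, lo_guard, hi_guard))
    events.sort(key=lambda e: (e.individual, e.time))
    trace.switches = events
    return events


def _slope_switches(trace, i, span, ratio, lo_guard, hi_guard) -> list[SwitchEvent]:
    """Opt-in detection of significant slope changes without a sign flip."""
    win = trace.window_length
    steps = np.diff(trace.filtered[i]) / win
    out = []
    for k in range(span, steps.size - span + 1):
        before = steps[k - span : k].mean()
        after = steps[k : k + span].mean()
        t = trace.times[k]
        if not (lo_guard < t < hi_guard) or np.sign(before) != np.sign(after) or before == 0:
            continue
        change = (after - before) / abs(before)
        if change < -ratio:
            out.append(SwitchEvent(i, float(t), "leader_to_follower", float(t)))
        elif change > ratio:
            out.append(SwitchEvent(i, float(t), "follower_to_leader", float(t)))
    return out


def shortlist_leaders(trace: InfluenceTrace) -> set[int]:
    """Candidate leaders: final smoothed influence above the 1 - 2/N quantile.

    With N individuals the quantile keeps roughly the top two; ties at the
    quantile are all returned, and a pair (quantile 0) returns both ids.
    """
    finals = trace.final_values()
    n = finals.size
    if n < 2:
        raise ValueError("need at least 2 individuals")
    q = np.quantile(finals, 1.0 - 2.0 / n)
    return {int(i) for i in np.nonzero(finals >= q)[0]}


@dataclass
class LeadershipOrder:
    """Result of the recursive ordering loop.

    ``order`` lists ids from most to least influential; ``ordered`` is False
    when no direction of net information flow could be established (the
    order is then meaningless and reported as such).
    """

    order: list[int]
    ordered: bool


def order_leadership(
    series: TimeSeriesSet,
    candidates: set[int],
    measure: str = "te",
    threshold: float = 0.0,
    win: int | None = None,
    **measure_params,
) -> LeadershipOrder:
    """Establish a chain of influence among candidate individuals.

    The most influential candidate (largest final cumulative influence) is
    recorded and removed, and the analysis re-run on the remainder until a
    pair is left, which is ordered by the sign of the net measure over the
    whole record.  Returns ``ordered=False`` when no net flow exceeds the
    threshold anywhere along the way.
    """
    ids = sorted(candidates)
    if len(ids) < 2:
        raise ValueError("need at least 2 candidates")
    order: list[int] = []
    while len(ids) > 2:
        sub = series.subset(ids)
        wi = window_divergence(sub, win or sub.n_samples // 3, measure, threshold, **measure_params)
        trace = cumulative_trace(wi)
        finals = trace.final_values()
        if np.allclose(finals, finals[0]):
            return LeadershipOrder(order + ids, ordered=False)
        top = int(np.argmax(finals))
        order.append(ids.pop(top))
    # pair base case: direction of the whole-record net flow
    sub = series.subset(ids)
    raw = pairwise_influence(sub.values, measure=measure, **measure_params)
    net = raw[0, 1] - raw[1, 0]
    if abs(net) <= threshold:
        return LeadershipOrder(order + ids, ordered=False)
    pair = ids if net > 0 else ids[::-1]
    return LeadershipOrder(order + pair, ordered=True)


def clustering_coefficient(adj: WeightedAdjacency) -> np.ndarray:
    """Local clustering coefficient per node of the binarized adjacency.

    Edge direction is ignored (an edge exists iff either directed weight is
    positive).  ``C = 2 xi / (k (k - 1))`` with ``xi`` the number of edges
    among the node's ``k`` neighbours; nodes with fewer than two neighbours
    get 0.  High values single out individuals at the centre of a cluster.
    """
    m = (adj.matrix + adj.matrix.T) > 0
    g = nx.from_numpy_array(m.astype(int))
    cc = nx.clustering(g)
    return np.array([cc[i] for i in range(adj.n)])


def detect_clusters(states: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means cluster assignment of per-individual state vectors.

    Euclidean distance, k-means++ initialization with a fixed seed; ``k`` is
    typically the number of individuals with the largest clustering
    coefficient.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if not 1 <= k <= states.shape[0]:
        raise ValueError("k must be between 1 and the number of individuals")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(states)
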