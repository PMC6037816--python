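"""Pairwise directed-influence measures.

Two model-free measures of directed coupling between scalar time series are
provided: histogram transfer entropy (TE) and directed event synchronization
(ES).  Both feed the same net-influence construction: the signed difference
of the two directed values is kept as an edge only when it exceeds a
calibrated threshold, giving an adjacency with antisymmetric support whose
row sums minus column sums (the network divergence) quantify who drives whom.
"""

from __future__ import annotations

import math

import numpy as np

from .types import EventTrain, WeightedAdjacency

__all__ = [
    "transfer_entropy",
    "extract_events",
    "directed_event_sync",
    "default_tau_max",
    "slice_train",
    "event_sync_matrix",
    "net_adjacency",
    "pairwise_influence",
]


def transfer_entropy(
    source: np.ndarray,
    target: np.ndarray,
    n_bins: int = 18,
    lag: int = 1,
) -> float:
    """Transfer entropy (bits) from ``source`` to ``target``.

    The reduction in uncertainty about the target's next value given the
    source's current value, beyond what the target's own current value
    provides:

    ``TE = sum p(x', x, y) log2[ p(x' | x, y) / p(x' | x) ]``

    with ``x' = target[t+lag]``, ``x = target[t]``, ``y = source[t]``.
    Probabilities are estimated by equal-width histograms over the pooled
    min-max range of the two series, so source and target share a common
    alphabet.  Empty cells contribute zero.  The estimate is nonnegative up
    to floating error; a constant target (or fully degenerate pooled range)
    yields exactly 0.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 1:
        raise ValueError("source and target must be 1-D arrays of equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if lag < 1 or source.size <= lag:
        raise ValueError("lag must be >= 1 and shorter than the series")

    lo = min(source.min(), target.min())
    hi = max(source.max(), target.max())
    # sub-resolution variation (e.g. float jitter around a consensus state)
    # carries no information; treat it as constant
    if hi - lo <= 1e-12 * max(1.0, abs(hi), abs(lo)):
        return 0.0
    # digitize to 0..n_bins-1 over the pooled range
    scale = n_bins / (hi - lo)
    s_idx = np.minimum((source - lo) * scale, n_bins - 1).astype(np.intp)
    t_idx = np.minimum((target - lo) * scale, n_bins - 1).astype(np.intp)

    x_next = t_idx[lag:]
    x_now = t_idx[:-lag]
    y_now = s_idx[:-lag]
    n = x_next.size

    flat = (x_next * n_bins + x_now) * n_bins + y_now
    c_xyz = np.bincount(flat, minlength=n_bins**3).reshape(n_bins, n_bins, n_bins)
    c_xy = c_xyz.sum(axis=2)  # (x_next, x_now)
    c_yz = c_xyz.sum(axis=0)  # (x_now, y_now)
    c_y = c_xyz.sum(axis=(0, 2))  # (x_now,)

    mask = c_xyz > 0
    num = c_xyz[mask].astype(float) * c_y[np.nonzero(mask)[1]]
    den = c_yz[np.nonzero(mask)[1], np.nonzero(mask)[2]].astype(float) * c_xy[
        np.nonzero(mask)[0], np.nonzero(mask)[1]
    ]
    te = float(np.sum(c_xyz[mask] / n * np.log2(num / den)))
    return max(te, 0.0)


def extract_events(
    series: np.ndarray,
    c: float = 1.0,
    min_separation: int = 5,
) -> EventTrain:
    """Extract spike events from a scalar series.

    Events are strict local maxima of ``|series|`` exceeding
    ``mean(|series|) + c * std(|series|)``.  Maxima closer than
    ``min_separation`` samples are merged (the larger peak survives).  Each
    event's weight is the number of contiguous above-threshold samples merged
    around it (always >= 1), recording event multiplicity at that location.
    """
    x = np.abs(np.asarray(series, dtype=float))
    if x.size < 3:
        raise ValueError("series must have at least 3 samples")
    if x.std() <= 1e-12 * max(1.0, x.max()):  # sub-resolution jitter only
        return EventTrain(np.empty(0), np.empty(0))
    thr = x.mean() + c * x.std()
    above = x > thr
    if not above.any():
        return EventTrain(np.empty(0), np.empty(0))

    interior = np.arange(1, x.size - 1)
    is_peak = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:]) & above[1:-1]
    peaks = interior[is_peak]
    if peaks.size == 0:
        return EventTrain(np.empty(0), np.empty(0))

    # enforce minimum separation, keeping the larger peak
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < min_separation:
            if x[p] > x[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)

    # weight = size of the contiguous above-threshold run containing the peak
    edges = np.diff(np.concatenate(([False], above, [False])).astype(np.int8))
    runs_start = np.flatnonzero(edges == 1)
    runs_end = np.flatnonzero(edges == -1) - 1
    weights = []
    for p in kept:
        j = np.searchsorted(runs_start, p, side="right") - 1
        weights.append(max(int(runs_end[j] - runs_start[j] + 1), 1))
    return EventTrain(np.asarray(kept, dtype=float), np.asarray(weights, dtype=float))


def default_tau_max(a: EventTrain, b: EventTrain) -> float:
    """Default synchronization horizon: half the pair's median inter-event interval."""
    gaps = np.concatenate([np.diff(a.times), np.diff(b.times)])
    if gaps.size == 0:
        return np.inf
    return float(np.median(gaps)) / 2.0


def directed_event_sync(a: EventTrain, b: EventTrain, tau_max: float) -> float:
    """Directed event synchronization: how often ``b``'s events follow ``a``'s.

    For an event pair ``(k_a, k_b)`` the dynamical delay is half the smallest
    of the four adjacent inter-event waiting times, capped at ``tau_max``.
    The pair contributes ``min(w_a, w_b)`` when ``0 < t_b - t_a <= tau``.
    The sum is normalized by ``sqrt(m_a * m_b)`` (and clipped at 1) so the
    result lies in [0, 1].  Simultaneous events contribute nothing (the
    strict inequality), so identical trains score 0 in both directions.
    """
    if tau_max <= 0:
        raise ValueError("tau_max must be positive")
    ma, mb = a.n_events, b.n_events
    if ma == 0 or mb == 0:
        return 0.0

    def local_scale(train: EventTrain) -> np.ndarray:
        t = train.times
        gaps = np.diff(t)
        prev_gap = np.concatenate(([np.inf], gaps))
        next_gap = np.concatenate((gaps, [np.inf]))
        return np.minimum(prev_gap, next_gap)

    la, lb = local_scale(a), local_scale(b)
    total = 0.0
    for ka in range(ma):
        d = b.times - a.times[ka]
        tau = np.minimum(np.minimum(la[ka], lb) / 2.0, tau_max)
        hit = (d > 0) & (d <= tau)
        if hit.any():
            total += float(np.minimum(a.weights[ka], b.weights[hit]).sum())
    return min(total / math.sqrt(ma * mb), 1.0)


def slice_train(train: EventTrain, start: float, stop: float) -> EventTrain:
    """Events with ``start <= time < stop`` (times kept absolute)."""
    keep = (train.times >= start) & (train.times < stop)
    return EventTrain(train.times[keep], train.weights[keep])


def event_sync_matrix(
    trains: list[EventTrain],
    tau_max: "float | np.ndarray | None" = None,
) -> np.ndarray:
    """Directed ES for every ordered pair of event trains.

    ``tau_max`` may be a scalar, a symmetric per-pair matrix, or None, in
    which case each pair uses half its pooled median inter-event interval.
    """
    n = len(trains)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if tau_max is None:
                tm = default_tau_max(trains[i], trains[j])
            elif np.ndim(tau_max) == 2:
                tm = float(np.asarray(tau_max)[i, j])
            else:
                tm = float(tau_max)
            if not np.isfinite(tm) or tm <= 0:
                continue
            raw[i, j] = directed_event_sync(trains[i], trains[j], tm)
            raw[j, i] = directed_event_sync(trains[j], trains[i], tm)
    return raw


def net_adjacency(pairwise: np.ndarray, threshold: float) -> WeightedAdjacency:
    """Thresholded net-influence adjacency from a raw directed-measure matrix.

    ``A[i, j] = raw[i, j] - raw[j, i]`` when that difference exceeds
    ``threshold``, else 0.  The result has zero diagonal and antisymmetric
    support, and re-applying the construction leaves it unchanged.
    """
    raw = np.asarray(pairwise, dtype=float)
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    diff = raw - raw.T
    out = np.where(diff > threshold, diff, 0.0)
    np.fill_diagonal(out, 0.0)
    return WeightedAdjacency(out, measure="net", threshold=float(threshold))


def pairwise_influence(
    values: np.ndarray,
    measure: str = "te",
    *,
    n_bins: int = 18,
    lag: int = 1,
    spike_std: float = 1.0,
    min_separation: int = 5,
    tau_max: float | None = None,
) -> np.ndarray:
    """Raw directed measure for every ordered pair of series.

    Returns the N x N matrix with entry (i, j) the raw directed measure from
    individual ``i`` to individual ``j`` (zero diagonal).  For ES, event
    trains are extracted once per series with the spike threshold computed on
    the data passed in (so per-window calls adapt to local statistics), and
    ``tau_max`` defaults to half the median inter-event interval of each pair.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    raw = np.zeros((n, n))
    if measure == "te":
        for i in range(n):
            for j in range(n):
                if i != j:
                    raw[i, j] = transfer_entropy(values[i], values[j], n_bins=n_bins, lag=lag)
    elif measure == "es":
        trains = [extract_events(v, c=spike_std, min_separation=min_separation) for v in values]
        raw = event_sync_matrix(trains, tau_max)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return raw
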