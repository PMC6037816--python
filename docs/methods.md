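# Methods

This note documents the models, estimators and numerical choices behind
`switchlead`, in enough detail to judge what a passing test suite does and
does not establish.

## Influence measures

**Transfer entropy.** `TE(j→i)` is estimated by plug-in histograms over the
triple `(x_{t+lag}^{(i)}, x_t^{(i)}, x_t^{(j)})` with equal-width bins over
the *pooled* min–max range of the two series in the analysis window, so
source and target share one alphabet and the estimate adapts to
nonstationary amplitude. Defaults: 18 bins for simulator observables (10 is
appropriate for short acceleration records), lag 1 sample, log base 2
(bits). Empty cells contribute nothing; a constant (or jointly degenerate)
window returns exactly 0. The plug-in estimator is biased upward on finite
samples, but the *net* value `TE(i→j) − TE(j→i)` cancels the bias to first
order, which is why thresholding operates on net values (see Calibration).

**Directed event synchronization.** Events are strict local maxima of the
rectified series exceeding `mean + c·std` (default `c = 1`), with maxima
closer than `min_separation` samples (default 5) merged into the larger
peak; an event's weight is the length of the contiguous above-threshold run
it sits in, recording multiplicity. For an event pair the dynamical delay is
half the smallest of the four adjacent waiting times, capped at `τ_max`; a
pair contributes `min(w_a, w_b)` when the target's event follows the
source's by `0 < d ≤ τ`. The sum is normalized by `√(m_a m_b)` and clipped
to `[0, 1]`. Simultaneous events never count, so identical trains score 0
both ways. When the detector windows a record, events are extracted **once
from the whole record** (so the event definition does not drift across
windows), each pair's `τ_max` is fixed from the whole-record trains, and a
window's target train extends `τ` past the window edge so cross-boundary
echoes are not lost.

`τ_max` defaults to half the pair's median inter-event interval. This is the
right choice when the coupling delay is unknown; when it *is* known the
horizon should match it. The particle model's interaction delay is exactly
one update step, so the packaged particle experiments use `τ_max = 2`
samples — the adaptive default admits symmetric chance coincidences that
dilute the measured direction. Likewise, TE's lag should match the coupling
delay: 1 step for the particle model, 10 samples (0.1 s, the follower's
response time constant) for the fish model.

## Network construction and cumulative influence

Edges are net values thresholded at `Ā` (entry `(i, j)` holds the net
influence of `i` on `j`; at most one of a pair's two directions is nonzero;
the diagonal is zero). The network divergence `ΔS^{(i)} = S_out − S_in` sums
to zero across individuals in every window — each retained edge counts once
positively and once negatively — and so does the cumulative influence
`S^{(i)}`, before normalization. Traces shown or reported as "normalized"
are scaled by the largest absolute smoothed value across the whole group
(global, not per-individual), so they stay mutually comparable in `[-1, 1]`.

The cumulative step values (anchored at zero before the first window) are
smoothed with a centered moving average of width 3 windows and interpolated
with a cubic smoothing spline whose penalty is chosen by generalized
cross-validation (`scipy.interpolate.make_smoothing_spline`); records with
fewer than 5 knots fall back to an exact cubic spline.

## Switch detection

Extrema of `Ŝ^{(i)}` are located by derivative sign changes on a dense grid
(25 points per window) and then filtered:

1. **Prominence (zigzag) pruning.** A genuine leadership phase accumulates
   influence over several windows; shallow rebounds are estimator noise.
   Alternating extrema are pruned until every excursion exceeds
   `min_prominence` times a robust per-window noise scale (1.4826/√2 times
   the median absolute successive difference of the window steps, which is
   insensitive to the rare sign flips at true switches). When a pruned
   wiggle separated two same-direction extrema they merge: the more extreme
   survives, the earlier on near-ties, and the merged span is remembered.
   Default `min_prominence = 2.0`, calibrated jointly with the flank rule on
   training schedules (single, double and five-switch runs at 15 replicates)
   against constant-leader runs, before any acceptance measurement.
2. **Dating.** A surviving (possibly plateau-merged) extremum is dated at
   the extremum of the filtered step values over its merged span — the
   interpolant's analytic extremum can sit at the edge of a flat plateau.
3. **Flank admissibility.** The filtered steps must rise for at least 2
   consecutive moves before a maximum and fall for 2 after (mirrored for
   minima), with small opposing moves tolerated as plateau jitter (2% of the
   trace range).
4. **Edge guard.** Extrema within 1 window of either end are discarded.
5. **Raw-peak correction.** The reported time snaps to the most extreme raw
   step value within 2 windows of the dated extremum (earlier on ties),
   undoing interpolation bias. Times are therefore quantized to window
   boundaries.

A maximum is a `leader_to_follower` event, a minimum `follower_to_leader`.
An opt-in slope mode additionally flags a switch when the mean slope over 3
windows changes magnitude by more than 50% without changing sign; the
extremum rules alone reproduce every quantitative benchmark, so slope mode
is off by default.

Per-window *roles* (used for TPR/FPR scoring) come from the interpolant's
slope at each window's centre: leader iff strictly positive. For scoring, a
scheduled switch counts as detected when every individual whose role changes
has a correctly-directed event within **2 windows** of the scheduled step
and no spurious events remain. One window would be stricter than the
benchmark's own practice, which counts detections displaced ~1,200 steps by
interpolation as true positives.

## Calibration

The spurious-link threshold is the one-sided upper `t`-confidence bound
(default `α = 0.05`) on the mean **signed net** measure over non-interacting
surrogate pairs, pooled over both directions (the pooled mean is zero by
construction; the bound is driven by the spread). Raw directed values are
unusable here: the histogram-TE bias on a 20,000-sample record with 18 bins
is of order 0.1 bits, two orders of magnitude above the meaningful
threshold, and only the net construction cancels it. Typical calibrated
values for particle pairs: ~5·10⁻³ (TE, bits) and ~4·10⁻³ (ES).

Window length is selected on training data with known switches: the scan
records, per candidate length, the fraction of runs whose full event set is
correct and the spread of detected times, and keeps the most successful
length (smallest spread on ties). For the particle model 800–1,000 steps
performs best and 1,000 is used throughout; for the fish model 5 s.

For observational records with no ground truth, `make_ground_truth_merge`
builds a switching record from a constant-leadership pair by concatenating
it with its individual-swapped copy (moving-average blend over ±5 samples at
the seam); the seam is a known switch for window selection.

## Synthetic generators

**Particle model.** Followers take the circular mean heading of all
particles (self included) within radius `R` under periodic minimal-image
distances; leaders hold a fixed goal heading. Every particle's updated
heading receives uniform noise `η·ζ`, `ζ ~ U[−π, π)`. Positions advance at
constant speed `v` and wrap on the `L`-torus; the observable is the wrapped
first difference of heading. By default the goal heading is redrawn
uniformly at every scheduled leadership change, so a switch changes the
group's goal direction and is observable at all. The noise-sweep (ROC)
experiments instead let the incoming leader adopt the current goal
(`redraw_goal=False`): under that convention a noiseless switch injects no
signal whatsoever — the group sits in consensus and the ROC curve starts
exactly at the origin — while at positive noise the direction of influence
remains observable through the noise-driven fluctuations. Standard conditions: `N = 2`, `L = 1`,
`v = 0.05`, `η = 0.2`, `R` chosen so the expected number of *other*
particles in range is 1 (`R = L·√(m/(π(N−1)))`, `m = 1` — also used for the
triplet and ten-particle experiments), 10,000 transient steps discarded,
10,000 analysed steps per leadership segment plus a 10,000-step tail.
Surrogates disable coupling by shrinking `R` below any inter-particle
distance.

**Fish-shoal model.** Each fish's turn rate follows the mean-reverting
stochastic process `dω = v[−α(ω − ω*) dt + σ dW]` (Euler–Maruyama, `dt =
0.01 s`), heading and position by forward Euler at constant speed in a 4-m
circular arena. The response set point `ω*` sums wall avoidance
(`k_W·sign(φ_W)/τ_W`, active only when moving outward, with `τ_W` the
anticipated straight-line time to the wall clipped to `[0.1, 5]` s and
`φ_W` the signed angle from heading to the inward wall normal at the
anticipated crossing), group-mean alignment (`k_v·v·sin(φ_j − φ_i)`, the
turn-toward-the-neighbour's-heading convention) and attraction
(`k_p·d_{ij}·sin(bearing of j in i's frame)`). Leaders have
`k_v = k_p = 0`; followers `k_v, k_p > 0`. The published parameter set for
this model family is not available, so the defaults are this package's own
calibration: `v = 0.1 m/s`, `α = 100 m⁻¹` (relaxation rate `vα = 10 s⁻¹` — a
follower reacts within ~0.1 s), `σ = 50 m⁻¹·rad·s^{-1/2}` (stationary
turn-rate sd ≈ 1.1 rad/s), `k_W = 1`, `k_v = 100`, `k_p = 16`, chosen so a
follower measurably trails its leader's turns.

## What the synthetic benchmarks do and do not show

The generators provide ground truth that field data cannot: scheduled
switches, controllable noise, decoupled surrogates. Passing the benchmark
suite shows the estimator chain recovers scheduled leadership changes under
those models' assumptions — pairwise coupling, stationary segment dynamics,
uniform sampling, no measurement noise or tracking gaps. It does not show
robustness to occlusion dropouts, smoothing-induced autocorrelation in
camera tracks, or non-stationary individual state, all present in real
recordings. Two specific limitations:

- With the package's fish calibration, TE-based detection reproduces the
  benchmark behaviour (switch at 60 s of a 130-s record recovered at ~59 s
  with per-window TPR ≈ 0.9), but the rectified-turn-rate spike trains do
  not echo cleanly enough for ES to rank the pair reliably: the follower's
  response is oscillatory rather than a single displaced spike. Fish ES is
  implemented and exposed but not benchmarked. The leader–follower lag
  structure itself is clean: the signed turn-rate cross-correlation is
  maximal at a positive lag before a switch and at a negative lag after.
- In sparse groups (expected one neighbour), relay individuals have
  near-zero net divergence (incoming ≈ outgoing influence), so an incoming
  leader's minimum can be shallow; switch times in the triplet benchmark
  pool the runs in which a correctly-directed event matched the schedule.

## Numerical conventions

Angles wrap to `(−π, π]`. Individuals are 0-based everywhere. Sample index
0 is the first *analysed* sample (after transient/discard); reported switch
times are in the native unit of the input (steps, or seconds via `dt`). One
seeded `numpy` Generator drives each simulation run; schedule changes never
reseed, and identical seeds give bit-identical output. Ties between equally
distant raw-peak candidates resolve to the earlier time. k-means uses
k-means++ with a fixed seed; the clustering coefficient binarizes the net
adjacency and ignores direction.

Benchmark problem sizes: 30 replicates per experiment, 30,000–65,000 steps
per particle run, 13,000 steps per fish run — the sizes at which the
reference summary statistics are quoted and minutes-scale on one CPU.
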