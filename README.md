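# switchlead

Detection of **intermittent, switching leader–follower relationships** in
coupled dynamical systems from movement time series.

In many animal groups — fish shoals, bird flocks, self-propelled particle
swarms — leadership is usually assumed to be fixed: one individual initiates
heading changes and the others follow, for the whole observation. That
assumption often fails. This package detects *when* leadership changes hands,
not just *who* leads on average. It is aimed at researchers in collective
behaviour and network inference who have per-individual scalar observables
(turn rate, acceleration magnitude) sampled on a common clock.

## Method

For `N` individuals observed through scalar series `x_t^(i)`, the record is
split into consecutive windows of `win` samples. In each window every ordered
pair is scored with a model-free directed measure:

- **Transfer entropy (TE)** — the reduction in uncertainty about individual
  *i*'s next value given individual *j*'s current value, beyond *i*'s own
  history, estimated with equal-width histograms (default 18 bins) over the
  pair's pooled range:

  `TE(j→i) = Σ p(x'_i, x_i, x_j) log₂ [ p(x'_i | x_i, x_j) / p(x'_i | x_i) ]`

- **Directed event synchronization (ES)** — the normalized count of event
  pairs in which *j*'s spikes follow *i*'s within a dynamical delay
  `τ = ½ · min(adjacent inter-event intervals)`, capped at `τ_max`.

The signed difference of the two directed values is kept as a network edge
only when it exceeds a threshold `Ā` calibrated from **non-interacting
surrogate pairs** (one-sided t-test upper confidence bound). Each
individual's **network divergence** `ΔS^(i) = S_out − S_in` (weighted
out-degree minus in-degree) is accumulated over windows into the
**cumulative influence function** `S^(i)(t)`: monotonically increasing for a
sustained leader, decreasing for a follower. A smoothing spline through the
(moving-average-filtered) step values gives `Ŝ^(i)(t)`; its interior extrema
mark leadership switches — a **maximum** when a leader steps down, a
**minimum** when a follower takes over — and each reported switch time snaps
back to the peak of the raw step function to undo interpolation bias.

Two synthetic generators with scheduled, controllable leadership are
included for validation and calibration: a leader-augmented Vicsek-type
self-propelled particle model (periodic square, alignment radius `R`,
uniform angular noise `η`) and a stochastic fish-shoal model (mean-reverting
turn-rate process with alignment, attraction and wall-avoidance response in
a circular arena).

## Worked example

```python
import numpy as np
from switchlead import (
    VicsekParams, SwitchSchedule, simulate_vicsek, simulate_independent_pairs,
    calibrate_threshold, detect_run,
)

# threshold from 30 non-interacting particle pairs
surr = simulate_independent_pairs("vicsek", 30, VicsekParams(), seed=42)
thr = calibrate_threshold(surr, "te", n_bins=18).upper_bound
print(f"threshold = {thr:.4f}")

# a pair with leadership switching from 0 to 1 at post-transient step 10,000
schedule = SwitchSchedule([(0, [0]), (20_000, [1])])
series = simulate_vicsek(VicsekParams(seed=7), schedule)
result = detect_run(series, win=1_000, measure="te", threshold=thr, n_bins=18)
for e in result.events:
    print(e.individual, e.direction, int(e.corrected_time))
```

Output:

```
threshold = 0.0049
0 leader_to_follower 10000
1 follower_to_leader 10000
```

The calibrated threshold (0.0049 bits) is the smallest net information flow
distinguishable from estimator noise on decoupled pairs. The detector then
reports that individual 0 stopped leading and individual 1 took over at
post-transient step 10,000 — the programmed switch time.

The same workflow is available from the shell:

```bash
switchlead simulate --model vicsek --config sim.yaml --out run1 --seed 7
switchlead calibrate --surrogates surr/ --measure te
switchlead detect --input run1.csv --measure te --win 1000 --threshold 0.0049 --out report.json
switchlead evaluate --runs runs/ --schedules runs/ --measure te --win 1000 --threshold 0.0049 --out eval.json
```

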