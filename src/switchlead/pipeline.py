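"""Config-driven end-to-end runs: calibrate -> window -> trace -> switches.

The pipeline mirrors the method's flowchart: (1) obtain data (file or
simulator), (2) fix the spurious-link threshold (given, or calibrated from
non-interacting surrogates), (3) compute windowed net-influence divergences
and the cumulative influence traces, (4) detect switches, shortlist leaders
and, when more than one candidate survives, run the ordering loop.  The
report carries full provenance (parameters, seeds, package version).
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Any

import numpy as np

from . import __version__
from .calibration import calibrate_threshold
from .evaluation import detect_run
from .influence import order_leadership, shortlist_leaders
from .io import derive_observable, read_trajectories
from .simulators import (
    FishParams,
    SwitchSchedule,
    VicsekParams,
    simulate_fish,
    simulate_independent_pairs,
    simulate_vicsek,
)
from .types import TimeSeriesSet

REPORT_SCHEMA = 1

_KNOWN_KEYS = {"input", "simulate", "measure", "detect", "calibrate", "seed"}


def _load_series(config: dict) -> TimeSeriesSet:
    if "input" in config:
        loaded = read_trajectories(config["input"])
        if isinstance(loaded, TimeSeriesSet):
            return loaded
        kind = config.get("measure", {}).get("observable", "accel_magnitude")
        return derive_observable(loaded, kind)
    sim = config["simulate"]
    schedule = SwitchSchedule(sim.get("schedule", [(0, [0])]))
    if sim["model"] == "vicsek":
        return simulate_vicsek(VicsekParams(**sim.get("params", {})), schedule)
    if sim["model"] == "fish":
        return simulate_fish(FishParams(**sim.get("params", {})), schedule)
    raise ValueError(f"unknown model {sim['model']!r}")


def _resolve_threshold(config: dict, measure: str, measure_params: dict) -> tuple[float, dict]:
    detect = config.get("detect", {})
    thr = detect.get("threshold", "auto")
    if isinstance(thr, (int, float)):
        return float(thr), {"mode": "fixed"}
    cal = config.get("calibrate")
    if not cal:
        raise ValueError("threshold 'auto' requires a 'calibrate' section")
    model = cal.get("model", "vicsek")
    params = (
        VicsekParams(**cal.get("params", {}))
        if model == "vicsek"
        else FishParams(**cal.get("params", {}))
    )
    surrogates = simulate_independent_pairs(
        model, cal.get("n_pairs", 30), params, seed=cal.get("seed", config.get("seed", 0))
    )
    report = calibrate_threshold(
        surrogates, measure=measure, alpha=cal.get("alpha", 0.05), **measure_params
    )
    return report.upper_bound, {
        "mode": "calibrated",
        "n_pairs": cal.get("n_pairs", 30),
        "mean": report.mean,
        "std": report.std,
        "confidence_level": report.confidence_level,
    }


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Run the full detection pipeline from a validated configuration dict."""
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if ("input" in config) == ("simulate" in config):
        raise ValueError("config needs exactly one of 'input' or 'simulate'")

    series = _load_series(config)
    mcfg = dict(config.get("measure", {}))
    measure = mcfg.pop("name", "te")
    mcfg.pop("observable", None)
    threshold, thr_info = _resolve_threshold(config, measure, mcfg)

    detect_cfg = dict(config.get("detect", {}))
    detect_cfg.pop("threshold", None)
    win = detect_cfg.pop("win", None)
    if win is None:
        raise ValueError("detect.win is required")

    result = detect_run(
        series, win=win, measure=measure, threshold=threshold,
        detect_params=detect_cfg, **mcfg,
    )
    trace = result.trace
    shortlist = sorted(shortlist_leaders(trace))
    ordering = None
    if len(shortlist) >= 2:
        lo = order_leadership(series, set(shortlist), measure, threshold, win, **mcfg)
        ordering = {"order": lo.order, "ordered": lo.ordered}

    norm = trace.normalized(trace.times)
    return {
        "schema_version": REPORT_SCHEMA,
        "provenance": {
            "switchlead_version": __version__,
            "config": config,
            "threshold": threshold,
            "threshold_info": thr_info,
            "measure": measure,
            "win": win,
        },
        "n_individuals": series.n_individuals,
        "dt": series.dt,
        "trace": {
            "times": (trace.times * series.dt).tolist(),
            "cumulative": trace.cumulative.tolist(),
            "normalized": norm.tolist(),
        },
        "switches": [
            {
                "individual": e.individual,
                "time": e.time * series.dt,
                "corrected_time": e.corrected_time * series.dt,
                "direction": e.direction,
            }
            for e in result.events
        ],
        "shortlist": shortlist,
        "ordering": ordering,
    }
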