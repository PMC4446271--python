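"""Reverberation-time measurement and paired-pulse protocols.

The reverberation time T_R of a burst evoked at t_stim is the first time
after the stimulus at which the firing rate h falls back to the threshold
h_T (10 Hz by default): T_R = inf{t > 0 : h(t_stim + t) = h_T}.  The
crossing is located from above, after the post-stimulus peak, by linear
interpolation between the bracketing grid points; the search window ends at
the next stimulus (or the end of the trace), and a burst with no crossing
inside its window is returned with ``terminated=False`` and the window
length as its duration.
"""
from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import DT_DEFAULT, Trace, child_seeds, simulate, simulate_stochastic
from .params import ModelParams, StimulusProtocol

__all__ = [
    "BurstEvent",
    "PairedPulseResult",
    "DistributionSummary",
    "reverberation_time",
    "burst_events",
    "paired_pulse",
    "interval_ratio_curve",
    "burst_duration_distribution",
    "events_to_csv",
    "threshold_crossing_duration",
]


@dataclasses.dataclass(frozen=True)
class BurstEvent:
    """One stimulus and its measured reverberation time."""

    stim_time: float
    duration: float     # s, T_R measured from the stimulus
    peak_h: float       # Hz, max firing rate inside the window
    terminated: bool    # threshold crossing found inside the window


@dataclasses.dataclass(frozen=True)
class PairedPulseResult:
    """Two bursts at a fixed inter-stimulus interval and their ratio."""

    interval: float
    first: BurstEvent
    second: BurstEvent

    @property
    def ratio(self) -> float:
        return self.second.duration / self.first.duration


def threshold_crossing_duration(times: np.ndarray, rate: np.ndarray,
                                stim_time: float, window_end: float,
                                h_T: float) -> tuple[float, float, bool]:
    """Generic down-crossing search on a sampled rate signal.

    Returns (duration, peak, terminated).  The search starts at the first
    sample at or after ``stim_time`` where rate >= h_T (so a reset to H is
    never mistaken for an immediate termination) and ends at ``window_end``.
    """
    i0 = int(np.searchsorted(times, stim_time, side="left"))
    i1 = int(np.searchsorted(times, window_end, side="left"))
    if i1 <= i0:
        return (0.0, 0.0, False)
    seg = rate[i0:i1]
    peak = float(np.max(seg))
    above = np.nonzero(seg >= h_T)[0]
    window = float(times[i1 - 1] - stim_time)
    if above.size == 0:
        return (window, peak, False)
    start = int(above[0])
    below = np.nonzero(seg[start:] < h_T)[0]
    if below.size == 0:
        return (window, peak, False)
    k = start + int(below[0])          # first sample strictly below h_T
    h_hi, h_lo = seg[k - 1], seg[k]
    t_hi, t_lo = times[i0 + k - 1], times[i0 + k]
    t_cross = t_hi + (h_hi - h_T) / (h_hi - h_lo) * (t_lo - t_hi)
    return (float(t_cross - stim_time), peak, True)


def reverberation_time(trace: Trace, stim_time: float,
                       h_T: float | None = None) -> BurstEvent:
    """Measure T_R for the burst evoked at ``stim_time`` (must be one of the
    trace's stimulus times)."""
    stims = trace.protocol.stim_times
    matches = [t for t in stims if math.isclose(t, stim_time, abs_tol=trace.dt_record / 2)]
    if not matches:
        raise ValueError(f"stim_time {stim_time} is not in the protocol {stims}")
    t0 = matches[0]
    later = [t for t in stims if t > t0]
    window_end = later[0] if later else float(trace.times[-1]) + trace.dt_record
    thr = trace.params.h_T if h_T is None else float(h_T)
    duration, peak, terminated = threshold_crossing_duration(
        trace.times, trace.h, t0, window_end, thr)
    return BurstEvent(stim_time=t0, duration=duration, peak_h=peak, terminated=terminated)


def burst_events(trace: Trace, h_T: float | None = None) -> list[BurstEvent]:
    """Measure one BurstEvent per stimulus of the trace's protocol."""
    return [reverberation_time(trace, t, h_T) for t in trace.protocol.stim_times]


def _paired_trace(params: ModelParams, interval: float, dt: float,
                  mode: str, seed: int | None, tail: float) -> Trace:
    protocol = StimulusProtocol.paired(interval)
    t_end = interval + tail
    if mode == "deterministic":
        return simulate(params, protocol, t_end, dt=dt)
    if mode == "stochastic":
        if seed is None:
            raise ValueError("stochastic mode requires a seed")
        return simulate_stochastic(params, protocol, t_end, dt=dt, seed=seed)
    raise ValueError(f"mode must be 'deterministic' or 'stochastic', got {mode!r}")


def paired_pulse(params: ModelParams, interval: float, dt: float = DT_DEFAULT,
                 mode: str = "deterministic", seed: int | None = None,
                 tail: float = 6.0) -> PairedPulseResult:
    """Stimulate at t=0 and t=interval and measure both bursts.

    ``tail`` extends the simulation past the second stimulus so the second
    burst can terminate.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    trace = _paired_trace(params, interval, dt, mode, seed, tail)
    first, second = burst_events(trace)
    return PairedPulseResult(interval=float(interval), first=first, second=second)


def interval_ratio_curve(params: ModelParams, intervals: Sequence[float],
                         dt: float = DT_DEFAULT, tail: float = 6.0) -> list[PairedPulseResult]:
    """Paired-pulse ratio as a function of the inter-stimulus interval."""
    arr = [float(v) for v in intervals]
    if any(v <= 0 for v in arr):
        raise ValueError("intervals must be positive")
    if any(b <= a for a, b in zip(arr, arr[1:])):
        raise ValueError("intervals must be strictly increasing")
    return [paired_pulse(params, v, dt=dt, tail=tail) for v in arr]


@dataclasses.dataclass(frozen=True)
class DistributionSummary:
    """Per-stimulus statistics of burst durations over a stochastic ensemble."""

    durations: pd.DataFrame          # one row per run, one column per stimulus
    terminated: pd.DataFrame
    mean: np.ndarray                 # per stimulus
    sd: np.ndarray
    histograms: list[tuple[np.ndarray, np.ndarray]]   # (counts, bin edges)
    sigma: float
    master_seed: int
    seeds: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sigma": self.sigma,
            "master_seed": int(self.master_seed),
            "n_runs": int(len(self.durations)),
            "mean": [float(v) for v in self.mean],
            "sd": [float(v) for v in self.sd],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def burst_duration_distribution(params: ModelParams, protocol: StimulusProtocol,
                                n_runs: int, sigma: float | None = None,
                                master_seed: int = 0, dt: float = DT_DEFAULT,
                                t_end: float | None = None, tail: float = 6.0,
                                n_bins: int = 30) -> DistributionSummary:
    """Ensemble of stochastic runs (child seeds derived from ``master_seed``)
    with per-stimulus mean, sd and histogram of the measured durations."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    s = params.sigma if sigma is None else float(sigma)
    end = (protocol.stim_times[-1] + tail) if t_end is None else float(t_end)
    seeds = child_seeds(master_seed, n_runs)
    rows = []
    flags = []
    for run, seed in enumerate(seeds):
        trace = simulate_stochastic(params, protocol, end, dt=dt, seed=int(seed), sigma=s)
        events = burst_events(trace)
        rows.append([e.duration for e in events])
        flags.append([e.terminated for e in events])
    cols = [f"stim_{i}" for i in range(len(protocol.stim_times))]
    durations = pd.DataFrame(rows, columns=cols)
    terminated = pd.DataFrame(flags, columns=cols)
    mean = durations.mean().to_numpy()
    # population (ddof=0) spread for n=1 degeneracy; ensembles are large anyway
    sd = durations.std(ddof=0).to_numpy()
    histograms = [np.histogram(durations[c].to_numpy(), bins=n_bins) for c in cols]
    return DistributionSummary(durations=durations, terminated=terminated,
                               mean=mean, sd=sd, histograms=histograms,
                               sigma=s, master_seed=int(master_seed), seeds=seeds)


def events_to_csv(events: Iterable[BurstEvent], path: str | Path) -> None:
    """One row per burst: stim_time,duration,peak_h,terminated."""
    df = pd.DataFrame([dataclasses.asdict(e) for e in events],
                      columns=["stim_time", "duration", "peak_h", "terminated"])
    df.to_csv(path, index=False)
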