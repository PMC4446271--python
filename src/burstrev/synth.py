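"""Surrogate experimental datasets with the statistical structure of the
recordings: per-trial burst durations under firing-rate noise, optional
Gaussian measurement jitter, and Poisson population spike rasters rendered
from rate traces so a rate-threshold duration estimator has realistic input.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bursts import burst_events, threshold_crossing_duration
from .dynamics import DT_DEFAULT, Trace, simulate_stochastic
from .params import ModelParams, StimulusProtocol

__all__ = [
    "SyntheticDataset",
    "generate_trials",
    "generate_paired_conditions",
    "generate_spike_surrogate",
    "rate_from_raster",
    "raster_burst_duration",
]

#: Default sd (s) of the additive measurement jitter on durations -- a
#: declared stand-in loosely matching the spread of slice-burst durations.
MEASUREMENT_SD_DEFAULT = 0.1


@dataclasses.dataclass(frozen=True)
class SyntheticDataset:
    """Per-trial burst durations plus full generating provenance.

    ``trials`` columns: trial, condition, stim_times (semicolon-joined),
    duration_<i> and terminated_<i> per stimulus, seed, ok.
    """

    trials: pd.DataFrame
    provenance: dict

    def durations(self, stim: int = 0, condition: str | None = None) -> np.ndarray:
        df = self.trials
        if condition is not None:
            df = df[df["condition"] == condition]
        return df[f"duration_{stim}"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.trials.to_csv(path, index=False)
        path.with_suffix(".provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SyntheticDataset":
        path = Path(path)
        trials = pd.read_csv(path)
        prov_path = path.with_suffix(".provenance.json")
        provenance = json.loads(prov_path.read_text()) if prov_path.exists() else {}
        return cls(trials=trials, provenance=provenance)

    def concat(self, other: "SyntheticDataset") -> "SyntheticDataset":
        trials = pd.concat([self.trials, other.trials], ignore_index=True)
        prov = {"combined": [self.provenance, other.provenance]}
        return SyntheticDataset(trials=trials, provenance=prov)


def _trial_seeds(master_seed: int, n_trials: int) -> np.ndarray:
    # two independent 32-bit streams per trial: simulation and jitter
    return np.random.SeedSequence(int(master_seed)).generate_state(2 * n_trials)


def generate_trials(params: ModelParams, protocol: StimulusProtocol, n_trials: int,
                    sigma: float | None = None,
                    measurement_sd: float = MEASUREMENT_SD_DEFAULT,
                    master_seed: int = 0, condition: str = "baseline",
                    dt: float = DT_DEFAULT, tail: float = 6.0) -> SyntheticDataset:
    """One stochastic simulation per trial (child seeds), durations measured
    by the threshold rule, then Gaussian measurement jitter of sd
    ``measurement_sd`` added and truncated at zero.

    Failed trials (integration errors) are kept with ``ok=False`` rather than
    dropped, so sample sizes stay honest.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if measurement_sd < 0:
        raise ValueError("measurement_sd must be >= 0")
    s = params.sigma if sigma is None else float(sigma)
    t_end = protocol.stim_times[-1] + tail
    seeds = _trial_seeds(master_seed, n_trials)
    rows = []
    n_stim = len(protocol.stim_times)
    for trial in range(n_trials):
        sim_seed = int(seeds[2 * trial])
        jitter_rng = np.random.default_rng(int(seeds[2 * trial + 1]))
        row: dict = {
            "trial": trial,
            "condition": condition,
            "stim_times": ";".join(f"{t:g}" for t in protocol.stim_times),
            "seed": sim_seed,
        }
        try:
            trace = simulate_stochastic(params, protocol, t_end, dt=dt,
                                        seed=sim_seed, sigma=s)
        except Exception:
            for i in range(n_stim):
                row[f"duration_{i}"] = np.nan
                row[f"terminated_{i}"] = False
            row["ok"] = False
            rows.append(row)
            continue
        for i, event in enumerate(burst_events(trace)):
            d = event.duration
            if measurement_sd > 0:
                d = max(0.0, d + measurement_sd * jitter_rng.standard_normal())
            row[f"duration_{i}"] = d
            row[f"terminated_{i}"] = event.terminated
        row["ok"] = True
        rows.append(row)
    trials = pd.DataFrame(rows)
    provenance = {
        "params": params.to_dict(),
        "protocol": list(protocol.stim_times),
        "n_trials": int(n_trials),
        "sigma": float(s),
        "measurement_sd": float(measurement_sd),
        "master_seed": int(master_seed),
        "condition": condition,
        "dt": float(dt),
        "tail": float(tail),
    }
    return SyntheticDataset(trials=trials, provenance=provenance)


def generate_paired_conditions(params: ModelParams, n_trials: int,
                               intervals: Sequence[float] = (2.0, 5.0, 35.0),
                               sigma: float | None = None,
                               measurement_sd: float = MEASUREMENT_SD_DEFAULT,
                               master_seed: int = 0, dt: float = DT_DEFAULT) -> SyntheticDataset:
    """Paired-pulse trials at each interval (labelled 'interval-<v>s').

    The default intervals cover the alternating 5 s / 35 s stimulation
    protocol plus a 2 s interval from the interval-sweep experiments; the
    short interval is what makes the facilitation recovery time t_f
    identifiable downstream (see :mod:`burstrev.fitting`).
    """
    parts = []
    for k, interval in enumerate(intervals):
        ds = generate_trials(params, StimulusProtocol.paired(interval), n_trials,
                             sigma=sigma, measurement_sd=measurement_sd,
                             master_seed=int(master_seed) + k,
                             condition=f"interval-{interval:g}s", dt=dt)
        parts.append(ds)
    out = parts[0]
    for ds in parts[1:]:
        out = out.concat(ds)
    return out


def generate_spike_surrogate(trace: Trace, n_units: int, seed: int,
                             scale: float = 1.0) -> pd.DataFrame:
    """Render a rate trace as a population spike raster.

    Each unit fires as an independent inhomogeneous Poisson process with
    intensity h+(t) * scale (the mean-field model constrains only the rate;
    no refractoriness).  Returns a DataFrame with columns (unit, time),
    sorted by unit then time.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rate = np.maximum(trace.h, 0.0) * float(scale)
    lam_max = float(rate.max())
    rng = np.random.default_rng(int(seed))
    units = []
    times = []
    t0, t1 = float(trace.times[0]), float(trace.times[-1])
    if lam_max > 0.0:
        for u in range(n_units):
            # thinning: homogeneous candidates at lam_max, accept at h(t)/lam_max
            n_cand = rng.poisson(lam_max * (t1 - t0))
            cand = np.sort(rng.uniform(t0, t1, n_cand))
            accept = rng.uniform(0.0, 1.0, n_cand) * lam_max <= np.interp(cand, trace.times, rate)
            kept = cand[accept]
            units.append(np.full(kept.size, u, dtype=np.int64))
            times.append(kept)
    if units:
        unit_col = np.concatenate(units)
        time_col = np.concatenate(times)
    else:
        unit_col = np.empty(0, dtype=np.int64)
        time_col = np.empty(0)
    return pd.DataFrame({"unit": unit_col, "time": time_col})


def rate_from_raster(raster: pd.DataFrame, n_units: int, bin: float = 0.05,
                     smooth: float = 0.0, t_end: float | None = None,
                     scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Estimate h(t) from a raster: binned counts / (n_units * bin * scale),
    optionally boxcar-smoothed over a ``smooth``-seconds window.

    Returns (bin centres, rate estimate).  An empty raster gives a zero rate
    (over [0, t_end] if given, else a single empty bin).
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    spike_times = raster["time"].to_numpy() if len(raster) else np.empty(0)
    end = float(t_end) if t_end is not None else (float(spike_times.max()) if spike_times.size else bin)
    n_bins = max(1, int(np.ceil(end / bin)))
    edges = np.arange(n_bins + 1) * bin
    counts, _ = np.histogram(spike_times, bins=edges)
    rate = counts / (n_units * bin * scale)
    if smooth > 0:
        w = max(1, int(round(smooth / bin)))
        kernel = np.ones(w) / w
        rate = np.convolve(rate, kernel, mode="same")
    centres = 0.5 * (edges[:-1] + edges[1:])
    return (centres, rate)


def raster_burst_duration(raster: pd.DataFrame, n_units: int, stim_time: float,
                          h_T: float = 10.0, bin: float = 0.05,
                          smooth: float = 0.1, t_end: float | None = None,
                          scale: float = 1.0) -> tuple[float, bool]:
    """Burst duration from a raster via the same threshold rule used on
    traces, applied to the reconstructed rate."""
    times, rate = rate_from_raster(raster, n_units, bin=bin, smooth=smooth,
                                   t_end=t_end, scale=scale)
    end = times[-1] + bin
    duration, _, terminated = threshold_crossing_duration(times, rate, stim_time, end, h_T)
    return (duration, terminated)
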