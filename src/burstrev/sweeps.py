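"""Parameter sweeps: the bell-shaped T_R(J) curve, paired-pulse ratio maps,
and the extracellular-calcium -> facilitation-steady-state experiment.

Burst duration rises sub-linearly with connectivity J, peaks at a unique
optimum, then falls as depression dominates; both packaged presets sit close
to their optimum.  Lowering extracellular calcium is modelled as an affine
shift of the facilitation steady state, X = X0 + a (Ca - Ca0), which
shortens the first evoked burst while leaving a 5-s second burst nearly
unchanged.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bursts import paired_pulse, reverberation_time
from .dynamics import DT_DEFAULT, simulate
from .params import ModelParams, StimulusProtocol

__all__ = [
    "SWEEPABLE",
    "SweepResult",
    "CalciumMap",
    "CalciumExperimentResult",
    "sweep",
    "ratio_map",
    "calcium_to_X",
    "calcium_experiment",
    "facilitation_range",
]

SWEEPABLE = ("J", "K", "L", "X", "t_r", "t_f", "sigma")


@dataclasses.dataclass(frozen=True)
class SweepResult:
    """Single-stimulus reverberation times over a parameter grid."""

    param: str
    grid: np.ndarray
    t_r_values: np.ndarray
    terminated: np.ndarray
    optimum: tuple[float, float]      # (parameter value, T_R) at the maximum
    preset_marker: float              # the swept parameter's value in `params`

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"param_value": self.grid, "T_R": self.t_r_values,
                             "terminated": self.terminated})

    def to_csv(self, path: str | Path, summary: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if summary:
            payload = {"param": self.param,
                       "optimum": {"param_value": self.optimum[0], "T_R": self.optimum[1]},
                       "preset_marker": self.preset_marker}
            path.with_suffix(".summary.json").write_text(json.dumps(payload, indent=2) + "\n")

    def n_local_maxima(self) -> int:
        """Count strict interior local maxima of the terminated T_R curve."""
        v = self.t_r_values
        inner = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
        # a plateau followed by a drop counts once: require strict rise before
        return int(np.count_nonzero(inner & (v[1:-1] > v[2:])))


def sweep(params: ModelParams, sweep_param: str, grid: Sequence[float],
          dt: float = DT_DEFAULT, t_end: float = 10.0) -> SweepResult:
    """Deterministic single-stimulus T_R for each value of one parameter.

    Unterminated bursts (no threshold crossing inside ``t_end``) are recorded
    with ``terminated=False`` and excluded from the optimum search.
    """
    if sweep_param not in SWEEPABLE:
        raise ValueError(f"sweep_param must be one of {SWEEPABLE}, got {sweep_param!r}")
    grid_arr = np.asarray(grid, dtype=float)
    if grid_arr.ndim != 1 or grid_arr.size < 1:
        raise ValueError("grid must be a non-empty 1-D sequence")
    if np.any(np.diff(grid_arr) <= 0):
        raise ValueError("grid must be strictly increasing")
    protocol = StimulusProtocol.single()
    values = np.empty_like(grid_arr)
    flags = np.zeros(grid_arr.shape, dtype=bool)
    for i, v in enumerate(grid_arr):
        p = params.replace(**{sweep_param: float(v)})
        trace = simulate(p, protocol, t_end, dt=dt)
        event = reverberation_time(trace, 0.0)
        values[i] = event.duration
        flags[i] = event.terminated
    if flags.any():
        masked = np.where(flags, values, -np.inf)
        k = int(np.argmax(masked))
        optimum = (float(grid_arr[k]), float(values[k]))
    else:
        optimum = (float("nan"), float("nan"))
    return SweepResult(param=sweep_param, grid=grid_arr, t_r_values=values,
                       terminated=flags, optimum=optimum,
                       preset_marker=float(getattr(params, sweep_param)))


def ratio_map(params: ModelParams, J_grid: Sequence[float], interval: float,
              dt: float = DT_DEFAULT, tail: float = 6.0) -> pd.DataFrame:
    """Second/first duration ratio vs connectivity J at a fixed interval.

    The ratio is reported as NaN when either burst fails to terminate or when
    the first response is not a sustained network burst (duration below twice
    the uncoupled decay time tau ln(H/h_T), i.e. the network barely echoes
    the stimulus).
    """
    grid_arr = np.asarray(J_grid, dtype=float)
    rows = []
    floor = 2.0 * params.tau * np.log(params.H / params.h_T)
    for J in grid_arr:
        res = paired_pulse(params.replace(J=float(J)), interval, dt=dt, tail=tail)
        sustained = (res.first.terminated and res.second.terminated
                     and res.first.duration >= floor)
        rows.append({"J": float(J),
                     "first_duration": res.first.duration,
                     "second_duration": res.second.duration,
                     "ratio": res.ratio if sustained else float("nan"),
                     "sustained": sustained})
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class CalciumMap:
    """Affine map from extracellular calcium (mM) to the facilitation
    steady state: X(Ca) = X0 + a (Ca - Ca0).

    The default slope is fixed by the two anchored conditions 2 mM -> 0.5
    (baseline) and 1 mM -> 0.4925 (low calcium), giving a = 0.0075 per mM.
    """

    X0: float = 0.5
    Ca0: float = 2.0
    a: float = 0.0075

    def __post_init__(self) -> None:
        if not 0.0 < self.X0 < 1.0:
            raise ValueError("X0 must lie in (0, 1)")


def calcium_to_X(cal_map: CalciumMap, Ca: float) -> float:
    """Evaluate the affine calcium map; raises if X would leave (0, 1)."""
    X = cal_map.X0 + cal_map.a * (float(Ca) - cal_map.Ca0)
    if not 0.0 < X < 1.0:
        raise ValueError(f"calcium {Ca} mM maps to X={X:.4g} outside (0, 1)")
    return X


def facilitation_range(params: ModelParams, dt: float = DT_DEFAULT,
                       t_end: float = 10.0) -> tuple[float, float, float]:
    """(min x, max x, T_R) over the first-burst window [0, T_R]."""
    trace = simulate(params, StimulusProtocol.single(), t_end, dt=dt)
    event = reverberation_time(trace, 0.0)
    mask = trace.times <= event.duration
    return (float(trace.x[mask].min()), float(trace.x[mask].max()), event.duration)


@dataclasses.dataclass(frozen=True)
class CalciumExperimentResult:
    """Paired-pulse durations at baseline and lowered calcium."""

    Ca_baseline: float
    Ca_low: float
    X_baseline: float
    X_low: float
    interval: float
    baseline: "tuple[float, float]"   # (first, second) durations, s
    low: "tuple[float, float]"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"condition": ["baseline", "baseline", "low-calcium", "low-calcium"],
             "Ca_mM": [self.Ca_baseline, self.Ca_baseline, self.Ca_low, self.Ca_low],
             "X": [self.X_baseline, self.X_baseline, self.X_low, self.X_low],
             "burst": ["first", "second", "first", "second"],
             "duration": [*self.baseline, *self.low]})


def calcium_experiment(params: ModelParams, cal_map: CalciumMap, Ca_low: float,
                       interval: float = 5.0, dt: float = DT_DEFAULT,
                       tail: float = 6.0) -> CalciumExperimentResult:
    """Paired-pulse protocol at baseline calcium and at ``Ca_low``.

    Lowering X shortens the first burst (facilitation controls it) while the
    second burst, already limited by depression, barely changes.
    """
    X_base = calcium_to_X(cal_map, cal_map.Ca0)
    X_low = calcium_to_X(cal_map, Ca_low)
    base = paired_pulse(params.replace(X=X_base), interval, dt=dt, tail=tail)
    low = paired_pulse(params.replace(X=X_low), interval, dt=dt, tail=tail)
    return CalciumExperimentResult(
        Ca_baseline=cal_map.Ca0, Ca_low=float(Ca_low),
        X_baseline=X_base, X_low=X_low, interval=float(interval),
        baseline=(base.first.duration, base.second.duration),
        low=(low.first.duration, low.second.duration))
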