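"""Recovery of the free model parameters from burst-duration data.

Five of the eight constants (tau, K, L, X, H) are fixed from the literature;
the remaining three -- connectivity J and the recovery times t_f and t_r --
are identified from summary statistics of a recording session: the mean
first-burst duration and the paired-pulse duration ratios at 5 s and 35 s,
plus (when the dataset provides it) the ratio at 2 s.

The 2-s ratio matters for identifiability: duration summaries at 5 s and
35 s alone leave a near-exact (t_f, t_r) trade-off (the two time constants
compensate each other in both the first duration and the 5-s ratio, and the
35-s ratio is ~1 for any plausible t_r), so t_f is pinned only by an
interval short enough that residual facilitation is still present.

The fit minimises squared *relative* errors between deterministic model
predictions and the observed summaries (relative errors keep seconds-scale
and ratio-scale residuals commensurate): a coarse grid over the declared
bounds, then bounded least-squares refinement from the best grid points.
Deterministic given its inputs.  The firing-rate noise amplitude sigma is
estimated separately, by matching the ensemble spread of first-burst
durations.
"""
from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .bursts import burst_duration_distribution, paired_pulse
from .dynamics import DT_DEFAULT
from .params import ModelParams, StimulusProtocol
from .synth import SyntheticDataset

__all__ = ["FitResult", "FitError", "summary_stats", "observed_summaries",
           "fit", "estimate_noise_sigma"]

FREE_PARAMS = ("J", "t_f", "t_r")
DEFAULT_BOUNDS = {"J": (1.0, 3.0), "t_f": (0.5, 3.0), "t_r": (0.5, 10.0)}
#: summaries every fit requires
REQUIRED_STATS = ("first_duration", "ratio_5s", "ratio_35s")
DEFAULT_INTERVALS = (2.0, 5.0, 35.0)
_RATIO_RE = re.compile(r"^ratio_([0-9.]+)s$")
_FAIL_LOSS = 1e6


class FitError(RuntimeError):
    """No parameter set in the search volume produces a terminating burst."""


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Point estimates, loss at the optimum, and search diagnostics.

    ``diagnostics['curvature']`` is the second difference of the objective
    under a +/-5% perturbation of each free parameter at the optimum;
    near-zero entries flag flat (poorly identified) directions rather than
    hiding them.
    """

    estimates: dict[str, float]
    objective: float
    fixed: ModelParams
    diagnostics: dict

    def to_json(self, path: str | Path) -> None:
        payload = {"estimates": self.estimates, "objective": self.objective,
                   "fixed": self.fixed.to_dict(), "diagnostics": self.diagnostics}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def summary_stats(params: ModelParams, dt: float = DT_DEFAULT,
                  intervals: Sequence[float] = DEFAULT_INTERVALS,
                  tail: float = 6.0) -> dict[str, float]:
    """Deterministic model predictions of the fitted summaries.

    Returns ``first_duration`` (s, from the longest interval, where the
    first burst is never cut short by the second stimulus) and one
    ``ratio_<interval>s`` per paired-pulse interval.  At intervals shorter
    than the burst itself the first duration is window-truncated -- exactly
    what a recording at that interval would show -- and the ratio uses it.
    Raises :class:`FitError` when a second burst (or the longest-interval
    first burst) fails to terminate.
    """
    stats: dict[str, float] = {}
    ordered = sorted(float(v) for v in intervals)
    for interval in ordered:
        res = paired_pulse(params, interval, dt=dt, tail=tail)
        if not res.second.terminated:
            raise FitError("model burst does not terminate inside the window")
        if interval == ordered[-1]:
            if not res.first.terminated:
                raise FitError("model burst does not terminate inside the window")
            stats["first_duration"] = res.first.duration
        stats[f"ratio_{interval:g}s"] = res.ratio
    return stats


def observed_summaries(dataset: SyntheticDataset) -> dict[str, float]:
    """Reduce a paired-condition dataset to observed summary statistics.

    Uses trials labelled ``interval-<v>s``; each interval contributes the
    ratio of its condition means (robust to per-trial zero durations), and
    the first-burst duration comes from the longest-interval condition,
    where the first burst is never truncated by the second stimulus.
    """
    df = dataset.trials
    if "ok" in df.columns:
        df = df[df["ok"].astype(bool)]
    stats: dict[str, float] = {}
    firsts: dict[float, float] = {}
    for condition, grp in df.groupby("condition"):
        m = re.match(r"^interval-([0-9.]+)s$", str(condition))
        if not m:
            continue
        interval = float(m.group(1))
        firsts[interval] = float(grp["duration_0"].mean())
        stats[f"ratio_{interval:g}s"] = float(
            grp["duration_1"].mean() / grp["duration_0"].mean())
    if not firsts:
        raise ValueError("dataset has no interval-<v>s conditions")
    stats["first_duration"] = firsts[max(firsts)]
    missing = [k for k in REQUIRED_STATS if k not in stats]
    if missing:
        raise ValueError(f"dataset is missing required summaries: {missing}")
    return stats


def _target_from(observed) -> dict[str, float]:
    target = observed_summaries(observed) if isinstance(observed, SyntheticDataset) \
        else {k: float(v) for k, v in dict(observed).items()}
    for k in REQUIRED_STATS:
        if k not in target or not np.isfinite(target[k]) or target[k] <= 0:
            raise ValueError(f"observed summary {k!r} missing or not positive")
    return target


def fit(observed: SyntheticDataset | Mapping[str, float],
        free: Sequence[str] = FREE_PARAMS,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        fixed: ModelParams | None = None,
        dt: float = DT_DEFAULT,
        grid_points: int = 7,
        n_starts: int = 3) -> FitResult:
    """Fit the free parameters to observed summary statistics.

    ``observed`` is either a paired-condition :class:`SyntheticDataset` or a
    mapping with at least first_duration, ratio_5s and ratio_35s (ratio_2s
    is used whenever present).  ``fixed`` supplies the literature-fixed
    constants; it defaults to the islands preset.
    """
    from .params import ISLANDS

    target = _target_from(observed)
    base = ISLANDS if fixed is None else fixed
    free = tuple(free)
    if not free or any(f not in FREE_PARAMS for f in free):
        raise ValueError(f"free must be a non-empty subset of {FREE_PARAMS}")
    bnds = {f: tuple(map(float, (bounds or DEFAULT_BOUNDS)[f])) for f in free}

    stat_names = sorted(k for k in target if k == "first_duration" or _RATIO_RE.match(k))
    intervals = sorted(float(_RATIO_RE.match(k).group(1))
                       for k in stat_names if _RATIO_RE.match(k))
    targets = np.array([target[k] for k in stat_names])
    evaluations = {"n": 0, "failures": 0}

    def residuals(values: np.ndarray) -> np.ndarray:
        evaluations["n"] += 1
        p = base.replace(**{f: float(np.clip(v, *bnds[f])) for f, v in zip(free, values)})
        try:
            stats = summary_stats(p, dt=dt, intervals=intervals)
        except FitError:
            evaluations["failures"] += 1
            return np.full(len(stat_names), np.sqrt(_FAIL_LOSS / len(stat_names)))
        model = np.array([stats[k] for k in stat_names])
        return (model - targets) / targets

    def loss(values: np.ndarray) -> float:
        return float(np.sum(residuals(values) ** 2))

    lo = np.array([bnds[f][0] for f in free])
    hi = np.array([bnds[f][1] for f in free])
    axes = [np.linspace(a, b, grid_points) for a, b in zip(lo, hi)]
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=-1)
    grid_losses = np.array([loss(pt) for pt in points])
    if np.all(grid_losses >= _FAIL_LOSS):
        raise FitError("no terminating burst anywhere inside the bounds")
    order = np.argsort(grid_losses)

    scale = np.maximum(np.abs(hi - lo) / 2.0, 1e-3)
    best = None
    for k in order[:max(1, n_starts)]:
        res = least_squares(residuals, points[k], bounds=(lo, hi), x_scale=scale,
                            xtol=1e-10, ftol=1e-12, gtol=1e-12, diff_step=1e-3)
        if best is None or res.cost < best.cost:
            best = res
    opt = np.clip(best.x, lo, hi)
    f_opt = loss(opt)

    curvature = {}
    for i, f in enumerate(free):
        step = 0.05 * max(abs(opt[i]), 1e-3)
        up = opt.copy(); up[i] += step
        dn = opt.copy(); dn[i] -= step
        curvature[f] = float(loss(up) - 2.0 * f_opt + loss(dn))

    diagnostics = {
        "stats_used": stat_names,
        "grid_points_per_axis": grid_points,
        "grid_best": {f: float(v) for f, v in zip(free, points[order[0]])},
        "grid_best_loss": float(grid_losses[order[0]]),
        "n_evaluations": evaluations["n"],
        "n_failures": evaluations["failures"],
        "target": {k: float(v) for k, v in target.items()},
        "curvature": curvature,
        "refine_success": bool(best.success),
    }
    return FitResult(estimates={f: float(v) for f, v in zip(free, opt)},
                     objective=float(f_opt), fixed=base, diagnostics=diagnostics)


def estimate_noise_sigma(observed_sd: float, params: ModelParams,
                         protocol: StimulusProtocol, sigma_grid: Sequence[float],
                         n_runs: int = 500, master_seed: int = 0,
                         dt: float = DT_DEFAULT) -> float:
    """Pick the noise amplitude whose ensemble first-burst duration sd best
    matches ``observed_sd`` (least absolute error on the sd)."""
    grid = [float(s) for s in sigma_grid]
    if not grid or any(s < 0 for s in grid):
        raise ValueError("sigma grid must be non-empty and non-negative")
    errs = []
    for s in grid:
        summary = burst_duration_distribution(params, protocol, n_runs,
                                              sigma=s, master_seed=master_seed, dt=dt)
        errs.append(abs(float(summary.sd[0]) - float(observed_sd)))
    return grid[int(np.argmin(errs))]
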