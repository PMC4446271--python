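"""Reduced dynamics under h ~ H and the closed-form reverberation time.

During the early burst the firing rate is approximated by the constant H in
the facilitation and depression equations, which then decouple from h:

    x(t) = x_inf + (X - x_inf) * exp(-beta t),  beta = 1/t_f + K H,
    x_inf = (X/t_f + K H) / beta,

and y obeys the linear equation dy/dt = 1/t_r - (1/t_r + L H x(t)) y, solved
here by an integrating factor (the integral of x is analytic; the remaining
quadrature is done on a dense Simpson grid).

While h > 0 the h equation is linear in h, so the exact representation

    h(t) = H * exp( (-t + J * int_0^t x y ds) / tau )

holds for any (x, y) path; plugging the reduced path in gives the
approximated firing rate, and expanding the integral to second order in t
yields the closed-form estimate T_R(J) implemented in
:func:`tr_closed_form`, with theta = 1 - J X tau:

    T_R(J) = [theta - sqrt(theta^2 - 2 J tau X H (K - L X) tau ln(H/h_T))]
             / (J tau X H (K - L X))

The closed form is kept exactly in this printed grouping; its disagreement
with the reduced-system oracle (which grows with J) is measured, not hidden:
:func:`compare_estimates` reports all three curves side by side and flags
the regime where the closed form deviates by more than a factor of two.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson

from .bursts import threshold_crossing_duration
from .dynamics import DT_DEFAULT, simulate
from .params import ModelParams, StimulusProtocol

__all__ = [
    "AnalyticEstimate",
    "approximated_xy",
    "firing_rate_integral_form",
    "reduced_tr",
    "tr_closed_form",
    "compare_estimates",
]


@dataclasses.dataclass(frozen=True)
class AnalyticEstimate:
    """Closed-form reverberation-time estimate and its validity."""

    T_R_closed: float
    theta: float
    valid: bool


def _x_reduced(params: ModelParams, t: np.ndarray) -> np.ndarray:
    p = params
    beta = 1.0 / p.t_f + p.K * p.H
    x_inf = (p.X / p.t_f + p.K * p.H) / beta
    return x_inf + (p.X - x_inf) * np.exp(-beta * t)


def _int_x_reduced(params: ModelParams, t: np.ndarray) -> np.ndarray:
    """Analytic integral of the reduced x(t) from 0 to t."""
    p = params
    beta = 1.0 / p.t_f + p.K * p.H
    x_inf = (p.X / p.t_f + p.K * p.H) / beta
    return x_inf * t + (p.X - x_inf) * (1.0 - np.exp(-beta * t)) / beta


def approximated_xy(params: ModelParams, t: float | np.ndarray,
                    n_quad: int = 20001) -> tuple[np.ndarray, np.ndarray]:
    """(x(t), y(t)) of the reduced system (h held at H), initial (X, 1).

    ``t`` may be a scalar or array of non-negative times; returns arrays of
    the same shape.  y uses the exact integrating factor
    mu(t) = exp(t/t_r + L H int_0^t x ds) with a dense-Simpson quadrature of
    int mu, accurate to well below 1e-6 for the packaged presets.
    """
    p = params
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    x_vals = _x_reduced(params, t_arr)
    t_max = float(t_arr.max()) if t_arr.size else 0.0
    if t_max == 0.0:
        y_vals = np.ones_like(t_arr)
    else:
        grid = np.linspace(0.0, t_max, n_quad)
        log_mu = grid / p.t_r + p.L * p.H * _int_x_reduced(params, grid)
        # rescale to avoid overflow for long horizons
        shift = log_mu.max()
        integrand = np.exp(log_mu - shift)
        cum = cumulative_simpson(integrand, x=grid, initial=0.0)
        log_mu_t = t_arr / p.t_r + p.L * p.H * _int_x_reduced(params, t_arr)
        cum_t = np.interp(t_arr, grid, cum)
        y_vals = np.exp(-log_mu_t) + (1.0 / p.t_r) * cum_t * np.exp(shift - log_mu_t)
    if np.ndim(t) == 0:
        return (float(x_vals[0]), float(y_vals[0]))
    return (x_vals, y_vals)


def firing_rate_integral_form(params: ModelParams, times: np.ndarray,
                              x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Evaluate h(t) = H exp((-t + J int_0^t x y ds)/tau) on the given path.

    The integral is computed by composite Simpson on the stored grid.  With
    the exact (x, y) path from a full simulation this representation is
    exact (the h equation is linear in h while h > 0); with the reduced path
    it gives the early-burst approximation.
    """
    times = np.asarray(times, dtype=float)
    integral = cumulative_simpson(np.asarray(x) * np.asarray(y), x=times, initial=0.0)
    return params.H * np.exp((-(times - times[0]) + params.J * integral) / params.tau)


def reduced_tr(params: ModelParams, t_max: float = 10.0,
               n_grid: int = 100001) -> tuple[float, bool]:
    """Reverberation time of the reduced system: first down-crossing of h_T
    by H exp((-t + J int x y)/tau) with the reduced (x, y) path.

    Returns (duration, terminated); duration is ``t_max`` when the reduced
    firing rate never falls back to threshold inside the horizon.
    """
    grid = np.linspace(0.0, t_max, n_grid)
    x, y = approximated_xy(params, grid)
    h = firing_rate_integral_form(params, grid, x, y)
    duration, _, terminated = threshold_crossing_duration(
        grid, h, 0.0, t_max + (grid[1] - grid[0]), params.h_T)
    return (duration, terminated)


def tr_closed_form(params: ModelParams) -> AnalyticEstimate:
    """Closed-form T_R(J), evaluated exactly in the printed grouping.

    theta = 1 - J X tau; the physical root is the '-' branch (verified
    against the reduced-system oracle; see compare_estimates).  The estimate
    is flagged invalid when the discriminant is negative or the prefactor
    J tau X H (K - L X) vanishes; in the latter case the analytic limit
    tau ln(H/h_T) / theta is still returned as the value.
    """
    p = params
    c = p.tau * math.log(p.H / p.h_T)
    theta = 1.0 - p.J * p.X * p.tau
    a = p.J * p.tau * p.X * p.H * (p.K - p.L * p.X)
    disc = theta * theta - 2.0 * a * c
    if disc < 0.0:
        return AnalyticEstimate(T_R_closed=float("nan"), theta=theta, valid=False)
    # '-' branch (theta - sqrt(disc))/a, rationalized to 2c/(theta + sqrt(disc))
    # which is exact for a = 0 and immune to cancellation at small J
    value = 2.0 * c / (theta + math.sqrt(disc))
    valid = bool(a != 0.0 and value > 0 and math.isfinite(value))
    return AnalyticEstimate(T_R_closed=value, theta=theta, valid=valid)


def full_tr(params: ModelParams, dt: float = DT_DEFAULT, t_end: float = 10.0) -> tuple[float, bool]:
    """Numerical T_R of the full system for a single stimulus at t=0."""
    from .bursts import reverberation_time

    trace = simulate(params, StimulusProtocol.single(), t_end, dt=dt)
    event = reverberation_time(trace, 0.0)
    return (event.duration, event.terminated)


def compare_estimates(params: ModelParams, J_grid, dt: float = DT_DEFAULT,
                      t_end: float = 10.0) -> pd.DataFrame:
    """Full-system, reduced-system and closed-form T_R on a grid of J.

    Returns a DataFrame with columns J, T_R_full, T_R_reduced, T_R_closed,
    valid.  ``df.attrs['closed_form_note']`` records where the printed closed
    form deviates from the reduced oracle by more than a factor of two.
    """
    rows = []
    for J in np.asarray(J_grid, dtype=float):
        pj = params.replace(J=float(J))
        tr_full, term_full = full_tr(pj, dt=dt, t_end=t_end)
        tr_red, term_red = reduced_tr(pj, t_max=t_end)
        est = tr_closed_form(pj)
        rows.append({"J": float(J), "T_R_full": tr_full, "T_R_reduced": tr_red,
                     "T_R_closed": est.T_R_closed, "valid": est.valid,
                     "full_terminated": term_full, "reduced_terminated": term_red})
    df = pd.DataFrame(rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        off = df["T_R_closed"] / df["T_R_reduced"]
    bad = df["J"][(off > 2.0) | (off < 0.5)]
    if len(bad):
        df.attrs["closed_form_note"] = (
            "printed closed form deviates from the reduced-system oracle by "
            f">2x for J >= {bad.min():.3g}; the printed grouping is kept as-is"
        )
    else:
        df.attrs["closed_form_note"] = "closed form within 2x of the reduced oracle on this grid"
    return df
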