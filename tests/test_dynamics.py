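"""Integrator correctness: fixed point, drift arithmetic, stimulus events,
box invariance, convergence, and agreement with an adaptive ODE oracle."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from burstrev.dynamics import (
    IntegrationError,
    NetworkState,
    apply_stimulus,
    derivatives,
    resting_state,
    simulate,
    simulate_stochastic,
)
from burstrev.params import ModelParams, StimulusProtocol


def test_resting_state_is_a_fixed_point(islands):
    rest = resting_state(islands)
    assert (rest.h, rest.x, rest.y) == (0.0, islands.X, 1.0)
    assert sum(abs(d) for d in derivatives(rest, islands)) < 1e-12
    low = islands.replace(X=0.4925)
    assert resting_state(low).x == 0.4925
    assert sum(abs(d) for d in derivatives(resting_state(low), low)) < 1e-12


def test_drift_matches_hand_arithmetic(islands):
    # tau dh/dt = -50 + 1.98*0.5*1*50 = -0.5  =>  dh/dt = -50 Hz/s
    # dx/dt = 0 + 0.004*0.5*50 = 0.1 /s ; dy/dt = -0.0054*0.5*1*50 = -0.135 /s
    dh, dx, dy = derivatives(NetworkState(h=50.0, x=0.5, y=1.0), islands)
    assert dh == pytest.approx(-50.0, rel=1e-9)
    assert dx == pytest.approx(0.1, rel=1e-12)
    assert dy == pytest.approx(-0.135, rel=1e-12)


def test_negative_h_is_rectified_in_couplings(islands):
    dh, dx, dy = derivatives(NetworkState(h=-5.0, x=0.7, y=0.8), islands)
    assert dh == pytest.approx(5.0 / islands.tau)          # pure -h/tau relaxation
    assert dx == pytest.approx((islands.X - 0.7) / islands.t_f)
    assert dy == pytest.approx((1.0 - 0.8) / islands.t_r)


def test_stimulus_is_a_hard_idempotent_reset(islands):
    s = NetworkState(h=3.2, x=0.6, y=0.4, t=1.0)
    hit = apply_stimulus(s, islands)
    assert (hit.h, hit.x, hit.y, hit.t) == (50.0, 0.6, 0.4, 1.0)
    assert apply_stimulus(hit, islands) == hit
    assert apply_stimulus(NetworkState(0.0, 0.5, 1.0), islands).h == 50.0


def test_unstimulated_network_stays_at_rest(islands):
    trace = simulate(islands, StimulusProtocol.from_iterable(()), 1.0, dt=1e-3)
    assert np.all(trace.h == 0.0)
    assert np.all(trace.x == islands.X)
    assert np.all(trace.y == 1.0)


def test_trace_grid_and_initial_state(islands):
    trace = simulate(islands, StimulusProtocol.single(), 0.5, dt=1e-4)
    assert len(trace.times) == len(trace.h) == len(trace.x) == len(trace.y)
    assert np.allclose(np.diff(trace.times), 1e-4)
    # stimulus at t=0: recorded state is post-reset from (0, X, 1)
    assert trace.h[0] == islands.H and trace.x[0] == islands.X and trace.y[0] == 1.0


def test_deterministic_and_seeded_reproducibility(islands):
    proto = StimulusProtocol.paired(1.0)
    a = simulate(islands, proto, 2.0)
    b = simulate(islands, proto, 2.0)
    assert np.array_equal(a.h, b.h) and np.array_equal(a.y, b.y)
    s1 = simulate_stochastic(islands, proto, 2.0, seed=42)
    s2 = simulate_stochastic(islands, proto, 2.0, seed=42)
    s3 = simulate_stochastic(islands, proto, 2.0, seed=43)
    assert np.array_equal(s1.h, s2.h)
    assert not np.array_equal(s1.h, s3.h)


def test_zero_noise_reproduces_deterministic_path(islands):
    proto = StimulusProtocol.single()
    det = simulate(islands, proto, 1.0)
    sto = simulate_stochastic(islands, proto, 1.0, seed=7, sigma=0.0)
    assert np.array_equal(det.h, sto.h)
    assert np.array_equal(det.x, sto.x)
    assert np.array_equal(det.y, sto.y)


def test_step_halving_converges(islands):
    from burstrev.bursts import reverberation_time

    proto = StimulusProtocol.single()
    d1 = reverberation_time(simulate(islands, proto, 6.0, dt=1e-4), 0.0).duration
    d2 = reverberation_time(simulate(islands, proto, 6.0, dt=5e-5), 0.0).duration
    assert abs(d2 - d1) / d1 < 0.005


def test_fixed_step_path_matches_adaptive_oracle(islands):
    p = islands

    def rhs(t, s):
        h, x, y = s
        hp = max(h, 0.0)
        return [(-h + p.J * x * y * hp) / p.tau,
                (p.X - x) / p.t_f + p.K * (1.0 - x) * hp,
                (1.0 - y) / p.t_r - p.L * x * y * hp]

    trace = simulate(p, StimulusProtocol.single(), 5.0)
    sol = solve_ivp(rhs, (0.0, 5.0), [p.H, p.X, 1.0], t_eval=trace.times,
                    rtol=1e-10, atol=1e-12, method="LSODA")
    assert np.max(np.abs(sol.y[0] - trace.h)) < 0.1


def test_h_decays_when_recurrent_drive_subcritical(islands):
    # with J*x*y < 1 throughout and no further stimulus, h+ can only shrink
    weak = islands.replace(J=0.8)
    trace = simulate(weak, StimulusProtocol.single(), 1.0)
    assert np.max(weak.J * trace.x * trace.y) < 1.0
    hp = np.maximum(trace.h, 0.0)
    assert np.all(np.diff(hp) <= 1e-12)


def test_divergent_state_raises_with_time_reached():
    # runaway regime: strong recurrence, no depletion at all
    p = ModelParams(tau=0.01, t_f=1.3, t_r=2.0, J=50.0, K=0.0, L=0.0, X=0.5, H=50.0)
    with pytest.raises(IntegrationError, match="t = "):
        simulate(p, StimulusProtocol.single(), 5.0)


def test_record_stride_subsamples_same_path(islands):
    proto = StimulusProtocol.single()
    full = simulate(islands, proto, 1.0, dt=1e-4)
    strided = simulate(islands, proto, 1.0, dt=1e-4, record_stride=10)
    assert strided.dt_record == pytest.approx(1e-3)
    assert np.array_equal(strided.h, full.h[::10])


def test_trace_csv_round_trip(tmp_path, islands):
    from burstrev.dynamics import read_trace_csv

    trace = simulate(islands, StimulusProtocol.single(), 0.1, dt=1e-3)
    path = tmp_path / "trace.csv"
    trace.to_csv(path)
    df = read_trace_csv(path)
    assert list(df.columns) == ["time", "h", "x", "y"]
    assert np.allclose(df["h"].to_numpy(), trace.h)
    assert (tmp_path / "trace.json").exists()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    tau=st.floats(0.005, 0.05),
    t_f=st.floats(0.3, 3.0),
    t_r=st.floats(0.5, 30.0),
    J=st.floats(0.0, 3.0),
    K=st.floats(0.0, 0.008),
    L=st.floats(0.002, 0.05),
    X=st.floats(0.05, 0.95),
    seed=st.integers(0, 2**31 - 1),
)
def test_box_invariance_of_x_and_y(tau, t_f, t_r, J, K, L, X, seed):
    """Trajectories started inside the unit square keep x, y in [0, 1]."""
    p = ModelParams(tau=tau, t_f=t_f, t_r=t_r, J=J, K=K, L=L, X=X, H=50.0,
                    h_T=10.0, sigma=2.0)
    trace = simulate_stochastic(p, StimulusProtocol.single(), 2.0, dt=1e-4,
                                seed=seed, record_stride=10)
    assert trace.x.min() >= -1e-12 and trace.x.max() <= 1.0 + 1e-12
    assert trace.y.min() >= -1e-12 and trace.y.max() <= 1.0 + 1e-12
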