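"""Surrogate datasets: per-trial durations, spike rasters, and the
raster -> rate -> duration measurement loop."""
import numpy as np
import pytest

from burstrev.bursts import paired_pulse, reverberation_time
from burstrev.dynamics import simulate
from burstrev.params import StimulusProtocol
from burstrev.synth import (
    SyntheticDataset,
    generate_paired_conditions,
    generate_spike_surrogate,
    generate_trials,
    rate_from_raster,
    raster_burst_duration,
)


def test_dataset_files_are_byte_identical_for_same_seed(tmp_path, islands):
    proto = StimulusProtocol.paired(5.0)
    for run in ("a", "b"):
        ds = generate_trials(islands, proto, 6, sigma=2.0, master_seed=21)
        ds.to_csv(tmp_path / f"{run}.csv")
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
    assert (tmp_path / "a.provenance.json").read_bytes() == \
        (tmp_path / "b.provenance.json").read_bytes()


def test_noiseless_trial_equals_deterministic_run(islands):
    proto = StimulusProtocol.paired(5.0)
    ds = generate_trials(islands, proto, 1, sigma=0.0, measurement_sd=0.0,
                         master_seed=5)
    det = paired_pulse(islands, 5.0)
    assert ds.trials["duration_0"].iloc[0] == det.first.duration
    assert ds.trials["duration_1"].iloc[0] == det.second.duration
    assert bool(ds.trials["ok"].iloc[0])


def test_sample_mean_near_ensemble_mean(islands):
    proto = StimulusProtocol.paired(5.0)
    ds = generate_trials(islands, proto, 20, sigma=2.0, measurement_sd=0.0,
                         master_seed=8)
    d0 = ds.durations(0)
    # 3 sd-of-mean band around the ~2 s deterministic duration
    assert abs(d0.mean() - 2.04) < 3.0 * max(d0.std(ddof=1), 1e-3) / np.sqrt(len(d0)) + 0.05


def test_measurement_jitter_changes_values_but_never_signs(islands):
    proto = StimulusProtocol.paired(5.0)
    clean = generate_trials(islands, proto, 8, sigma=2.0, measurement_sd=0.0,
                            master_seed=13)
    noisy = generate_trials(islands, proto, 8, sigma=2.0, measurement_sd=0.1,
                            master_seed=13)
    assert not np.allclose(clean.durations(0), noisy.durations(0))
    assert np.all(noisy.durations(0) >= 0.0)
    # same child seeds: simulated (pre-jitter) bursts are shared
    assert clean.trials["seed"].tolist() == noisy.trials["seed"].tolist()


def test_dataset_round_trip(tmp_path, islands):
    ds = generate_trials(islands, StimulusProtocol.paired(5.0), 3, sigma=2.0,
                         master_seed=2)
    ds.to_csv(tmp_path / "trials.csv")
    back = SyntheticDataset.from_csv(tmp_path / "trials.csv")
    assert back.trials["duration_0"].tolist() == pytest.approx(
        ds.trials["duration_0"].tolist())
    assert back.provenance["master_seed"] == 2


def test_paired_conditions_cover_requested_intervals(islands):
    ds = generate_paired_conditions(islands, 2, intervals=(5.0, 35.0),
                                    sigma=2.0, master_seed=4)
    assert set(ds.trials["condition"]) == {"interval-5s", "interval-35s"}
    assert len(ds.trials) == 4


def test_silent_trace_gives_empty_raster(islands):
    trace = simulate(islands, StimulusProtocol.from_iterable(()), 1.0, dt=1e-3)
    raster = generate_spike_surrogate(trace, n_units=20, seed=1)
    assert len(raster) == 0
    t, r = rate_from_raster(raster, n_units=20, bin=0.05, t_end=1.0)
    assert np.all(r == 0.0)


def test_constant_rate_is_recovered_by_binning(islands):
    # 1 s of h = 50 Hz across 100 units ~ Poisson counting at 5000 expected spikes
    trace = simulate(islands, StimulusProtocol.from_iterable(()), 1.0, dt=1e-3)
    trace = trace.__class__(times=trace.times, h=np.full_like(trace.h, 50.0),
                            x=trace.x, y=trace.y, protocol=trace.protocol,
                            params=trace.params, dt=trace.dt)
    raster = generate_spike_surrogate(trace, n_units=100, seed=3)
    _, rate = rate_from_raster(raster, n_units=100, bin=0.05, t_end=1.0)
    assert rate.mean() == pytest.approx(50.0, rel=0.1)


def test_raster_rate_and_duration_reconstruction(islands):
    trace = simulate(islands, StimulusProtocol.single(), 10.0, record_stride=10)
    true_T = reverberation_time(trace, 0.0).duration
    errs = {}
    for n_units in (50, 200):
        raster = generate_spike_surrogate(trace, n_units, seed=17)
        t, r = rate_from_raster(raster, n_units, bin=0.05, smooth=0.1, t_end=10.0)
        href = np.interp(t, trace.times, np.maximum(trace.h, 0.0))
        errs[n_units] = np.sqrt(np.sum((r - href) ** 2) / np.sum(href ** 2))
    assert errs[50] < 0.15
    assert errs[200] < errs[50]          # more units, better reconstruction
    d, term = raster_burst_duration(
        generate_spike_surrogate(trace, 100, seed=17), 100, 0.0, t_end=10.0)
    assert term
    assert abs(d - true_T) / true_T < 0.2


def test_rate_estimator_is_deterministic(islands):
    trace = simulate(islands, StimulusProtocol.single(), 4.0, record_stride=10)
    raster = generate_spike_surrogate(trace, 30, seed=9)
    a = rate_from_raster(raster, 30, bin=0.05, smooth=0.1, t_end=4.0)
    b = rate_from_raster(raster, 30, bin=0.05, smooth=0.1, t_end=4.0)
    assert np.array_equal(a[1], b[1])
    raster2 = generate_spike_surrogate(trace, 30, seed=9)
    assert raster.equals(raster2)


def test_generator_input_validation(islands):
    proto = StimulusProtocol.paired(5.0)
    with pytest.raises(ValueError):
        generate_trials(islands, proto, 0)
    with pytest.raises(ValueError):
        generate_trials(islands, proto, 2, measurement_sd=-0.1)
    trace = simulate(islands, StimulusProtocol.single(), 0.5, dt=1e-3)
    with pytest.raises(ValueError):
        generate_spike_surrogate(trace, 0, seed=1)
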