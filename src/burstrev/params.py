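"""Model parameters, stimulation protocols, and packaged presets.

The mean-field network is described by eight constants (relaxation time tau,
facilitation/depression recovery times t_f and t_r, connectivity J, rate
constants K and L, facilitation steady state X, stimulus rate H) plus the
burst-termination threshold h_T and the firing-rate noise amplitude sigma.

Two presets are shipped: ``islands`` (hippocampal micro-culture networks of
5-30 neurons) and ``slices`` (acute hippocampal slice). They differ in the
depression recovery time (2 s vs 20 s), depletion rate L and connectivity J.
"""
from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "ModelParams",
    "StimulusProtocol",
    "preset",
    "preset_names",
    "ISLANDS",
    "SLICES",
]

_FIELDS = ("tau", "t_f", "t_r", "J", "K", "L", "X", "H", "h_T", "sigma")


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Constants of the depression-facilitation network model.

    Units: times in seconds, rates in Hz.  ``K`` and ``L`` multiply the
    rectified firing rate h+ (Hz) to give per-second rates of facilitation
    build-up and vesicle depletion respectively, so their numeric values are
    used with h in Hz and t in s.
    """

    tau: float    # firing-rate relaxation time, s
    t_f: float    # facilitation recovery time, s
    t_r: float    # depression (vesicle pool) recovery time, s
    J: float      # mean synaptic connectivity, dimensionless
    K: float      # facilitation rate constant
    L: float      # depletion rate constant
    X: float      # facilitation steady state, in (0, 1)
    H: float      # stimulus-imposed firing rate, Hz
    h_T: float = 10.0   # burst-termination threshold, Hz
    sigma: float = 0.0  # firing-rate noise amplitude, Hz

    def __post_init__(self) -> None:
        for name in ("tau", "t_f", "t_r"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.X < 1.0:
            raise ValueError(f"X must lie in (0, 1), got {self.X}")
        if not 0.0 < self.h_T < self.H:
            raise ValueError(f"need 0 < h_T < H, got h_T={self.h_T}, H={self.H}")
        if self.J < 0:
            raise ValueError(f"J must be non-negative, got {self.J}")
        if self.K < 0 or self.L < 0:
            raise ValueError(f"K and L must be non-negative, got K={self.K}, L={self.L}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in _FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - set(_FIELDS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Load parameters from a YAML or JSON config file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclasses.dataclass(frozen=True)
class StimulusProtocol:
    """An ordered schedule of stimulation times (seconds).

    Each stimulus instantaneously resets the population firing rate to H,
    modelling a population spike that recruits the whole network.
    """

    stim_times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.stim_times)
        object.__setattr__(self, "stim_times", times)
        if any(t < 0 for t in times):
            raise ValueError("stimulus times must be non-negative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("stimulus times must be strictly increasing")

    @classmethod
    def single(cls, t: float = 0.0) -> "StimulusProtocol":
        return cls((t,))

    @classmethod
    def paired(cls, interval: float, first: float = 0.0) -> "StimulusProtocol":
        if interval <= 0:
            raise ValueError("interval must be positive")
        return cls((first, first + interval))

    @classmethod
    def from_iterable(cls, times: Iterable[float]) -> "StimulusProtocol":
        return cls(tuple(times))


def _load_preset(name: str) -> ModelParams:
    ref = resources.files("burstrev").joinpath(f"presets/{name}.yaml")
    return ModelParams.from_dict(yaml.safe_load(ref.read_text()))


def preset_names() -> tuple[str, ...]:
    return ("islands", "slices")


def preset(name: str) -> ModelParams:
    """Return a packaged parameter set by name ('islands' or 'slices')."""
    if name not in preset_names():
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}")
    return _load_preset(name)


ISLANDS = _load_preset("islands")
SLICES = _load_preset("slices")
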