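"""Entorhinal Poisson drive with an onset ramp.

Each entorhinal axon fires as an independent inhomogeneous Poisson process
whose rate ramps linearly from 0 to the mean rate (default 3.0 Hz) over the
first second, then stays constant.  The ramp avoids the strong oscillatory
transient a step-function input evokes in the network.

Spike times are generated by thinning a homogeneous process at the peak
rate, with a counter-based substream per (seed, population, cell), so trains
are independent across cells and invariant to generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class StimulusSpec:
    rate_hz: float = 3.0
    ramp_ms: float = 1000.0
    duration_ms: float = 4000.0
    seed: int = 0

    def __post_init__(self):
        if self.rate_hz < 0:
            raise ConfigurationError("rate must be >= 0")
        if not (0 <= self.ramp_ms <= self.duration_ms):
            raise ConfigurationError("require 0 <= ramp <= duration")

    def rate_at(self, t_ms):
        """Instantaneous rate lambda(t) in Hz."""
        t = np.asarray(t_ms, dtype=float)
        if self.ramp_ms == 0:
            return np.full_like(t, self.rate_hz)
        return self.rate_hz * np.minimum(t / self.ramp_ms, 1.0)

    @property
    def expected_count(self) -> float:
        """Integral of lambda(t) over the stimulus duration."""
        ramp_s = self.ramp_ms / 1000.0
        rest_s = (self.duration_ms - self.ramp_ms) / 1000.0
        return self.rate_hz * (0.5 * ramp_s + rest_s)


def _cell_rng(spec: StimulusSpec, population: str, cell_id: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=spec.seed,
        spawn_key=(zlib.crc32(population.encode()) & 0x7FFFFFFF, int(cell_id)),
    )
    return np.random.default_rng(ss)


def poisson_ramp_train(
    spec: StimulusSpec, cell_id: int, population: str = "EC"
) -> np.ndarray:
    """Spike times (ms, sorted) for one cell, by thinning."""
    if spec.rate_hz == 0:
        return np.empty(0)
    rng = _cell_rng(spec, population, cell_id)
    # Homogeneous candidates at the peak rate over the whole window.
    lam_ms = spec.rate_hz / 1000.0  # events per ms
    n_exp = lam_ms * spec.duration_ms
    n_cand = rng.poisson(n_exp)
    t = np.sort(rng.uniform(0.0, spec.duration_ms, size=n_cand))
    keep = rng.uniform(size=n_cand) * spec.rate_hz <= spec.rate_at(t)
    return t[keep]


def population_trains(
    spec: StimulusSpec, n_cells: int, population: str = "EC"
) -> list[np.ndarray]:
    """Independent trains for cells ``0..n_cells-1``."""
    return [poisson_ramp_train(spec, i, population) for i in range(n_cells)]
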