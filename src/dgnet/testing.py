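"""Deterministic synthetic fixtures for tests and operator validation.

Small rasters with analytically known structure (global synchrony, injected
sinusoidal rate modulation, offset train pairs) used to validate the
analysis operators independently of the simulator.
"""

from __future__ import annotations

import numpy as np

from .engine import POP_CODES, SpikeRaster


def raster_from_trains(
    trains: list[np.ndarray],
    positions_mm: np.ndarray,
    duration_ms: float,
    population: str = "GC",
) -> SpikeRaster:
    """Assemble a raster from per-cell spike-time arrays."""
    code = POP_CODES[population]
    cells = np.concatenate(
        [np.full(len(tr), i, dtype=np.int32) for i, tr in enumerate(trains)]
    ) if trains else np.empty(0, np.int32)
    times = np.concatenate([np.asarray(tr, float) for tr in trains]) if trains else np.empty(0)
    return SpikeRaster(
        population=np.full(len(times), code, dtype=np.int8),
        cell_id=cells,
        position_mm=np.asarray(positions_mm, float)[cells] if len(times) else np.empty(0),
        t_ms=times,
        duration_ms=duration_ms,
    )


def synchronous_raster(
    n_cells: int = 50,
    burst_period_ms: float = 100.0,
    duration_ms: float = 2000.0,
    axis_length_mm: float = 10.0,
    jitter_ms: float = 1.0,
    seed: int = 0,
) -> SpikeRaster:
    """Every cell fires in every population burst (global synchrony limit)."""
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0, axis_length_mm, n_cells)
    bursts = np.arange(burst_period_ms / 2, duration_ms, burst_period_ms)
    trains = [
        np.sort(bursts + rng.normal(0, jitter_ms, len(bursts)))
        for _ in range(n_cells)
    ]
    trains = [tr[(tr >= 0) & (tr < duration_ms)] for tr in trains]
    return raster_from_trains(trains, positions, duration_ms)


def sinusoidal_raster(
    n_cells: int = 100,
    f0_hz: float = 18.0,
    mean_rate_hz: float = 20.0,
    mod_depth: float = 0.9,
    duration_ms: float = 4000.0,
    axis_length_mm: float = 10.0,
    seed: int = 0,
) -> SpikeRaster:
    """Inhomogeneous Poisson trains with rate modulated at ``f0_hz``."""
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0, axis_length_mm, n_cells)
    lam_max = mean_rate_hz * (1 + mod_depth) / 1000.0
    trains = []
    for _ in range(n_cells):
        n = rng.poisson(lam_max * duration_ms)
        t = np.sort(rng.uniform(0, duration_ms, n))
        lam = mean_rate_hz / 1000.0 * (
            1 + mod_depth * np.sin(2 * np.pi * f0_hz * t / 1000.0)
        )
        trains.append(t[rng.uniform(size=n) * lam_max <= lam])
    return raster_from_trains(trains, positions, duration_ms)


def offset_pair_raster(
    offset_ms: float = 15.0,
    distance_mm: float = 0.3,
    period_ms: float = 50.0,
    duration_ms: float = 2000.0,
    jitter_ms: float = 0.5,
    seed: int = 0,
) -> SpikeRaster:
    """Two cells: identical trains, the second delayed by ``offset_ms``."""
    rng = np.random.default_rng(seed)
    base = np.arange(10.0, duration_ms - offset_ms - 10.0, period_ms)
    base = base + rng.normal(0, jitter_ms, len(base))
    trains = [np.sort(base), np.sort(base + offset_ms)]
    return raster_from_trains(trains, np.array([1.0, 1.0 + distance_mm]), duration_ms)


def poisson_raster(
    n_cells: int = 100,
    rate_hz: float = 5.0,
    duration_ms: float = 2000.0,
    axis_length_mm: float = 10.0,
    seed: int = 0,
) -> SpikeRaster:
    """Independent homogeneous Poisson trains (no structure)."""
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0, axis_length_mm, n_cells)
    trains = []
    for _ in range(n_cells):
        n = rng.poisson(rate_hz * duration_ms / 1000.0)
        trains.append(np.sort(rng.uniform(0, duration_ms, n)))
    return raster_from_trains(trains, positions, duration_ms)
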