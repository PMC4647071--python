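"""Population sizes and cell placement along the dentate axes.

The model places five populations -- medial and lateral entorhinal cortex
afferents (MEC, LEC), granule cells (GC), basket cells (BC) and mossy cells
(MC) -- along a one-dimensional septo-temporal axis (default 10 mm) plus a
normalized transverse coordinate.  Full-scale counts follow rat anatomy:
one million granule cells, 112k entorhinal axons (split evenly between MEC
and LEC), 6k basket cells and 30k mossy cells.  Reduced-scale models keep
the same ratios, so emergent results can be checked at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

POPULATIONS = ("MEC", "LEC", "GC", "BC", "MC")

#: Full-scale (1:1, one hemisphere of an adult rat) cell counts.
FULL_SCALE_COUNTS = {
    "MEC": 56_000,
    "LEC": 56_000,
    "GC": 1_000_000,
    "BC": 6_000,
    "MC": 30_000,
}


@dataclass(frozen=True)
class ScaleSpec:
    """Model scale and geometry.

    Parameters
    ----------
    scale_factor:
        Fraction of full scale in (0, 1]; population counts are
        ``round(full_count * scale_factor)``.
    axis_length_mm:
        Septo-temporal extent of the dentate gyrus in mm.
    transverse_extent:
        Normalized transverse extent (cells get a coordinate in [0, 1]).
    """

    scale_factor: float = 1.0
    axis_length_mm: float = 10.0
    transverse_extent: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.scale_factor <= 1.0):
            raise ConfigurationError(
                f"scale_factor must be in (0, 1], got {self.scale_factor}"
            )
        if self.axis_length_mm <= 0:
            raise ConfigurationError("axis_length_mm must be positive")


@dataclass
class PopulationLayout:
    """Realized cell counts and positions.

    ``positions[pop]`` is an ``(n, 2)`` array of (septo-temporal mm,
    transverse fraction) coordinates.  MEC/LEC positions live on an
    entorhinal band axis normalized to the same septo-temporal range they
    map onto (see :mod:`dgnet.connectivity`).
    """

    scale: ScaleSpec
    counts: dict[str, int]
    positions: dict[str, np.ndarray]
    seed: int

    def __getitem__(self, pop: str) -> np.ndarray:
        return self.positions[pop]

    def septotemporal(self, pop: str) -> np.ndarray:
        return self.positions[pop][:, 0]

    @property
    def total_cells(self) -> int:
        return sum(self.counts.values())


def scaled_counts(full_counts: dict[str, int], scale_factor: float) -> dict[str, int]:
    """Proportionally scaled per-population counts (rounded, minimum 1)."""
    out = {}
    for pop, full in full_counts.items():
        if full <= 0:
            raise ConfigurationError(
                f"population {pop!r} has non-positive full-scale count {full}"
            )
        n = int(round(full * scale_factor))
        out[pop] = max(n, 1)
    return out


def build_layout(
    scale: ScaleSpec,
    counts_config: dict[str, int] | None = None,
    seed: int = 0,
) -> PopulationLayout:
    """Place every population uniformly at random along the dentate axes.

    Positions are i.i.d. uniform over [0, axis_length] x [0, transverse
    extent]; the layout is bit-identical for a given seed.  Each population
    draws from its own RNG substream so adding a population does not perturb
    the others.
    """
    full = dict(FULL_SCALE_COUNTS)
    if counts_config:
        unknown = set(counts_config) - set(POPULATIONS)
        if unknown:
            raise ConfigurationError(f"unknown population(s): {sorted(unknown)}")
        full.update(counts_config)
    counts = scaled_counts(full, scale.scale_factor)

    ss = np.random.SeedSequence(entropy=seed, spawn_key=(ord("L"),))
    children = ss.spawn(len(POPULATIONS))
    positions = {}
    for pop, child in zip(POPULATIONS, children):
        rng = np.random.default_rng(child)
        n = counts[pop]
        pos = np.empty((n, 2))
        pos[:, 0] = rng.uniform(0.0, scale.axis_length_mm, size=n)
        pos[:, 1] = rng.uniform(0.0, scale.transverse_extent, size=n)
        positions[pop] = pos
    return PopulationLayout(scale=scale, counts=counts, positions=positions, seed=seed)


def desk_scale_preset() -> tuple[ScaleSpec, dict[str, int]]:
    """Ratio-preserving 1:100 reduction of the full-scale network.

    10,000 GC, 1,120 EC-origin axons, 60 BC and 300 MC -- the default test
    scale for interactive work.
    """
    return ScaleSpec(scale_factor=0.01), dict(FULL_SCALE_COUNTS)


def compact_scale_preset() -> tuple[ScaleSpec, dict[str, int]]:
    """Ratio-preserving 1:500 reduction (2,000 GC, 224 EC, 12 BC, 60 MC).

    Useful for fast structural work (wiring statistics, cluster formation,
    activity totals).  Coherent population rhythms need the desk preset or
    larger: with only 12 basket cells, inhibition arrives too sparsely to
    synchronize the network.
    """
    return ScaleSpec(scale_factor=0.002), dict(FULL_SCALE_COUNTS)
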