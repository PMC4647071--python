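"""Exception types used across the package."""


class DgnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DgnetError):
    """A config value is missing, malformed, or inconsistent."""


class WiringError(DgnetError):
    """Connectivity could not be realized (e.g., empty presynaptic pool)."""


class NumericalInstabilityError(DgnetError):
    """Membrane integration produced NaN/inf state."""

    def __init__(self, population: str, cell_id: int, time_ms: float):
        self.population = population
        self.cell_id = cell_id
        self.time_ms = time_ms
        super().__init__(
            f"non-finite membrane state in {population} cell {cell_id} "
            f"at t={time_ms:.2f} ms"
        )


class ResourceError(DgnetError):
    """A preallocated buffer (spike store / event queue) overflowed."""
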