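"""Double-exponential conductance synapses.

Every connection in the model is either AMPA-like (excitatory, E_rev = 0 mV)
or GABA_A-like (inhibitory, E_rev = -75 mV for the basket-to-granule
pathway).  A presynaptic event at t = 0 opens a conductance

    g(t) = w * N * (exp(-t / tau_fall) - exp(-t / tau_rise)),

where N normalizes the peak so that max_t g(t) = w.  Events sum linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .params import PATHWAYS, load_synapse_table


@dataclass(frozen=True)
class SynapseParams:
    """Peak conductance, kinetics and reversal potential of one pathway."""

    weight: float        # peak conductance (uS convention)
    tau_rise: float      # ms
    tau_fall: float      # ms
    e_rev: float         # mV

    def __post_init__(self):
        if not (self.tau_fall > self.tau_rise > 0):
            raise ConfigurationError(
                f"require tau_fall > tau_rise > 0, got rise={self.tau_rise}, "
                f"fall={self.tau_fall}"
            )
        if self.weight < 0:
            raise ConfigurationError("synaptic weight must be >= 0")

    @property
    def t_peak(self) -> float:
        """Time to peak of the conductance waveform (ms)."""
        tr, tf = self.tau_rise, self.tau_fall
        return tr * tf / (tf - tr) * math.log(tf / tr)

    @property
    def peak_norm(self) -> float:
        """N such that the peak of N*(exp(-t/tf) - exp(-t/tr)) is 1."""
        tp = self.t_peak
        return 1.0 / (math.exp(-tp / self.tau_fall) - math.exp(-tp / self.tau_rise))


def conductance_waveform(t, p: SynapseParams):
    """Conductance at time ``t`` (ms) after a single event.

    Vectorized over ``t``; negative times return 0 (event not yet arrived).
    """
    t = np.asarray(t, dtype=float)
    g = p.weight * p.peak_norm * (np.exp(-t / p.tau_fall) - np.exp(-t / p.tau_rise))
    return np.where(t >= 0, g, 0.0)


def synaptic_current(g, v_post, e_rev):
    """I = g * (V - E_rev); positive current hyperpolarizes."""
    return np.asarray(g) * (np.asarray(v_post) - e_rev)


def pathway_defaults() -> dict[str, SynapseParams]:
    """The nine pathway parameter sets exactly as tabulated."""
    table = load_synapse_table()
    return {
        pw: SynapseParams(
            weight=row["weight"],
            tau_rise=row["tau_rise"],
            tau_fall=row["tau_fall"],
            e_rev=row["e_rev"],
        )
        for pw, row in table.items()
    }


def convergence_ranges() -> dict[str, tuple[int, int]]:
    """Per-pathway [min, max] synapse counts per postsynaptic cell."""
    table = load_synapse_table()
    return {pw: table[pw]["convergence"] for pw in PATHWAYS}
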