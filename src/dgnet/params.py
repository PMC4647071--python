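"""Parameter loading.

All quantitative defaults live in three YAML files under ``dgnet/data``:

* ``synapses.yaml`` -- per-pathway synaptic parameters (convergence ranges,
  weights, double-exponential kinetics, reversal potentials), with field
  names mirroring the synaptic parameter table.
* ``biophysics.yaml`` -- passive properties and channel densities per cell
  type, keyed by the biophysics table row names.
* ``network.yaml`` -- geometry, conduction, terminal fields, laminar
  targets, pathway gains and the entorhinal stimulus.

Users can load an alternate file with the ``path=`` arguments.
"""

from __future__ import annotations

import copy
import functools
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: Internal pathway keys, in engine order.
PATHWAYS = (
    "MEC_GC",
    "LEC_GC",
    "BC_GC",
    "MC_GC",
    "GC_BC",
    "MEC_BC",
    "LEC_BC",
    "MC_BC",
    "GC_MC",
)


def _table_key(pathway: str) -> str:
    pre, post = pathway.split("_")
    return f"{pre} to {post}"


def _read_yaml(name: str, path: str | Path | None):
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    ref = resources.files("dgnet.data") / name
    with ref.open() as fh:
        return yaml.safe_load(fh)


@functools.lru_cache(maxsize=None)
def _synapse_yaml_default():
    return _read_yaml("synapses.yaml", None)


def load_synapse_table(path: str | Path | None = None) -> dict:
    """Raw synaptic parameter table keyed by internal pathway names."""
    raw = copy.deepcopy(_synapse_yaml_default() if path is None else _read_yaml("synapses.yaml", path))
    table = {}
    for pw in PATHWAYS:
        key = _table_key(pw)
        try:
            table[pw] = {
                "convergence": tuple(raw["Synapse counts"][key]),
                "weight": float(raw["Synaptic weights"][key]),
                "tau_rise": float(raw["EPSP/IPSP rise time (ms)"][key]),
                "tau_fall": float(raw["EPSP/IPSP fall time (ms)"][key]),
                "e_rev": float(raw["Reversal potentials (mV)"][key]),
            }
        except KeyError as exc:
            raise ConfigurationError(f"synapse table missing {key!r}: {exc}") from exc
    return table


@functools.lru_cache(maxsize=None)
def _biophysics_default():
    return _read_yaml("biophysics.yaml", None)


def load_biophysics(path: str | Path | None = None) -> dict:
    """Cell-type biophysics blocks (granule_cell, mossy_cell, basket_cell)."""
    raw = _biophysics_default() if path is None else _read_yaml("biophysics.yaml", path)
    return copy.deepcopy(raw)


@functools.lru_cache(maxsize=None)
def _network_default():
    return _read_yaml("network.yaml", None)


def load_network_config(path: str | Path | None = None) -> dict:
    """Network-level defaults (geometry, fields, targets, gains, stimulus)."""
    raw = _network_default() if path is None else _read_yaml("network.yaml", path)
    return copy.deepcopy(raw)
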