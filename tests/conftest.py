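import numpy as np
import pytest

from dgnet.connectivity import build_connectivity
from dgnet.populations import ScaleSpec, build_layout

TINY_COUNTS = {"MEC": 30_000, "LEC": 30_000, "GC": 500_000, "BC": 12_000, "MC": 15_000}


@pytest.fixture(scope="session")
def tiny_layout():
    """~500 GC / 60 EC / 12 BC / 15 MC; fast to wire and simulate."""
    return build_layout(ScaleSpec(scale_factor=0.001), TINY_COUNTS, seed=7)


@pytest.fixture(scope="session")
def tiny_network(tiny_layout):
    graph = build_connectivity(tiny_layout, include_mc=True, seed=7)
    return tiny_layout, graph
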