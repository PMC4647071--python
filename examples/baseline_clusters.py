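"""Baseline network: spatio-temporal clusters from random entorhinal input.

Runs the no-mossy-cell network at the desk scale (10k granule cells) under
3 Hz ramped Poisson entorhinal drive and quantifies the emergent clusters
with the spatio-temporal correlation (STC): granule cells within a
millimeter of each other are co-active within tens of milliseconds even
though the input is Poisson.  Takes a couple of minutes on one core.
"""

from dgnet import compute_stc, simulate, stc_extent
from dgnet.experiments import build_network, ANALYSIS_WINDOW_MS
from dgnet.stimulus import StimulusSpec

layout, graph = build_network(scale="desk", include_mc=False, seed=0)
print(f"network: {layout.counts}")
res = simulate(layout, graph, stimulus=StimulusSpec(seed=0),
               duration_ms=4000.0, seed=0)
print(f"spikes: GC={res.counts['GC']}, BC={res.counts['BC']}, "
      f"EC={res.counts['MEC'] + res.counts['LEC']} (4 s)")

stc = compute_stc(res.raster, "GC", n_sample=800, seed=0,
                  window=ANALYSIS_WINDOW_MS,
                  positions=layout.septotemporal("GC"))
ext = stc_extent(stc)
print(f"STC spatial extent  = {ext['spatial_mm']:.2f} mm")
print(f"STC temporal extent = {ext['temporal_ms']:.1f} ms")
print("\nThe correlation stays above 1/e of its zero-point value over a "
      "sub-millimeter neighborhood and a few time bins: granule cell "
      "activity is organized in local spatio-temporal clusters set by the "
      "perforant-path terminal fields, not uniform noise.")
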