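# dgnet — a spiking network model of the rat dentate gyrus

`dgnet` is a conductance-based simulator of the dentate gyrus circuit:
granule cells (GC) driven by Poisson-firing medial/lateral entorhinal
cortex afferents (MEC/LEC, the perforant path), basket cells (BC) providing
feedforward (EC→BC→GC) and feedback (GC→BC→GC) perisomatic GABA_A
inhibition, and mossy cells (MC) forming the excitatory associational loop
(direct MC→GC excitation plus disynaptic MC→BC→GC inhibition).  It is
aimed at computational neuroscientists studying how interneuron and
associational circuitry shape the spatio-temporal dynamics of granule cell
output.

The model reproduces, at reduced scale, the circuit's emergent phenomena:

* **spatio-temporal clusters** — local (~1 mm, tens of ms) patches of
  co-active granule cells despite purely Poisson input, quantified by the
  spatio-temporal correlation (STC): the mean pairwise Pearson
  cross-correlation of 5 ms-binned spike trains, averaged in 0.05 mm
  distance bins;
* **feedback-inhibition rhythmicity** — strengthening BC→GC introduces a
  narrow ~18 Hz population oscillation (read from the mean spike-density
  DFT: spike counts on a 0.05 mm × 8 ms grid, magnitude DFT per spatial
  row, averaged over rows), which stronger perforant-path drive speeds up
  toward ~32 Hz;
* **feedforward gain control** — scaling EC→BC divides total granule cell
  output many-fold without inducing rhythm;
* **associational synchrony and rebalancing** — literature-strength MC→GC
  weights lock the network into ~10 Hz global synchrony; the rebalanced
  weights (fit to a paired commissural/perforant-path activation protocol)
  dissolve it into clusters while raising total output above the
  mossy-cell-free baseline.

Cell models: granule cells are reduced 5-region cables (soma, granule cell
layer, inner/middle/outer molecular-layer thirds) carrying the tabulated
laminar channel densities (Na, fast/slow delayed-rectifier K, A-type K,
L/N/T-type Ca, SK, BK); basket and mossy cells are single-compartment.
Synapses are peak-normalized double-exponential conductances
g(t) = w·N·(e^(−t/τ_fall) − e^(−t/τ_rise)); axons are conduction delays
(distance / 0.25 m s⁻¹ + 0.8 ms).  Connectivity is probabilistic and
topographic: Gaussian axon terminal fields along the 10 mm septo-temporal
axis with tabulated convergence ranges, laminar targeting (MEC→middle
third, LEC→outer third, MC→inner third, BC→soma), and a position-dependent
mossy-cell field (septal cells project over ~2/3 of the axis, temporal
cells ~1/3).  The integration kernel (exponential Euler, dt = 0.1 ms,
tabulated channel kinetics, ring-buffer event queues) is numba-compiled
and runs a 4-s, 10,000-granule-cell simulation in about a minute on one
core.  See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```bash
python examples/single_cell_properties.py
```

prints the measured passive properties of the three cell models:

```
granule cell  RMP =   -75.35 mV   Rin =   192.2 MOhm   tau_m =  28.8 ms
basket cell   RMP =   -64.85 mV   Rin =   142.3 MOhm   tau_m =   7.1 ms
mossy cell    RMP =   -64.94 mV   Rin =    53.9 MOhm   tau_m =  61.0 ms
```

The granule cell rests at its tabulated −75 mV with a ~30 ms membrane time
constant and ~190 MΩ input resistance; these passive values anchor network
excitability.  The other examples run the network itself:

* `examples/baseline_clusters.py` — baseline clusters and their STC extents;
* `examples/inhibition_rhythm.py` — the 18 Hz feedback rhythm, its absence
  at baseline, and the drive-induced shift toward 32 Hz;
* `examples/associational_loop.py` — mossy-cell synchrony vs. the
  rebalanced regime;
* `examples/rebalance_fit.py` — the excitation/inhibition rebalancing fit.

A thin CLI wraps the same functionality:

```bash
dgnet simulate --scale 0.01 --seed 0 --duration-ms 4000 --out run/
dgnet analyze stc --raster run/raster.tsv --out run/stc/
dgnet experiment run --name feedback-strong --scale desk --seed 0 --out exp/
```

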