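# Model and methods

`dgnet` is a conductance-based spiking network model of the rat dentate
gyrus: granule cells (GC) driven by medial and lateral entorhinal cortex
(MEC/LEC) afferents, with basket cells (BC) supplying feedforward
(EC-driven) and feedback (GC-driven) perisomatic GABA_A inhibition, and
mossy cells (MC) forming the excitatory associational loop (direct MC->GC
excitation in the inner molecular layer plus disynaptic MC->BC->GC
inhibition).  This note documents the model's assumptions, parameters,
numerical choices, and the deliberate deviations and limitations a user
should know about.

## Populations and geometry

Cells live on a one-dimensional septo-temporal axis (default 10 mm, chosen
consistent with a rat dentate in which associational terminal fields span
up to ~7.5 mm) plus a normalized transverse coordinate that enters only
into within-network distances, not connection probabilities.  Full-scale
counts are 1,000,000 GC, 112,000 EC afferents (split evenly MEC/LEC -- the
split is not separately constrained), 6,000 BC, and 30,000 MC.  The mossy
cell total is not fixed by the reference tables; 30,000 is standard rat
anatomy and is configurable.  Placement is uniform i.i.d. per population
(density statistics are what matter; no lattice structure is implied).

Two reduced presets ship with the package:

* **desk** (1:100): 10,000 GC, 1,120 EC, 60 BC, 300 MC -- the default
  interactive scale.
* **compact** (1:500): 2,000 GC, 224 EC, 12 BC, 60 MC -- used by some
  bundled reproduction scripts where a smaller network suffices.

Emergent-regime results quoted in the README were obtained at the desk
scale; the acceptance script states the scale it uses for each quantity.

## Cell models

**Granule cell.**  The >200-compartment morphologies of the reference full-scale model
are reduced to five cable-connected regions -- soma, granule-cell-layer
segment, and inner/middle/outer molecular-layer thirds (each dendritic
region standing for two parallel equivalent branches) -- because every
laminar parameter in the biophysics table is specified at
third-of-molecular-layer resolution.  Channel densities (Na; slow and fast
delayed-rectifier K; A-type K; L-, N-, T-type Ca; SK; BK; leak) are taken
per region exactly from the table, including the absence of Na in the
outer third and of A-type K outside the soma.

The printed passive entries are mutually inconsistent: soma surface area
4.97E-4 cm^2 with leak 2.9E-4 S/cm^2 would give an input resistance of a
few MOhm, not the printed 185.86 MOhm.  We keep the printed leak densities
and capacitances (so tau_m = Cm/g_leak ~ 34 ms, within 15% of the printed
31 ms) and choose the compartment dimensions so that the somatic input
resistance is ~186 MOhm; the resulting cell is electrotonically compact,
so laminar synapses are visible at the soma.  Resting potential equals the
leak reversal (-75.01 mV) because every voltage-gated channel is
essentially closed at rest.

**Basket cell.**  Single compartment, fast-spiking (Na + fast delayed
rectifier + leak; tau_m ~ 7 ms, rest -65 mV).  The reference table's basket
block is not available in the transcription, so this is the package's own
minimal fast-spiking design.

**Mossy cell.**  Single compartment with the tabulated densities
(rest -64.75 mV, soma 2.51E-3 cm^2).  Spike repolarization leans on the
large tabulated BK conductance, consistent with the small delayed-rectifier
density.

**Kinetics.**  The densities table prints no gating kinetics (they were
inherited from earlier published dentate models).  We use a single
parametric family -- Boltzmann steady states with Gaussian-bump time
constants (`dgnet.cells.GATE_PARAMS`) -- with parameters chosen so that
(i) every channel is effectively closed at the tabulated resting
potentials, (ii) spike shape and threshold (~ -50 mV) are conventional,
and (iii) SK/BK activate only on spike-evoked Ca transients (Ca pool:
first-order decay to 5E-6 with tau = 10 ms; influx scaling CA_PHI chosen
so a somatic spike raises the pool by ~1E-3).  All kinetics live in one
table and can be swapped wholesale.

## Synapses

All synapses are difference-of-two-exponentials conductances, normalized
so the peak equals the tabulated weight, with linear event superposition.
AMPA-like pathways reverse at 0 mV; the BC->GC GABA_A pathway at -75 mV
(shunting at rest).  Kinetics rows missing from the table (GC->MC, MC->GC,
MC->BC) default to the MEC->GC values (1.05 / 5.75 ms).

**Weight units and pathway gains.**  The table's weights are printed
without units, and applied literally as uS they are one to two orders of
magnitude below the physiological range (e.g. a perisomatic basket synapse
of 1.09E-5 uS could never gate a ~190 MOhm granule cell against its
dendritic drive).  We therefore treat the tabulated weights as relative
conductances and multiply each pathway by a fixed gain
(`network.yaml: gains`), calibrated once during development so that
unitary and aggregate PSPs land in the physiological regime and the
network reproduces the qualitative operating regimes described for the
system (sparse clustered baseline activity; feedback-inhibition
rhythmicity; feedforward suppression; associational synchrony and its
rebalancing).  This mirrors the reference model's own re-optimization of
synaptic conductances against network-level behavior.  Experiment
multipliers (the scientific manipulations) act on top of these fixed
gains; `pathway_defaults()` always returns the printed values.

Two calibration facts are worth knowing.  First, perisomatic inhibition
only gates granule cell output once the BC->GC conductance competes with
the soma-dendrite axial coupling (~0.12 uS here), i.e. at nS-scale unitary
IPSPs; below that the dendritic drive simply holds the soma up and
inhibition barely changes totals.  Second, a reduced-scale interneuron
population (60 BCs standing in for 6,000) delivers inhibition in discrete,
infrequent packets; to preserve the spatial overlap and duty cycle of
inhibition the basket axon field is widened to 4 mm and the per-spike IPSP
amplitude enlarged.  For the same reason the feedback-strength sweep spans
multipliers {1, 10, 20, 40} of the tabulated BC->GC weight (the regime
boundary between asynchronous and rhythmic states is farther from baseline
at reduced scale than a small multiplier sweep suggests); the 40x
level is the "strong feedback" condition used by the rhythm analyses.
Since the tabulated weights are the post-rebalancing values, the
multiplier-1 mossy-cell network is the canonical rebalanced state, and the
"literature-strength" state is reached by scaling MC->GC back up (x10 by
default).

## Connectivity

Axon terminal fields are Gaussian densities along the septo-temporal axis
(sigma = extent/4, truncated at +/- extent/2), centered on the soma
(intrinsic cells) or on the topographically mapped dentate coordinate
(EC afferents; a uniform band mapping stands in for the full zonal tracer
map).  Extents: EC 1.25 mm (reported 1-1.5 mm); MC linearly interpolated
from 2/3 of the axis at the septal pole to 1/3 at the temporal pole; GC
collaterals and BC axons are local fields whose extents are package
choices (see `network.yaml`), set wide enough that the discretized
interneuron population at reduced scale preserves the spatial overlap of
inhibition that the full-scale network has.

For each postsynaptic cell a convergence count is drawn uniformly from the
tabulated range and allocated over presynaptic candidates with probability
proportional to field density at the postsynaptic position; multiple
synapses per pair are expected at reduced scale and are stored as one edge
with a synapse count.  Realized in-degrees are asserted to lie within the
tabulated ranges at build time.  GC->MC convergence is not tabulated; the
default of 400-800 reflects the thousands of mossy-fiber inputs a mossy
cell receives and makes the associational loop functional at reduced
scale.  Conduction delays are septo-temporal distance / 0.25 m/s plus a
0.8 ms synaptic latency (both configurable; velocities are unmyelinated
axon order of magnitude).

`randomize_topography` resamples presynaptic partners uniformly over the
whole population while preserving every post cell's synapse count,
removing distance structure from a pathway (used for the MC->GC topography
experiments).

## Stimulus

Each EC afferent is an independent inhomogeneous Poisson process: rate 0
ramping linearly to 3.0 Hz over the first 1,000 ms, then constant; 4 s
total.  The ramp avoids the step-input transient.  Trains are generated by
thinning with counter-based substreams keyed by (seed, population, cell),
so they are independent of generation order.

## Integration

Clock-driven, default dt = 0.1 ms.  Membrane update is exponential Euler
per compartment with staggered gating; gate steady states and per-step
decay factors are tabulated on a 0.25 mV grid.  Synaptic channels are
integrated analytically as two-state (rise/fall) kernels; presynaptic
events are queued in per-pathway ring buffers quantized at dt (delays
round to at least one step).  Entorhinal and forced-volley events are
known a priori and enter the same delivery path.  Spike detection is an
upward crossing of 0 mV at the soma with a 1 ms refractory; spike times
are recorded at the step midpoint.  The integration is deterministic given
the seed; halving dt changes subthreshold trajectories by < 1 mV (spiking
trajectories are chaotic at the network level, as for any such model).
Non-finite membrane state aborts with the cell and time; spike-store
overflow raises a resource error rather than silently dropping events.

## Analyses

* **STC**: every pairwise Pearson cross-correlation of 5 ms-binned spike
  trains in a sample of up to 10,000 cells, averaged in 0.05 mm distance
  bins (self-pairs excluded; silent cells dropped; raw-covariance mode
  available).  Cluster extents are read at the 1/e-of-peak threshold,
  contiguously from the origin, at zero lag (spatial) and minimal distance
  (temporal).
* **Spike-density spectrum**: counts on a 0.05 mm x 8 ms grid, magnitude
  DFT per spatial row with the row mean removed, averaged over rows
  (Nyquist 62.5 Hz).  `spectral_peak` reports the dominant in-band local
  maximum; "no peak" is returned when no local maximum has prominence
  above the detection threshold (calibrated on synthetic flat vs.
  rate-modulated rasters).
* **ISI histograms** pool consecutive per-cell intervals by population.

Analyses are pure functions of the raster and parameters.

## Scenarios, rebalancing, and the synthetic target curve

Named scenarios wrap the principal manipulations (feedback sweep 1x-4x,
feedforward sweep, perforant-path drive sweep, mossy-cell network with
literature-strength vs. rebalanced weights, randomized MC topography,
single-pathway perturbations on the rebalanced base).  The rebalancing
procedure runs the paired-activation protocol -- a synchronous volley
through the MC efferents preceding a perforant-path test volley at
increasing delays, GC response expressed as % of the unconditioned
control -- and fits (BC->GC up, MC->GC down) by multiplicative coordinate
descent to a target curve.  The experimental target curve is not available
in tabulated form; the packaged default
(`data/rebalance_target_synthetic.yaml`) is a clearly marked synthetic
stand-in with the qualitative shape of the in-vivo findings (strong
inhibition at short delays recovering toward control).  The commissural
system is represented by the forced MC volley because the model is
unilateral.

## What the synthetic conditions do and do not show

The Poisson-drive generator and reduced scales reproduce the *mechanisms*
-- shared-input clusters, feedback-loop rhythmogenesis, feedforward gain
control, associational synchrony -- at a few hundred to ten thousand
cells.  Quantities that depend on absolute population size (total spike
counts, the depth of spectral peaks, cluster counts) do not transfer
numerically from the million-cell reference model, and the discreteness of a
60-cell interneuron population makes reduced-scale rhythms noisier and
more intermittent than the full-scale figures suggest.  Passing tests
therefore establish regime-level agreement (peak locations, monotonic
effects, extents, relative changes), not spike-for-spike equivalence, and
say nothing about biological dentate beyond what the model's assumptions
(no NMDA/GABA_B, no basket-basket coupling, no septal theta input, no
transverse topography) allow.

Two quantitative residuals of the scale-down are known and deliberate.
The baseline STC spatial extent at the 1/e threshold is ~0.45 mm (the
full-scale reference reports correlations persisting to ~1 mm); it is set by the
perforant-path field width and grows toward ~0.6 mm with the associational
loop and ~1 mm with randomized mossy wiring, so the ordering of conditions
is preserved even though the absolute figure is about half the reference value.
And total granule output in the rebalanced network is hypersensitive to
the BC->GC amplitude: halving it raises totals by ~70-110% here versus the
reference model's 49%, because inhibition arrives in fewer, larger packets.  For
the same reason, driving the perforant path 10x at base feedback leaves a
weak narrow ~40 Hz line in the spectrum where the million-cell reference
stayed asynchronous: the undersampled interneuron population cannot supply
smooth tonic inhibition under heavy drive.  Both residuals are reported as
measured.

## Problem sizes used by tests and the acceptance script

Single-cell checks run in seconds.  Network-level checks run 4-s
simulations at the desk or compact presets with analysis windows excluding
the 1 s onset ramp; STC sampling uses up to ~800 cells at these scales.
These sizes are the package's reproduction defaults; all of them are
parameters, and the full-scale configuration is expressible but not
exercised by the bundled scripts.
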