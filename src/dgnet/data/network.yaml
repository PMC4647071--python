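# Network-level defaults: geometry, conduction, terminal fields, laminar
# targets, pathway gains, and the entorhinal stimulus.
geometry:
  axis_length_mm: 10.0
  transverse_extent: 1.0

conduction:
  velocity_m_per_s: 0.25
  synaptic_latency_ms: 0.8

# Septo-temporal axon terminal field extents (mm unless noted).  Fields are
# Gaussian (sigma = extent / 4) truncated at +/- extent / 2.  The mossy cell
# extent varies linearly with soma position from 2/3 of the axis at the
# septal pole to 1/3 at the temporal pole.
terminal_fields:
  EC_extent_mm: 1.25          # perforant path: 1-1.5 mm reported range
  GC_extent_mm: 2.0           # mossy-fiber collaterals: local hilar field
  BC_extent_mm: 4.0           # basket axon field (wide enough that the
                              # undersampled interneuron population keeps
                              # spatially overlapping inhibition)
  MC_extent_fraction_septal: 0.6667
  MC_extent_fraction_temporal: 0.3333

# Postsynaptic compartment targeted by each pathway (granule cell regions:
# soma, GCL, inner, middle, outer; BC and MC are single-compartment).
targets:
  MEC_GC: middle
  LEC_GC: outer
  BC_GC: soma
  MC_GC: inner
  GC_BC: soma
  MEC_BC: soma
  LEC_BC: soma
  MC_BC: soma
  GC_MC: soma

# Per-pathway gain applied on top of the table weights (unit-convention
# calibration against the model's operating regimes; see docs/methods.md)
# and a single global weight scale.
weight_scale: 1.0
gains:
  MEC_GC: 9.0
  LEC_GC: 9.0
  BC_GC: 60.0
  GC_BC: 20.0
  MEC_BC: 4.0
  LEC_BC: 4.0
  MC_GC: 110.0
  MC_BC: 2.0
  GC_MC: 15.0

stimulus:
  rate_hz: 3.0
  ramp_ms: 1000.0
  duration_ms: 4000.0
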