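# Passive and active biophysical parameters per cell type.
#
# Granule cell rows are per-region vectors over the reduced 5-region scheme
# [soma, GCL, inner 1/3, middle 1/3, outer 1/3]; absent channels are 0.
# The basket cell block is a fast-spiking single-compartment design of this
# package (Na + fast delayed rectifier + leak); see docs/methods.md.
granule_cell:
  regions: [soma, GCL, inner, middle, outer]
  "Soma S.A. (cm2)": 4.97E-04
  "R.M.P. (mV)": -75.01
  "Rin (M-Ohms)": 185.86
  "Membrane time constant (ms)": 31
  "Cm (uF/cm2)": [9.8, 9.8, 15.68, 15.68, 15.68]
  "Ra (ohm-cm)": 210
  "Leak (S/cm2)": [2.90E-04, 2.90E-04, 4.57E-04, 4.57E-04, 4.57E-04]
  "Sodium (S/cm2)": [0.84, 0.126, 0.091, 0.056, 0]
  "Delayed rectifier K (slow)": [0.006, 0.006, 0.006, 0.006, 0.008]
  "Delayed rectifier K (fast)": [0.036, 0.009, 0.009, 0.00225, 0.00225]
  "A-type K (S/cm2)": [0.108, 0, 0, 0, 0]
  "L-type Ca (S/cm2)": [0.0025, 0.00375, 0.00375, 0.00025, 0]
  "N-type Ca (S/cm2)": [1.47E-03, 7.35E-04, 7.35E-04, 7.35E-04, 7.35E-04]
  "T-type Ca (S/cm2)": [0.000074, 0.00015, 0.0005, 0.001, 0.002]
  "Ca-dependent K (SK)": [0.001, 0.0004, 0.0002, 0, 0]
  "Ca- and V- dependent K (BK)": [1.20E-04, 1.20E-04, 2.00E-04, 4.80E-04, 4.80E-04]
  "Tau for decay of Ca (ms)": 10
  "Steady-state Ca (mol)": 5.00E-06

mossy_cell:
  "Soma S.A. (cm2)": 2.51E-03
  "R.M.P. (mV)": -64.75
  "Cm (uF/cm2)": 0.6
  "Ra (ohm-cm)": 100
  "Leak (S/cm2)": 1.10E-05
  "Sodium (S/cm2)": 0.12
  "Delayed rectifier K (fast)": 5.00E-04
  "A-type K (S/cm2)": 1.00E-05
  "L-type Ca (S/cm2)": 6.00E-04
  "N-type Ca (S/cm2)": 5.00E-05
  "Ca-dependent K (SK)": 1.60E-03
  "Ca- and V- dependent K (BK)": 1.65E-02
  "Tau for decay of Ca (ms)": 10
  "Steady-state Ca (mol)": 5.00E-06

basket_cell:
  "Soma S.A. (cm2)": 5.00E-05
  "R.M.P. (mV)": -65.0
  "Cm (uF/cm2)": 1.0
  "Ra (ohm-cm)": 100
  "Leak (S/cm2)": 1.50E-04
  "Sodium (S/cm2)": 0.35
  "Delayed rectifier K (fast)": 0.13
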