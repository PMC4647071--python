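# Per-pathway synaptic parameters.
#
# Field names mirror the model's synaptic parameter table: synapse counts
# (convergence ranges), synaptic weights, EPSP/IPSP rise/fall times, and
# reversal potentials.  Weights are peak conductances (uS convention, see
# docs/methods.md); kinetics rows missing from the source table (GC to MC,
# MC to GC, MC to BC) default to the MEC-to-GC values of 1.05 / 5.75 ms.
"Synapse counts":
  "MEC to GC": [1050, 1200]   # GC spines, middle 1/3
  "LEC to GC": [1100, 1300]   # GC spines, outer 1/3
  "BC to GC": [40, 80]
  "GC to BC": [500, 1400]
  "MEC to BC": [100, 200]
  "LEC to BC": [100, 200]
  "MC to GC": [750, 850]
  "MC to BC": [950, 1050]
  # Not constrained by the source table; see docs/methods.md.
  "GC to MC": [400, 800]

"Synaptic weights":
  "MEC to GC": 1.17E-5
  "LEC to GC": 1.50E-5
  "BC to GC": 1.09E-5
  "GC to MC": 2.00E-5
  "GC to BC": 1.13E-4
  "MEC to BC": 4.21E-6
  "LEC to BC": 4.21E-6
  "MC to GC": 1.17E-6
  "MC to BC": 2.27E-5

"EPSP/IPSP rise time (ms)":
  "MEC to GC": 1.05
  "LEC to GC": 1.05
  "BC to GC": 1.05
  "GC to BC": 0.1
  "MEC to BC": 1.05
  "LEC to BC": 1.05
  "GC to MC": 1.05
  "MC to GC": 1.05
  "MC to BC": 1.05

"EPSP/IPSP fall time (ms)":
  "MEC to GC": 5.75
  "LEC to GC": 5.75
  "BC to GC": 5.75
  "GC to BC": 0.59
  "MEC to BC": 18
  "LEC to BC": 18
  "GC to MC": 5.75
  "MC to GC": 5.75
  "MC to BC": 5.75

"Reversal potentials (mV)":
  "MEC to GC": 0
  "LEC to GC": 0
  "BC to GC": -75
  "GC to BC": 0
  "MEC to BC": 0
  "LEC to BC": 0
  "GC to MC": 0
  "MC to GC": 0
  "MC to BC": 0
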