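"""Excitation/inhibition rebalancing against a paired-activation curve.

The procedure mirrors the in-vivo paired-stimulation paradigm: a
synchronous volley through the mossy-cell (commissural/associational)
system precedes a perforant-path test volley at increasing delays, and the
granule cell response is expressed as a percentage of the unconditioned
control.  Basket->granule inhibition is strengthened and mossy->granule
excitation weakened by coordinate descent until the simulated curve matches
the target (here: the packaged synthetic stand-in curve).
"""

from dgnet.experiments import load_rebalance_target, paired_activation_curve, rebalance

delays, target = load_rebalance_target()
print("target  :", dict(zip(delays.astype(int), target)))

initial = paired_activation_curve({}, delays, seed=0, scale=0.001)
print("initial :", dict(zip(delays.astype(int),
                            initial["percent_of_control"].round(1))))

fit = rebalance(delays, target, seed=0, scale=0.001, max_evals=20)
print("fitted  :", dict(zip(delays.astype(int),
                            fit["achieved_percent"].round(1))))
print(f"multipliers: BC->GC x{fit['multipliers']['BC_GC']:.2f}, "
      f"MC->GC x{fit['multipliers']['MC_GC']:.2f} "
      f"(sse={fit['sse']:.1f}, converged={fit['converged']})")
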