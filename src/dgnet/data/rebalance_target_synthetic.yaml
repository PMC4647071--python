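# SYNTHETIC stand-in for the experimental paired-activation target curve.
#
# The rebalancing procedure fits the simulated commissural->perforant-path
# inhibition curve to this target: granule cell output to a PP test volley,
# as a percentage of the unconditioned control, for increasing delays
# between commissural (mossy-cell) and PP activation.  The real curve comes
# from in-vivo paired-stimulation experiments that are not tabulated here;
# this file only reproduces their qualitative shape (predominantly
# inhibitory at short delays, recovering toward control with delay).
# Replace it with digitized experimental data where available.
delays_ms: [10, 20, 40, 80, 160, 320]
percent_of_control: [25, 35, 55, 75, 90, 98]
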