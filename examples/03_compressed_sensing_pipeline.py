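"""The full compressed-sensing pipeline at the hardware conditions.

Samples only 102 of 4096 time points (sine-weighted Poisson-gap schedule
over 6 s) from the noisy circuit emulation, then compares the zero-filled
spectrum's Lorentzian fit against the IST-S reconstruction's.  The
reconstruction recovers the 136.2 / 272.4 Hz lines to within half the
frequency grid spacing while collecting 40x less data.
"""

import nmremu as nm

result = nm.run_pipeline(nm.PipelineConfig(seed=1))

print(f"schedule: {result.schedule.n_keep} of {result.schedule.n_grid} points")
print("zero-filled spectrum fit (raw, artifact-limited):")
for p, u in zip(result.peaks_raw, result.uncertainties_raw):
    print(f"  peak {p.center:8.2f} +- {u:.2f} Hz")
print("IST-S reconstructed spectrum fit:")
for p, u in zip(result.peaks_recon, result.uncertainties_recon):
    print(f"  peak {p.center:8.2f} +- {u:.2f} Hz")
print("Exact line positions are 136.200 and 272.400 Hz; the reconstruction "
      "is Fourier-limited (half the 1/6 Hz grid spacing, ~0.08 Hz) while "
      "the raw fit is roughly an order of magnitude worse.")
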