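"""Design the two bandpass filters used by the pipeline.

Third-order digital Butterworth bandpasses at the 1000 Hz CSI rate:
[1, 10] Hz for finger tapping / ruler vibration and [3, 6] Hz for resting
tremor.  Prints the transfer-function coefficients (a normalized to a[0]=1).
"""

from csimotion import design_butterworth_bandpass

for label, (f_lo, f_hi) in [("finger tapping / ruler", (1.0, 10.0)),
                            ("resting tremor", (3.0, 6.0))]:
    spec = design_butterworth_bandpass(3, f_lo, f_hi, fs=1000.0)
    print(f"{label} band [{f_lo}, {f_hi}] Hz:")
    print("  b =", ", ".join(f"{v:.4e}" for v in spec.b))
    print("  a =", ", ".join(f"{v:.4f}" for v in spec.a))

# b sums to zero (a bandpass passes no DC); the a coefficients are the
# recursion weights of the sixth-degree denominator polynomial.
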