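"""Follow one resistance value through divider, ADC and reconstruction.

The firmware never sees the sensor resistance directly: it measures the
midpoint voltage of a series divider (known R1 = 10 kΩ against the sensor),
quantizes it with a 10-bit ADC, and inverts R2 = (R1·U)/U1 − R1.  The
reconstruction error is set by the quantization step.
"""

import respitex as rx

cfg = rx.AcquisitionConfig()  # R1 = 10 kΩ, U = Uref = 5 V, 10 bits

for r2 in (50.0, 150.0, 242.9, 400.0):
    u1 = rx.divider_voltage(r2, cfg)
    counts = rx.adc_quantize(u1, cfg)
    r2_hat = rx.estimate_resistance(counts=counts, cfg=cfg)
    print(
        f"R2 = {r2:6.1f} kΩ -> U1 = {u1:.4f} V -> counts = {counts:4d} "
        f"-> reconstructed {r2_hat:7.2f} kΩ (error {r2_hat - r2:+6.2f} kΩ)"
    )

# The reconstruction error grows with R2 because the divider voltage (and
# so the ADC resolution per kΩ) shrinks as the sensor resistance rises —
# a few kΩ at breathing-scale resistances, harmless to peak counting.
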