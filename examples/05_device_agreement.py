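"""Agreement between a sensing shirt and a clinical reference system.

Paired breath counts recorded at increasing exercise intensity (MET) are
summarized as mean absolute error and mean bias (device − reference).
"""

import respitex as rx

pairs = rx.default_agreement_pairs()
res = rx.agreement(pairs)

print("MET   shirt  reference  diff")
for label, dev, ref in res.pairs:
    print(f"{label:>4s}  {dev:5.0f}  {ref:9.0f}  {dev - ref:+5.0f}")
print(f"\nMAE  = {res.mean_absolute_error:.3f} breaths/min")
print(f"bias = {res.mean_bias:+.3f} breaths/min")

# MAE ≈ 1.33 with a small positive bias: the shirt counts on average two
# thirds of a breath per minute more than the reference system.
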