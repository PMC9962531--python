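"""Fabric characterization formulas used when qualifying a sensing textile."""

import respitex as rx

# Areal density of a 20 cm × 20 cm acclimatized sample
mp = rx.surface_mass(rx.SurfaceMassInput(m=12.6092, la=0.2, sa=0.2))
print(f"surface mass:        {mp:7.2f} g/m²")

# Air permeability from the mean flow through a 20 cm² test head
ap = rx.air_permeability(rx.AirPermInput(qv_mean=8.24, a=20.0))
print(f"air permeability:    {ap:7.2f} mm/s")

# Guarded-hot-plate thermal resistance
rct = rx.thermal_resistance(
    rx.ThermalResInput(tm=35.0, ta=20.0, a=0.04, h=12.5, dhc=0.5, rct0=0.031)
)
print(f"thermal resistance:  {rct:7.4f} m²·K/W")

# Replicate summary (mean, sample sd, cv) of repeated coefficient cycles
stats = rx.summarize([27.1, 29.5, 25.8, 28.0, 27.6])
print(f"replicates: mean {stats.mean:.2f} %, sd {stats.sd:.2f} %, cv {stats.cv:.2f}")
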