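# Methods

`respitex` simulates the complete signal chain of a textile respiration
monitor: a piezoresistive sensor printed on a garment stretches with the
chest, its resistance is read through a voltage divider by a
microcontroller ADC, and a slope-threshold algorithm counts breaths per
minute. Every stage is modelled explicitly so the chain's behaviour can be
studied, and its failure modes exercised, without hardware.

## Signal chain

### 1. Mechanical stimulus (`waveform`)

Two generators produce the elongation (mm) of the sensing region on a
uniform time grid:

* **Tensile-machine cycles** (`instron_waveform`): a triangular wave
  0 → `stretch_distance` → 0 mm at constant ramp rate equal to the beam
  speed. The kinematics of a constant-speed crosshead make the wave
  triangular, not sinusoidal. Cycle frequency in cycles/min is
  `beam_speed / (2 × stretch_distance)`; the standard sweep uses a 100 mm
  gauge length, 10 mm stretch and speeds 160/240/400/480 mm/min, i.e.
  8/12/20/24 cycles per minute. A sampling interval longer than the
  half-cycle is rejected (the triangle would alias).
* **Synthetic breathing** (`breathing_waveform`): per-breath raised-cosine
  pulses of height `depth` (mm), paced by a stepwise rate schedule in
  breaths/min. No published chest-motion waveform constrains the pulse
  shape; a raised cosine was chosen as the smoothest pulse with a single
  maximum, with `inspiration_fraction` (default 0.4) setting the asymmetry
  between inhale and exhale. A zero rate yields a flat apnea segment.
  Optional additions: seeded Gaussian elongation noise (`noise_sd`, mm),
  linear baseline drift (`drift_slope`, mm/min), and Poisson-timed smoothed
  bumps (`artifact_rate` events/min, `artifact_amplitude` mm, fixed 0.8 s
  width) emulating arm/torso motion — the classic source of false breaths
  in garment-mounted sensing. Elongation is clipped at zero after all
  additions. All randomness flows from one `numpy` generator seeded by the
  profile, so identical profiles give bitwise-identical traces.

The default sampling interval is 0.05 s (20 Hz). Neither the firmware loop
period nor the machine logger rate is standardized for this class of
device, so the value is configurable; 20 Hz over-samples the fastest
simulated breathing (24/min) by more than a factor of 50.

### 2. Sensor model (`sensor`)

The sensor is characterized by its *sensory coefficient* — the percent
resistance rise over the relaxed baseline, `R_rel = (R − R0)/R0 × 100`.
The packaged calibration for the cotton/MWCNT/polypyrrole print maps
stretch → coefficient as 5 mm → 27.49 %, 10 mm → 61.93 %, 15 mm → 89.89 %,
20 mm → 136.91 % (with the replicate sd and cv of those measurements).
"Stretch" throughout means absolute clamp/chest displacement in mm, not
engineering strain.

`fit_gauge_response` fits a monotone shape-preserving cubic (PCHIP)
through (0, 0) and the calibration points, so the curve reproduces every
point exactly and never decreases; beyond the last point it continues as a
power law through the last two points. A `mode="linear"` least-squares
line through the origin is offered as well — the coefficient does grow
roughly linearly with stretch — but a single slope cannot pass through all
four points, so interpolation is the default.

The default baseline is **R0 = 150 kΩ**. The detector threshold (80 kΩ,
below) must be crossed by breath-scale resistance swings; with the ~62 %
rise at a 10 mm stretch, R0 = 150 kΩ yields ~93 kΩ swings. Published
surface-resistance measurements of such prints are in the single-kΩ range
and cannot produce 80 kΩ deltas, and the effective sensing-path resistance
of a finished garment is not available, so R0 is an explicit, configurable
simulation parameter rather than a claim about any particular shirt.

**Hysteresis.** Real load/unload loops of printed sensors are open but no
axis-calibrated loop data exist to fit, so hysteresis is modelled
qualitatively: with `hysteresis_ratio` h ∈ (0, 1], the unloading branch
descends with gain h × the loading gain, and the resulting excess over the
loading branch decays exponentially with time constant `relaxation_tau`
(default 5 s). Properties guaranteed and tested: h = 1 reproduces the
loading branch exactly sample-by-sample; h < 1 opens a loop of positive
area; after a full cycle plus a rest of a few time constants the sensor
returns to R0. Only these qualitative properties are asserted anywhere.
Measurement noise (`NoiseSpec`) adds seeded Gaussian kΩ deviations,
floored at a positive value so the trace stays physical.

### 3. Acquisition (`acquisition`)

The divider places the sensor (R2) between supply and the ADC pin and the
known resistor R1 between pin and ground:

    U1 = U · R1 / (R1 + R2)        (midpoint voltage)
    R2 = (R1 · U) / U1 − R1        (firmware reconstruction)

Defaults mirror the prototype hardware: R1 = 10 kΩ, U = Uref = 5 V,
10-bit ADC. The ADC mapping is
`counts = round(u1 · (2^bits − 1)/Uref)` with round-half-away-from-zero;
microcontroller families differ in this convention, so it is documented
here and fixed. The reconstruction error from quantization is bounded by
the back-propagated half-LSB: `|ΔR2| ≤ R1·U/(U1 − LSB/2)² · LSB/2`,
verified numerically in the tests. A zero count would place the sensor at
infinite resistance; such samples are flagged as open-circuit and hold the
last valid value instead of propagating a non-finite number.

### 4. Breath detection (`detect`)

The detector replays the firmware logic. For each sample,
`delta = previous − current` resistance; `delta ≤ 0` (flat counts as
rising) extends the current rising run and accumulates the rise since the
last trough; the first `delta > 0` ends the run and marks a peak at the
previous sample iff the accumulated rise reaches the `susceptibility`
threshold, 80 kΩ by default. The accumulator then resets and re-arms at
the next trough.

The firmware description is ambiguous between thresholding the *per-sample*
delta and the *cumulative* rise. At any realistic sampling rate a single
inter-sample step never approaches 80 kΩ, so the cumulative reading is the
only one under which the device can work and is the default; a
`mode="per_sample"` is provided for fidelity experiments and, as the tests
show, fires only on near-instantaneous jumps.

Peaks are counted in tumbling half-open windows `[start, start + window)`
of 60 s by default (a rolling window is not modelled; whether the original
counter rolls or tumbles is unknowable from the description, and tumbling
is the simpler semantics). `breaths_per_minute` reports the count of the
most recent complete window; traces shorter than one window are scaled by
`60/duration` under an explicit `allow_scaling` flag, or rejected.

No smoothing precedes detection, matching the firmware. An optional
moving-average pre-filter (`prefilter_width` samples) exists because the
unfiltered accumulator is fragile under noise: any downward wiggle during
a slow inhale resets it, and breaths are silently lost (example
`04_breathing_patterns.py` demonstrates both the failure and the fix).

### 5. Classification (`detect.classify_rate`)

Rates map to labels per age group. Clinical anchor points: bradypnea
8–10/min, adult normal 12–16, hyperpnea ≈ 20, tachypnea > 24, apnea ≈ ≤ 2;
pediatric normal ranges newborn/infant 30–60, toddler 24–40, preschooler
22–34, school age 18–30, adolescent 12–16. The anchors leave gaps (3–7,
11, 17–19 for adults); the default table closes them conservatively —
≤ 2 apnea, < 12 bradypnea, 12–16 normal, 17–24 hyperpnea, > 24
tachypnea — which is an interpretation, not a clinical claim, and the
table is fully overridable. Note one consequence: a rate of exactly
24/min classifies as hyperpnea even though the 480 mm/min simulator
scenario is conventionally called "tachypnea". Pediatric groups omit the
hyperpnea band (it describes depth, which rate alone cannot establish).

### 6. Orchestration and agreement (`scenarios`)

`run_scenario` chains the stages for a single self-describing config
(YAML-serializable), logs the narration at INFO and per-window counts at
DEBUG, optionally writes every intermediate trace as headered CSV, and
compares the detected rate against an `expected_rate` when present. The
four packaged scenarios sweep the machine speeds above; with all defaults
and noise off they read exactly 8/12/20/24 breaths/min.

`agreement` reduces paired device/reference breath counts to mean absolute
error and mean bias (device − reference). The packaged six-pair fixture
(shirt vs clinical reference across exercise intensities, labelled by MET)
gives MAE 8/6 ≈ 1.33 and bias 4/6 ≈ 0.67 breaths/min. The MET value is
carried as a label only. Whether such counts are per-minute rates or
per-test totals does not affect the arithmetic.

### 7. Textile metrics (`textile`)

Standard fabric-lab formulas: surface mass `m/(La·Sa)` (g/m²), air
permeability `(q̄v/A)·167` (mm/s, flow in dm³/min through an area in cm²),
thermal resistance `(Tm − Ta)·A/(H − ΔHc) − Rct0` (m²·K/W, the power
correction ΔHc treated as watts), and the replicate summary mean / sample
standard deviation (n − 1 denominator) / coefficient of variation. The
packaged calibration table is internally consistent under either sd
convention at the 2-decimal rounding it is stated to; n − 1 is used as
the ordinary laboratory convention.

## What the synthetic data does and does not show

The generators emulate the *geometry* of breathing-induced stretch —
periodicity, depth, asymmetric inhale/exhale, apnea, drift, motion bumps,
additive noise — under a perfectly calibrated, instantaneously responding
sensor. They do not model viscoelastic creep of the fabric, garment fit
and pressure, electrode/contact noise spectra (only white noise is
offered), temperature or humidity response, or wear-and-wash degradation.
Exact rate recovery on clean simulations therefore validates the *logic*
of the chain (thresholds, windowing, quantization margins), not the
performance of any physical garment; the noisy and artifact-laden
configurations probe robustness but with idealized noise.

## Numerical choices and problem sizes

* Grids are `arange(n)·dt` with the endpoint included
  (`n = round(duration/dt) + 1`); a 60 s scenario at 20 Hz is 1201 samples.
* ADC tie-break: round-half-away-from-zero (2.5 V at 10 bits/5 V → 512).
* A peak exactly on a window boundary belongs to the window that contains
  its sample time (half-open windows).
* Detection starts in the "rising" state with an empty accumulator, so a
  trace that opens mid-exhale cannot produce a spurious first peak.
* Simulations used in the tests and the acceptance script are 60 s at
  20 Hz — the natural one-window size for a per-minute counter — and run
  in well under a second each.
* Seeds are explicit everywhere randomness exists; reruns are
  byte-identical including written CSVs.

## Known limitations

* The hysteresis model is phenomenological; do not use it to fit measured
  loops.
* The cumulative-rise reading of the detector is a reconstruction of an
  ambiguous description; the strict per-sample mode is provided so the
  difference stays measurable.
* Classification gap-filling (3–11 → bradypnea, 17–24 → hyperpnea) is a
  software convention, overridable, and not medical guidance.
* R0 = 150 kΩ is a simulation operating point chosen for threshold
  headroom, not a measured garment property.
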