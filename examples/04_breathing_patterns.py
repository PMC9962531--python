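"""Detect breathing patterns from a synthetic human-breathing signal.

Generates raised-cosine breathing at several rates with a little strain
noise, runs the full chain and classifies each detected rate against
age-dependent normal ranges.  The firmware's detector applies no smoothing;
with noisy slow breathing, tiny downward wiggles reset its rise accumulator
and breaths are missed — the optional moving-average pre-filter
(off by default, to match the firmware) restores the count.
"""

import respitex as rx

response = rx.fit_gauge_response(rx.default_calibration_points())
acq = rx.AcquisitionConfig()
raw = rx.DetectorConfig()                      # 80 kΩ susceptibility, no filter
filtered = rx.DetectorConfig(prefilter_width=5)  # 0.25 s moving average

for rate in (6, 14, 22, 28):
    profile = rx.BreathingProfile(
        rate_schedule=((0.0, float(rate)),), noise_sd=0.1, seed=1
    )
    strain = rx.breathing_waveform(profile, duration=60.0, dt=0.05)
    acquired = rx.acquire(rx.resistance_at(response, strain), acq)
    bpm_raw = rx.breaths_per_minute(rx.detect_breaths(acquired.trace, raw))
    bpm_filt = rx.breaths_per_minute(rx.detect_breaths(acquired.trace, filtered))
    label = rx.classify_rate(bpm_filt, "adult").label
    print(
        f"programmed {rate:2d}/min -> raw detector {bpm_raw:4g}/min, "
        f"pre-filtered {bpm_filt:g}/min -> {label}"
    )

# An infant breathing 35/min is normal, while for an adult it is tachypnea:
for group in ("infant", "adult"):
    print(f"35/min for {group}: {rx.classify_rate(35, group).label}")
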