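"""Slope-threshold breath detector and rate classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import respitex as rx

CFG = rx.DetectorConfig()  # susceptibility 80 kΩ, 60 s windows


def _trace(resistances, dt=0.05):
    r = np.asarray(resistances, dtype=float)
    return rx.ResistanceTrace(t=np.arange(r.size) * dt, resistance=r, dt=dt)


def triangle_train(n_cycles, amplitude, baseline=150.0, samples_per_ramp=20, dt=0.05):
    ramp = np.linspace(0.0, amplitude, samples_per_ramp + 1)
    cycle = np.concatenate([ramp[:-1], ramp[::-1][:-1]])
    r = baseline + np.tile(cycle, n_cycles)
    return _trace(np.append(r, baseline), dt)


class TestDetectBreaths:
    def test_constant_trace_has_no_peaks(self):
        events = rx.detect_breaths(_trace(np.full(100, 150.0)), CFG)
        assert events.n_peaks == 0

    def test_single_supra_threshold_excursion(self):
        events = rx.detect_breaths(triangle_train(1, 100.0), CFG)
        assert events.n_peaks == 1

    def test_sub_threshold_oscillation_ignored(self):
        events = rx.detect_breaths(triangle_train(10, 40.0), CFG)
        assert events.n_peaks == 0

    def test_counts_every_cycle_of_a_train(self):
        events = rx.detect_breaths(triangle_train(7, 120.0), CFG)
        assert events.n_peaks == 7

    def test_peak_marked_at_local_maximum(self):
        trace = triangle_train(1, 100.0)
        events = rx.detect_breaths(trace, CFG)
        i_max = int(np.argmax(trace.resistance))
        assert events.peak_times[0] == pytest.approx(trace.t[i_max])

    def test_singleton_trace_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            rx.detect_breaths(_trace([150.0]), CFG)

    @given(offset=st.floats(0.0, 1e4))
    def test_offset_invariance(self, offset):
        """Adding a constant to every sample changes nothing."""
        base = triangle_train(3, 100.0)
        shifted = _trace(base.resistance + offset)
        a = rx.detect_breaths(base, CFG)
        b = rx.detect_breaths(shifted, CFG)
        np.testing.assert_array_equal(a.peak_times, b.peak_times)

    @pytest.mark.parametrize("amplitude", [90.0, 150.0, 300.0])
    def test_threshold_monotonicity(self, amplitude):
        """Peak count never increases as susceptibility grows."""
        trace = triangle_train(6, amplitude)
        counts = [
            rx.detect_breaths(trace, rx.DetectorConfig(susceptibility=s)).n_peaks
            for s in (10.0, 40.0, 80.0, 120.0, 200.0, 400.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_flat_samples_extend_a_rising_run(self):
        """delta == 0 counts as rising, so a plateaued rise still triggers."""
        r = np.concatenate([
            np.full(5, 150.0),
            np.linspace(150.0, 200.0, 20),
            np.full(10, 200.0),          # plateau mid-rise
            np.linspace(200.0, 240.0, 20),
            np.linspace(240.0, 150.0, 30),
        ])
        events = rx.detect_breaths(_trace(r), CFG)
        assert events.n_peaks == 1

    def test_per_sample_mode_needs_coarse_steps(self):
        """The literal per-sample reading only fires on near-instant jumps."""
        fine = triangle_train(1, 100.0, samples_per_ramp=50)
        coarse = _trace([150.0, 250.0, 150.0], dt=1.0)
        per_sample = rx.DetectorConfig(mode="per_sample")
        assert rx.detect_breaths(fine, per_sample).n_peaks == 0
        assert rx.detect_breaths(coarse, per_sample).n_peaks == 1
        assert rx.detect_breaths(fine, CFG).n_peaks == 1

    def test_window_counts_partition_the_peaks(self):
        trace = triangle_train(12, 100.0, samples_per_ramp=300)  # 30 s/cycle
        cfg = rx.DetectorConfig(window=60.0)
        events = rx.detect_breaths(trace, cfg)
        assert sum(n for _, n in events.counts_per_window) == events.n_peaks
        for start, n in events.counts_per_window:
            in_window = np.count_nonzero(
                (events.peak_times >= start) & (events.peak_times < start + 60.0)
            )
            assert n == in_window


class TestFullChainRateRecovery:
    @pytest.mark.parametrize("rate", [4, 6, 10, 16, 22, 30])
    def test_breathing_chain_recovers_generator_rate(self, rate, gauge_response):
        """Clean simulations: detected rate equals the programmed rate."""
        profile = rx.BreathingProfile(rate_schedule=((0.0, float(rate)),))
        strain = rx.breathing_waveform(profile, 60.0, 0.05)
        sensed = rx.resistance_at(gauge_response, strain)
        acquired = rx.acquire(sensed, rx.AcquisitionConfig())
        events = rx.detect_breaths(acquired.trace, CFG)
        assert rx.breaths_per_minute(events) == rate

    def test_instron_chain_normal_breathing(self, gauge_response):
        """240 mm/min over 10 mm stretch reads 12 breaths/min end to end."""
        proto = rx.InstronProtocol(beam_speed=240.0, duration=60.0)
        strain = rx.instron_waveform(proto, 0.05)
        sensed = rx.resistance_at(gauge_response, strain)
        acquired = rx.acquire(sensed, rx.AcquisitionConfig())
        events = rx.detect_breaths(acquired.trace, CFG)
        assert rx.breaths_per_minute(events) == 12

    def test_artifact_sensitivity(self, gauge_response):
        """Sub-threshold artifacts change nothing; supra-threshold ones add
        exactly their number of excursions ("false breaths")."""
        def chain_count(artifact_amplitude):
            profile = rx.BreathingProfile(
                rate_schedule=((0.0, 0.0),),  # apnea: artifacts only
                artifact_rate=4.0,
                artifact_amplitude=artifact_amplitude,
                seed=5,
            )
            strain = rx.breathing_waveform(profile, 60.0, 0.05)
            sensed = rx.resistance_at(gauge_response, strain)
            events = rx.detect_breaths(sensed, CFG)
            return events.n_peaks, strain.artifact_times

        n_small, _ = chain_count(3.0)   # ~16 % rise ≈ 25 kΩ < 80 kΩ
        assert n_small == 0

        n_big, times = chain_count(10.0)  # ~62 % rise ≈ 93 kΩ > 80 kΩ
        # independent excursion count: artifacts closer than the 0.8 s bump
        # width merge into one excursion
        expected = 1 + int(np.count_nonzero(np.diff(times) > 0.8)) if times.size else 0
        assert n_big == expected


class TestBreathsPerMinute:
    def test_twelve_peaks_in_a_minute(self):
        events = rx.BreathEvents(
            peak_times=np.arange(12) * 5.0 + 2.0,
            counts_per_window=[(0.0, 12)],
            window=60.0,
            duration=60.0,
        )
        assert rx.breaths_per_minute(events) == 12

    def test_no_peaks_is_zero(self):
        events = rx.BreathEvents(
            peak_times=np.empty(0), counts_per_window=[(0.0, 0)],
            window=60.0, duration=60.0,
        )
        assert rx.breaths_per_minute(events) == 0

    def test_short_trace_scales_to_a_minute(self):
        events = rx.BreathEvents(
            peak_times=np.array([5.0, 15.0, 25.0]),
            counts_per_window=[(0.0, 3)],
            window=60.0,
            duration=30.0,
        )
        assert rx.breaths_per_minute(events) == 6
        with pytest.raises(ValueError, match="scaling"):
            rx.breaths_per_minute(events, allow_scaling=False)

    def test_uses_most_recent_complete_window(self):
        events = rx.BreathEvents(
            peak_times=np.concatenate([np.arange(8) * 7.0 + 1.0, [65.0, 70.0, 80.0]]),
            counts_per_window=[(0.0, 8), (60.0, 3)],
            window=60.0,
            duration=130.0,
        )
        assert rx.breaths_per_minute(events) == 3


class TestClassifyRate:
    @pytest.mark.parametrize(
        "rate,group,label",
        [
            (9, "adult", "bradypnea"),
            (14, "adult", "normal"),
            (20, "adult", "hyperpnea"),
            (25, "adult", "tachypnea"),
            (1, "adult", "apnea"),
            (45, "newborn", "normal"),
            (70, "newborn", "tachypnea"),
            (20, "toddler", "bradypnea"),
            (28, "school_age", "normal"),
        ],
    )
    def test_default_table(self, rate, group, label):
        assert rx.classify_rate(rate, group).label == label

    def test_unknown_age_group_lists_valid_ones(self):
        with pytest.raises(ValueError, match="newborn"):
            rx.classify_rate(12, "octogenarian")

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rx.classify_rate(-1)

    def test_table_is_overridable(self):
        table = {"athlete": (2.0, 8.0, 12.0, None)}
        assert rx.classify_rate(9, "athlete", table).label == "normal"
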