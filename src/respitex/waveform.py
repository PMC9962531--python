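"""Mechanical stimulus generators for a chest-worn strain sensor.

Two stimulus families drive the simulated sensing chain:

* :func:`instron_waveform` — deterministic triangular elongation cycles, the
  way a constant-beam-speed tensile testing machine stretches a clamped
  fabric sample.  Cycle frequency in cycles/min equals
  ``beam_speed / (2 * stretch_distance)``, so e.g. 160 mm/min over a 10 mm
  stretch gives 8 cycles per minute.
* :func:`breathing_waveform` — stochastic human-like breathing: raised-cosine
  elongation pulses paced by a rate schedule, with optional Gaussian noise,
  baseline drift, and Poisson-timed motion artifacts (the "false breath"
  failure mode of garment-mounted sensors).

All traces live on a uniform time grid with non-negative elongation in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StrainTrace",
    "InstronProtocol",
    "BreathingProfile",
    "instron_waveform",
    "breathing_waveform",
    "DEFAULT_DT",
]

#: Default sampling interval in seconds (20 Hz).  The fastest simulated
#: breathing rate of interest (24 cycles/min, 2.5 s period) is over-sampled
#: by a factor of 50 at this rate.  Configurable everywhere it is used.
DEFAULT_DT = 0.05


def _check_uniform_grid(t: np.ndarray, dt: float) -> None:
    if t.ndim != 1 or t.size < 1:
        raise ValueError("time grid must be a non-empty 1-D array")
    if not np.all(np.isfinite(t)):
        raise ValueError("time grid contains non-finite values")
    if t.size > 1:
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(steps, dt, rtol=1e-9, atol=1e-12):
            raise ValueError("time grid is not uniform with the stated dt")


@dataclass
class StrainTrace:
    """Elongation (mm) of the sensing region sampled on a uniform grid.

    Parameters
    ----------
    t : array of seconds, strictly increasing with constant spacing ``dt``.
    elongation : array of mm, non-negative and finite.
    dt : sampling interval in seconds.
    artifact_times : optional array of artifact centre times (s) injected by
        the generator; carried as metadata for diagnostics, not validated.
    """

    t: np.ndarray
    elongation: np.ndarray
    dt: float
    artifact_times: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.elongation = np.asarray(self.elongation, dtype=float)
        _check_uniform_grid(self.t, self.dt)
        if self.elongation.shape != self.t.shape:
            raise ValueError("t and elongation must have the same shape")
        if not np.all(np.isfinite(self.elongation)):
            raise ValueError("elongation contains non-finite values")
        if np.any(self.elongation < 0):
            raise ValueError("elongation must be non-negative everywhere")

    @property
    def duration(self) -> float:
        """Span of the grid in seconds (last minus first sample time)."""
        return float(self.t[-1] - self.t[0])

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.t, "elongation_mm": self.elongation}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "StrainTrace":
        df = pd.read_csv(path)
        t = df["t_s"].to_numpy(dtype=float)
        dt = float(t[1] - t[0]) if t.size > 1 else 1.0
        return cls(t=t, elongation=df["elongation_mm"].to_numpy(dtype=float), dt=dt)


@dataclass(frozen=True)
class InstronProtocol:
    """Constant-beam-speed cyclic stretch protocol.

    ``gauge_length`` is the clamp separation (mm), ``stretch_distance`` the
    peak elongation per cycle (mm), ``beam_speed`` the constant crosshead
    speed (mm/min), ``duration`` the test length (s).
    """

    gauge_length: float = 100.0
    stretch_distance: float = 10.0
    beam_speed: float = 160.0
    duration: float = 60.0

    def __post_init__(self) -> None:
        if self.gauge_length <= 0:
            raise ValueError("gauge_length must be positive")
        if self.stretch_distance < 0:
            raise ValueError("stretch_distance must be non-negative")
        if self.beam_speed < 0:
            raise ValueError("beam_speed must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.stretch_distance > self.gauge_length:
            raise ValueError("stretch_distance cannot exceed gauge_length")

    @property
    def cycles_per_minute(self) -> float:
        """Cycle frequency = beam_speed / (2 × stretch_distance)."""
        if self.beam_speed == 0:
            return 0.0
        return self.beam_speed / (2.0 * self.stretch_distance)

    @property
    def cycle_period(self) -> float:
        """Seconds per full load–unload cycle (inf for a stationary beam)."""
        cpm = self.cycles_per_minute
        return math.inf if cpm == 0 else 60.0 / cpm


@dataclass(frozen=True)
class BreathingProfile:
    """Parameters of a synthetic human-breathing strain signal.

    ``rate_schedule`` is a sequence of ``(start_s, breaths_per_min)`` pairs;
    the rate holds from each start time until the next entry.  A zero rate
    produces a flat (apnea) segment.  ``depth`` is the peak chest elongation
    per breath in mm; ``inspiration_fraction`` the fraction of the breath
    period spent inhaling.  ``artifact_rate`` (events/min) paces Poisson-timed
    smoothed rectangular bumps of height ``artifact_amplitude`` mm emulating
    limb/torso motion.  ``drift_slope`` (mm/min) adds a linear baseline drift
    and ``noise_sd`` (mm) seeded Gaussian measurement noise.
    """

    rate_schedule: Sequence[tuple[float, float]] = ((0.0, 12.0),)
    depth: float = 10.0
    inspiration_fraction: float = 0.4
    artifact_rate: float = 0.0
    artifact_amplitude: float = 0.0
    drift_slope: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rate_schedule:
            raise ValueError("rate_schedule must contain at least one entry")
        for _, rate in self.rate_schedule:
            if rate < 0:
                raise ValueError("breathing rates must be non-negative")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 < self.inspiration_fraction < 1.0:
            raise ValueError("inspiration_fraction must lie strictly in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be non-negative")


def _time_grid(duration: float, dt: float) -> np.ndarray:
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / dt)) + 1
    return np.arange(n) * dt


def instron_waveform(protocol: InstronProtocol, dt: float = DEFAULT_DT) -> StrainTrace:
    """Triangular elongation cycles at constant crosshead speed.

    Each cycle ramps 0 → ``stretch_distance`` → 0 mm with
    ``|d(elongation)/dt| = beam_speed``.  A stationary beam
    (``beam_speed == 0``) yields a constant-zero trace.

    Raises
    ------
    ValueError
        If ``dt`` exceeds the half-cycle duration (the triangle would alias),
        or if ``stretch_distance`` is zero while the beam moves.
    """
    t = _time_grid(protocol.duration, dt)
    if protocol.beam_speed == 0:
        return StrainTrace(t=t, elongation=np.zeros_like(t), dt=dt)
    if protocol.stretch_distance == 0:
        raise ValueError("stretch_distance must be positive when the beam moves")
    half_cycle = protocol.cycle_period / 2.0
    if dt > half_cycle:
        raise ValueError(
            f"dt={dt} s aliases the stimulus: half-cycle is {half_cycle:.4g} s"
        )
    frac = (t / protocol.cycle_period) % 1.0
    elong = protocol.stretch_distance * (1.0 - np.abs(2.0 * frac - 1.0))
    # Round-off can leave values like -1e-17 at cycle boundaries.
    np.clip(elong, 0.0, protocol.stretch_distance, out=elong)
    return StrainTrace(t=t, elongation=elong, dt=dt)


def _breath_onsets(
    schedule: Sequence[tuple[float, float]], duration: float
) -> list[tuple[float, float]]:
    """Breath (onset_s, period_s) pairs paced by a stepwise rate schedule."""
    sched = sorted((float(s), float(r)) for s, r in schedule)
    if sched[0][0] > 0:
        sched = [(0.0, 0.0)] + sched  # silence before the first entry
    starts = [s for s, _ in sched]
    onsets: list[tuple[float, float]] = []
    t = 0.0
    while t < duration:
        idx = np.searchsorted(starts, t, side="right") - 1
        rate = sched[idx][1]
        if rate <= 0:
            # apnea: jump to the next schedule change, or stop
            nxt = [s for s in starts if s > t]
            if not nxt:
                break
            t = nxt[0]
            continue
        period = 60.0 / rate
        onsets.append((t, period))
        t += period
    return onsets


def breathing_waveform(
    profile: BreathingProfile, duration: float, dt: float = DEFAULT_DT
) -> StrainTrace:
    """Synthetic chest-elongation signal for a breathing human.

    Each breath is a raised-cosine pulse of height ``profile.depth`` spanning
    one breath period: elongation rises over the inspiratory fraction of the
    period and falls over the rest.  Identical ``profile`` (including seed)
    and grid give a bitwise-identical trace.
    """
    t = _time_grid(duration, dt)
    elong = np.zeros_like(t)

    for onset, period in _breath_onsets(profile.rate_schedule, duration):
        ti = profile.inspiration_fraction * period
        te = period - ti
        lo = int(np.ceil(onset / dt - 1e-9))
        hi = min(int(np.floor((onset + period) / dt + 1e-9)), t.size - 1)
        if hi < lo:
            continue
        tau = t[lo : hi + 1] - onset
        pulse = np.where(
            tau < ti,
            0.5 * profile.depth * (1.0 - np.cos(np.pi * tau / ti)),
            0.5 * profile.depth * (1.0 + np.cos(np.pi * (tau - ti) / te)),
        )
        elong[lo : hi + 1] = np.maximum(elong[lo : hi + 1], pulse)

    rng = np.random.default_rng(profile.seed)

    artifact_times = np.empty(0)
    if profile.artifact_rate > 0 and profile.artifact_amplitude > 0:
        n_art = rng.poisson(profile.artifact_rate * duration / 60.0)
        artifact_times = np.sort(rng.uniform(0.0, duration, n_art))
        width = 0.8  # s; smoothed rectangular bump
        for centre in artifact_times:
            lo = max(int(np.ceil((centre - width / 2) / dt)), 0)
            hi = min(int(np.floor((centre + width / 2) / dt)), t.size - 1)
            if hi < lo:
                continue
            phase = (t[lo : hi + 1] - (centre - width / 2)) / width  # 0..1
            bump = profile.artifact_amplitude * np.sin(np.pi * phase) ** 2
            elong[lo : hi + 1] += bump

    if profile.drift_slope != 0.0:
        elong = elong + profile.drift_slope * t / 60.0

    if profile.noise_sd > 0:
        elong = elong + rng.normal(0.0, profile.noise_sd, t.size)

    np.clip(elong, 0.0, None, out=elong)
    return StrainTrace(t=t, elongation=elong, dt=dt, artifact_times=artifact_times)
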