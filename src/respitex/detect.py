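"""Slope-threshold breath detection and respiratory-rate classification.

The detector mirrors the firmware logic of the prototype: each new sample
yields ``delta = previous - current`` resistance.  ``delta <= 0`` means the
resistance is still rising (inhalation); the first sample with ``delta > 0``
ends the rising run, and a peak is marked there if the *accumulated* rise
since the last trough reaches the ``susceptibility`` threshold (80 kΩ by
default) — small wiggles never trigger it.  Peaks are then counted in
tumbling windows (60 s by default) to give breaths per minute, and the rate
is mapped to a clinical label (apnea/bradypnea/normal/hyperpnea/tachypnea)
using age-dependent normal ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sensor import ResistanceTrace

__all__ = [
    "DetectorConfig",
    "BreathEvents",
    "RateClassification",
    "detect_breaths",
    "breaths_per_minute",
    "classify_rate",
    "DEFAULT_RATE_TABLE",
    "AGE_GROUPS",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Peak-marking parameters.

    ``susceptibility``: minimum resistance rise (kΩ) between a trough and
    the following peak for the peak to count; controls stability against
    noise.  ``window``: counting window length in seconds.  ``mode``:
    ``"cumulative"`` (default) applies the threshold to the total rise since
    the last trough; ``"per_sample"`` applies it to the magnitude of the
    last single-sample delta, reproducing a stricter literal reading of the
    firmware, which only fires at very coarse sampling.  ``prefilter_width``
    > 1 enables an optional moving-average pre-filter (samples); off by
    default, matching the firmware.
    """

    susceptibility: float = 80.0
    window: float = 60.0
    mode: str = "cumulative"
    prefilter_width: int = 0

    def __post_init__(self) -> None:
        if self.susceptibility <= 0:
            raise ValueError("susceptibility must be positive")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.mode not in ("cumulative", "per_sample"):
            raise ValueError("mode must be 'cumulative' or 'per_sample'")
        if self.prefilter_width < 0:
            raise ValueError("prefilter_width must be non-negative")


@dataclass
class BreathEvents:
    """Detected peaks and per-window counts.

    ``peak_times`` are strictly increasing sample times (s) of marked peaks;
    ``counts_per_window`` holds ``(window_start_s, count)`` for consecutive
    half-open windows ``[start, start + window)`` covering the trace.
    """

    peak_times: np.ndarray
    counts_per_window: list[tuple[float, int]]
    window: float
    duration: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times.size)

    def to_csv(self, path) -> None:
        pd.DataFrame({"peak_time_s": self.peak_times}).to_csv(path, index=False)


@dataclass(frozen=True)
class RateClassification:
    """A breathing rate with its clinical label and the age group used."""

    rate: float
    label: str
    age_group: str


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    pad = np.concatenate((np.full(width - 1, x[0]), x))
    return np.convolve(pad, kernel, mode="valid")


def detect_breaths(trace: ResistanceTrace, cfg: DetectorConfig) -> BreathEvents:
    """Scan a resistance trace for breath peaks.

    The scan keeps a running rise accumulator.  While ``delta <= 0`` (flat
    samples count as rising, exactly as the firmware's condition dictates)
    the accumulator grows by the per-sample rise; at the first falling
    sample the rising run ends and a peak is marked at the previous sample
    iff the accumulated rise meets the susceptibility threshold.  The
    accumulator then resets and re-arms at the next trough.

    Raises
    ------
    ValueError
        For traces shorter than two samples (no slope exists).
    """
    r = trace.resistance
    if r.size < 2:
        raise ValueError("need at least two samples to detect slopes")
    if cfg.prefilter_width > 1:
        r = _moving_average(r, cfg.prefilter_width)

    peak_times: list[float] = []
    rise = 0.0
    rising = True
    last_delta = 0.0
    for i in range(1, r.size):
        delta = r[i - 1] - r[i]  # firmware convention: previous - current
        if delta <= 0:
            if not rising:
                rise = 0.0  # sample i-1 was a trough; re-arm
                rising = True
            rise += -delta
        else:
            if rising:
                threshold_met = (
                    rise >= cfg.susceptibility
                    if cfg.mode == "cumulative"
                    else abs(last_delta) >= cfg.susceptibility
                )
                if threshold_met:
                    peak_times.append(float(trace.t[i - 1]))
                rising = False
        last_delta = delta

    t0 = float(trace.t[0])
    duration = float(trace.t[-1] - trace.t[0])
    peaks = np.asarray(peak_times)
    n_windows = max(int(np.ceil(duration / cfg.window)), 1)
    counts = []
    for k in range(n_windows):
        start = t0 + k * cfg.window
        n = int(np.count_nonzero((peaks >= start) & (peaks < start + cfg.window)))
        counts.append((start, n))
    return BreathEvents(
        peak_times=peaks,
        counts_per_window=counts,
        window=cfg.window,
        duration=duration,
        t0=t0,
    )


def breaths_per_minute(events: BreathEvents, *, allow_scaling: bool = True) -> float:
    """Breathing rate from detected peaks.

    Returns the peak count of the most recent *complete* window (a window
    whose full span lies inside the trace).  For traces shorter than one
    window the total count is scaled by ``60 / duration`` when
    ``allow_scaling`` is true (the default), otherwise a ``ValueError``
    signals that no complete window exists.
    """
    complete = [
        (start, n)
        for start, n in events.counts_per_window
        if start + events.window <= events.t0 + events.duration + 1e-9
    ]
    if complete:
        start, n = complete[-1]
        return n * 60.0 / events.window
    if not allow_scaling:
        raise ValueError(
            f"trace spans {events.duration:g} s < one {events.window:g} s window "
            "and scaling is disabled"
        )
    if events.duration <= 0:
        raise ValueError("cannot scale a zero-duration trace to a rate")
    return events.n_peaks * 60.0 / events.duration


#: Age-dependent rate bands, breaths/min:
#: (apnea_max, normal_low, normal_high, hyperpnea_high or None).
#: Rates are labelled: <= apnea_max → apnea; < normal_low → bradypnea;
#: <= normal_high → normal; <= hyperpnea_high → hyperpnea; else tachypnea.
#: The adult band edges close the gaps the clinical ranges leave open
#: (bradypnea is classically 8–10, normal 12–16, hyperpnea ~20,
#: tachypnea > 24); pediatric groups carry their normal ranges and no
#: hyperpnea band.  Fully overridable via the ``table`` argument.
DEFAULT_RATE_TABLE: dict[str, tuple[float, float, float, float | None]] = {
    "newborn": (2.0, 30.0, 60.0, None),
    "infant": (2.0, 30.0, 60.0, None),
    "toddler": (2.0, 24.0, 40.0, None),
    "preschooler": (2.0, 22.0, 34.0, None),
    "school_age": (2.0, 18.0, 30.0, None),
    "adolescent": (2.0, 12.0, 16.0, None),
    "adult": (2.0, 12.0, 16.0, 24.0),
}

AGE_GROUPS = tuple(DEFAULT_RATE_TABLE)


def classify_rate(
    rate: float,
    age_group: str = "adult",
    table: dict[str, tuple[float, float, float, float | None]] | None = None,
) -> RateClassification:
    """Label a breathing rate for the given age group.

    Raises
    ------
    ValueError
        For negative rates or an unknown age group (the message lists the
        valid groups).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    tab = DEFAULT_RATE_TABLE if table is None else table
    if age_group not in tab:
        raise ValueError(
            f"unknown age group {age_group!r}; valid groups: {', '.join(tab)}"
        )
    apnea_max, lo, hi, hyper_hi = tab[age_group]
    if rate <= apnea_max:
        label = "apnea"
    elif rate < lo:
        label = "bradypnea"
    elif rate <= hi:
        label = "normal"
    elif hyper_hi is not None and rate <= hyper_hi:
        label = "hyperpnea"
    else:
        label = "tachypnea"
    return RateClassification(rate=float(rate), label=label, age_group=age_group)
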