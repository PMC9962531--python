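"""Microcontroller-side acquisition: voltage divider, ADC, reconstruction.

The sensor (unknown resistance ``R2``) sits in series with a known resistor
``R1`` across the supply ``U``; the midpoint voltage over R1 is::

    U1 = U * R1 / (R1 + R2)

The microcontroller quantizes U1 with its ADC and inverts the divider::

    R2 = (R1 * U) / U1 - R1

so the breath detector downstream sees the firmware's *reconstructed*
resistance, including quantization error.  Defaults mirror the prototype:
R1 = 10 kΩ, U = Uref = 5 V, 10-bit ADC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sensor import ResistanceTrace
from .waveform import _check_uniform_grid

__all__ = [
    "AcquisitionConfig",
    "AdcTrace",
    "AcquisitionResult",
    "divider_voltage",
    "adc_quantize",
    "estimate_resistance",
    "acquire",
    "OpenCircuitError",
]


class OpenCircuitError(ValueError):
    """Raised when a zero voltage/count makes the sensor look open-circuit."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Divider and ADC parameters.

    ``r1``: known series resistor (kΩ); ``u``: supply voltage (V);
    ``bits``: ADC resolution; ``uref``: ADC reference voltage (V), defaulting
    to the supply.
    """

    r1: float = 10.0
    u: float = 5.0
    bits: int = 10
    uref: float | None = None

    def __post_init__(self) -> None:
        if self.r1 <= 0:
            raise ValueError("R1 must be positive")
        if self.u <= 0:
            raise ValueError("supply voltage must be positive")
        if self.bits < 1:
            raise ValueError("ADC resolution must be at least 1 bit")
        if self.uref is not None and self.uref <= 0:
            raise ValueError("ADC reference voltage must be positive")

    @property
    def reference(self) -> float:
        return self.u if self.uref is None else self.uref

    @property
    def max_count(self) -> int:
        return 2**self.bits - 1


@dataclass
class AdcTrace:
    """Integer ADC readings on a uniform time grid."""

    t: np.ndarray
    counts: np.ndarray
    dt: float
    bits: int = 10

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        _check_uniform_grid(self.t, self.dt)
        if self.counts.shape != self.t.shape:
            raise ValueError("t and counts must have the same shape")
        if np.any(self.counts < 0) or np.any(self.counts > 2**self.bits - 1):
            raise ValueError("counts outside the ADC range")

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.t, "counts": self.counts}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, bits: int = 10) -> "AdcTrace":
        df = pd.read_csv(path)
        t = df["t_s"].to_numpy(dtype=float)
        dt = float(t[1] - t[0]) if t.size > 1 else 1.0
        return cls(t=t, counts=df["counts"].to_numpy(dtype=np.int64), dt=dt, bits=bits)


@dataclass
class AcquisitionResult:
    """Output of :func:`acquire`.

    ``trace`` is the firmware's reconstructed resistance; ``adc`` the raw
    counts; ``open_circuit`` flags samples whose count was zero (infinite
    apparent resistance) — those samples hold the last valid value in
    ``trace`` and should be excluded from downstream interpretation.
    """

    trace: ResistanceTrace
    adc: AdcTrace
    open_circuit: np.ndarray


def divider_voltage(r2, cfg: AcquisitionConfig) -> np.ndarray | float:
    """Midpoint voltage ``U * R1 / (R1 + R2)`` over the known resistor.

    Strictly decreasing in ``r2``; equals the full supply at ``r2 = 0``.
    """
    r2_arr = np.asarray(r2, dtype=float)
    if np.any(r2_arr < 0):
        raise ValueError("R2 must be non-negative")
    out = cfg.u * cfg.r1 / (cfg.r1 + r2_arr)
    return float(out) if np.isscalar(r2) else out


def adc_quantize(u1, cfg: AcquisitionConfig) -> np.ndarray | int:
    """Quantize a voltage to ADC counts.

    ``counts = round(u1 * (2**bits - 1) / Uref)`` with round-half-away-from-
    zero (the voltage is non-negative, so this is round-half-up), clipped to
    the ADC range.
    """
    u1_arr = np.asarray(u1, dtype=float)
    if np.any(u1_arr < 0):
        raise ValueError("ADC input voltage must be non-negative")
    raw = np.floor(u1_arr * cfg.max_count / cfg.reference + 0.5)
    counts = np.clip(raw, 0, cfg.max_count).astype(np.int64)
    return int(counts) if np.isscalar(u1) else counts


def estimate_resistance(
    u1=None, cfg: AcquisitionConfig = AcquisitionConfig(), *, counts=None
) -> np.ndarray | float:
    """Invert the divider: ``R2 = (R1 * U) / U1 - R1``.

    Accepts either a voltage (``u1``) or raw ADC ``counts`` (converted to
    voltage via the reference).  The exact algebraic inverse of
    :func:`divider_voltage` when no quantization intervenes.

    Raises
    ------
    OpenCircuitError
        If any voltage/count is zero: the divider equation would place the
        sensor at infinite resistance (open circuit).
    """
    if (u1 is None) == (counts is None):
        raise ValueError("provide exactly one of u1 or counts")
    if counts is not None:
        counts_arr = np.asarray(counts, dtype=float)
        if np.any(counts_arr == 0):
            raise OpenCircuitError("zero ADC count: sensor open circuit")
        voltage = counts_arr * cfg.reference / cfg.max_count
    else:
        voltage = np.asarray(u1, dtype=float)
        if np.any(voltage <= 0):
            raise OpenCircuitError("non-positive divider voltage: open circuit")
    out = cfg.r1 * cfg.u / voltage - cfg.r1
    scalar_in = (np.isscalar(u1) if u1 is not None else np.isscalar(counts))
    return float(out) if scalar_in else out


def acquire(trace: ResistanceTrace, cfg: AcquisitionConfig) -> AcquisitionResult:
    """Run a resistance trace through divider → ADC → reconstruction.

    Zero-count samples (sensor momentarily open) are flagged rather than
    propagated as infinities: the reconstructed trace holds the last valid
    value there (or the first valid value, for a zero at the start).
    """
    u1 = divider_voltage(trace.resistance, cfg)
    counts = adc_quantize(u1, cfg)
    open_circuit = counts == 0

    if np.all(open_circuit):
        raise OpenCircuitError("all samples read zero counts: sensor open circuit")

    safe_counts = counts.astype(float)
    valid_idx = np.flatnonzero(~open_circuit)
    if open_circuit.any():
        # hold-last-valid fill for the flagged samples
        fill = np.maximum.accumulate(
            np.where(open_circuit, -1, np.arange(counts.size))
        )
        fill[fill < 0] = valid_idx[0]
        safe_counts = safe_counts[fill]

    r2 = estimate_resistance(counts=safe_counts, cfg=cfg)
    out = ResistanceTrace(t=trace.t.copy(), resistance=r2, dt=trace.dt)
    adc = AdcTrace(t=trace.t.copy(), counts=counts, dt=trace.dt, bits=cfg.bits)
    return AcquisitionResult(trace=out, adc=adc, open_circuit=open_circuit)
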