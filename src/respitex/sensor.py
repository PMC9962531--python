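"""Piezoresistive sensor model: elongation → resistance.

The printed textile sensor is characterized by its *sensory coefficient*,
the percent resistance rise relative to the relaxed baseline::

    R_rel = (R - R0) / R0 * 100          [%]

Calibration data give the coefficient at a handful of stretch distances
(for the cotton/MWCNT/PPy print: 27.49 % at 5 mm up to 136.91 % at 20 mm).
:func:`fit_gauge_response` turns those points into a monotone
shape-preserving curve through the origin; :func:`resistance_at` then maps
any elongation trace to a resistance trace, optionally with load/unload
hysteresis and seeded measurement noise.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .waveform import StrainTrace, _check_uniform_grid

__all__ = [
    "CalibrationPoint",
    "GaugeResponse",
    "NoiseSpec",
    "ResistanceTrace",
    "fit_gauge_response",
    "resistance_at",
    "sensory_coefficient",
    "load_calibration_points",
    "default_calibration_points",
    "DEFAULT_R0_KOHM",
]

#: Default relaxed sensor resistance for simulation, in kΩ.  With the
#: cotton/MWCNT/PPy calibration (~62 % rise at 10 mm stretch) this baseline
#: gives ~93 kΩ breathing swings, comfortably above the detector's 80 kΩ
#: susceptibility threshold.
DEFAULT_R0_KOHM = 150.0


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration measurement: stretch (mm) → sensory coefficient (%)."""

    stretch: float
    sensory_coefficient: float

    def __post_init__(self) -> None:
        if self.stretch <= 0:
            raise ValueError("calibration stretch must be positive")
        if self.sensory_coefficient < 0:
            raise ValueError("sensory coefficient must be non-negative")


@dataclass
class NoiseSpec:
    """Additive Gaussian resistance noise (kΩ) with a reproducible seed."""

    resistance_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resistance_sd < 0:
            raise ValueError("resistance_sd must be non-negative")


@dataclass
class ResistanceTrace:
    """Sensor resistance (kΩ) on a uniform time grid; strictly positive."""

    t: np.ndarray
    resistance: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.resistance = np.asarray(self.resistance, dtype=float)
        _check_uniform_grid(self.t, self.dt)
        if self.resistance.shape != self.t.shape:
            raise ValueError("t and resistance must have the same shape")
        if not np.all(np.isfinite(self.resistance)):
            raise ValueError("resistance contains non-finite values")
        if np.any(self.resistance <= 0):
            raise ValueError("resistance must be strictly positive everywhere")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"t_s": self.t, "resistance_kohm": self.resistance}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResistanceTrace":
        df = pd.read_csv(path)
        t = df["t_s"].to_numpy(dtype=float)
        dt = float(t[1] - t[0]) if t.size > 1 else 1.0
        return cls(t=t, resistance=df["resistance_kohm"].to_numpy(dtype=float), dt=dt)


@dataclass
class GaugeResponse:
    """Calibrated stretch → relative-resistance-rise mapping.

    ``curve(s)`` returns the sensory coefficient (%) at stretch ``s`` mm;
    it passes through (0, 0), interpolates every calibration point, and is
    non-decreasing.  ``hysteresis_ratio`` is the unloading/loading gain
    ratio (1 = no hysteresis); ``relaxation_tau`` the time constant (s)
    with which an unloading offset decays back to the loading branch.
    """

    r0: float
    hysteresis_ratio: float = 1.0
    relaxation_tau: float = 5.0
    stretches: np.ndarray = field(default_factory=lambda: np.empty(0))
    coefficients: np.ndarray = field(default_factory=lambda: np.empty(0))
    mode: str = "pchip"
    _curve: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("base resistance R0 must be positive")
        if not 0.0 < self.hysteresis_ratio <= 1.0:
            raise ValueError("hysteresis_ratio must lie in (0, 1]")
        if self.relaxation_tau <= 0:
            raise ValueError("relaxation_tau must be positive")

    def curve(self, stretch) -> np.ndarray | float:
        """Sensory coefficient (%) at the given stretch(es), mm."""
        if self._curve is None:
            raise ValueError("GaugeResponse has no fitted curve")
        s = np.atleast_1d(np.asarray(stretch, dtype=float))
        if np.any(s < 0):
            raise ValueError("stretch must be non-negative")
        out = self._curve(s)
        return float(out[0]) if np.ndim(stretch) == 0 else out

    def resistance(self, stretch) -> np.ndarray | float:
        """Noise-free loading-branch resistance (kΩ) at the given stretch."""
        return self.r0 * (1.0 + np.asarray(self.curve(stretch)) / 100.0)


def _power_law_tail(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exponent and scale of y = c * s**p through the last two points."""
    x1, x2 = x[-2], x[-1]
    y1, y2 = y[-2], y[-1]
    if y1 <= 0:  # degenerate: fall back to linear continuation
        p = 1.0
        c = y2 / x2
    else:
        p = np.log(y2 / y1) / np.log(x2 / x1)
        c = y2 / x2**p
    return p, c


def fit_gauge_response(
    points: Sequence[CalibrationPoint],
    r0: float = DEFAULT_R0_KOHM,
    *,
    mode: str = "pchip",
    hysteresis_ratio: float = 1.0,
    relaxation_tau: float = 5.0,
) -> GaugeResponse:
    """Fit a monotone gauge-response curve to calibration points.

    ``mode="pchip"`` (default): monotone shape-preserving cubic through
    (0, 0) and every calibration point — the curve reproduces each point
    exactly — with power-law extrapolation beyond the last point.
    ``mode="linear"``: least-squares straight line through the origin; this
    reflects the observation that the coefficient grows roughly linearly
    with stretch, but does not interpolate the points exactly.

    Raises
    ------
    ValueError
        For fewer than two points, duplicate stretches, or a calibration
        set whose coefficient decreases with stretch (the offending pair is
        named in the message).
    """
    if len(points) < 2:
        raise ValueError("need at least two calibration points")
    pts = sorted(points, key=lambda p: p.stretch)
    x = np.array([p.stretch for p in pts], dtype=float)
    y = np.array([p.sensory_coefficient for p in pts], dtype=float)
    if np.any(np.diff(x) == 0):
        raise ValueError("calibration stretches must be distinct")
    for i in range(1, len(pts)):
        if y[i] < y[i - 1]:
            raise ValueError(
                "calibration set is not monotone: coefficient drops from "
                f"{y[i - 1]:g}% at {x[i - 1]:g} mm to {y[i]:g}% at {x[i]:g} mm"
            )

    x0 = np.concatenate(([0.0], x))
    y0 = np.concatenate(([0.0], y))

    if mode == "pchip":
        interp = PchipInterpolator(x0, y0, extrapolate=False)
        p_exp, c = _power_law_tail(x0, y0)
        x_last = x0[-1]

        def curve(s: np.ndarray) -> np.ndarray:
            s = np.atleast_1d(np.asarray(s, dtype=float))
            out = np.empty_like(s)
            inside = s <= x_last
            out[inside] = interp(s[inside])
            out[~inside] = c * s[~inside] ** p_exp
            return out

    elif mode == "linear":
        slope = float(np.sum(x * y) / np.sum(x * x))

        def curve(s: np.ndarray) -> np.ndarray:
            return slope * np.atleast_1d(np.asarray(s, dtype=float))

    else:
        raise ValueError(f"unknown fit mode {mode!r}; use 'pchip' or 'linear'")

    return GaugeResponse(
        r0=r0,
        hysteresis_ratio=hysteresis_ratio,
        relaxation_tau=relaxation_tau,
        stretches=x,
        coefficients=y,
        mode=mode,
        _curve=curve,
    )


def sensory_coefficient(r0: float, r) -> np.ndarray | float:
    """Percent relative resistance rise, ``(R - R0) / R0 * 100``."""
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    out = (np.asarray(r, dtype=float) - r0) / r0 * 100.0
    return float(out) if np.isscalar(r) else out


def resistance_at(
    response: GaugeResponse,
    strain: StrainTrace,
    noise: NoiseSpec | None = None,
) -> ResistanceTrace:
    """Map an elongation trace to a sensor resistance trace.

    With ``hysteresis_ratio == 1`` and no noise this is exactly
    ``R0 * (1 + curve(elongation)/100)`` sample by sample.  With
    ``hysteresis_ratio < 1`` the unloading branch descends with the scaled
    gain and the resulting excess over the loading branch relaxes
    exponentially with time constant ``relaxation_tau``, so a full
    load–unload cycle closes back to R0 after a few time constants.
    """
    loading = np.asarray(response.curve(strain.elongation), dtype=float)
    loading_r = response.r0 * (1.0 + loading / 100.0)

    h = response.hysteresis_ratio
    if h == 1.0:
        r = loading_r.copy()
    else:
        decay = np.exp(-strain.dt / response.relaxation_tau)
        r = np.empty_like(loading_r)
        r[0] = loading_r[0]
        offset = 0.0
        for i in range(1, r.size):
            de = strain.elongation[i] - strain.elongation[i - 1]
            if de < 0:
                cand = r[i - 1] + h * (loading_r[i] - loading_r[i - 1])
            else:
                cand = loading_r[i] + offset
            offset = max(cand - loading_r[i], 0.0) * decay
            r[i] = loading_r[i] + offset

    if noise is not None and noise.resistance_sd > 0:
        rng = np.random.default_rng(noise.seed)
        r = r + rng.normal(0.0, noise.resistance_sd, r.size)
        np.clip(r, 1e-6, None, out=r)

    return ResistanceTrace(t=strain.t.copy(), resistance=r, dt=strain.dt)


def load_calibration_points(path) -> list[CalibrationPoint]:
    """Read calibration points from CSV columns ``stretch_mm,coefficient_pct``."""
    df = pd.read_csv(path)
    return [
        CalibrationPoint(float(row["stretch_mm"]), float(row["coefficient_pct"]))
        for _, row in df.iterrows()
    ]


def default_calibration_points() -> list[CalibrationPoint]:
    """Packaged cotton/MWCNT/PPy calibration table (stretch → coefficient)."""
    ref = importlib.resources.files("respitex.data") / "sensory_calibration.csv"
    with importlib.resources.as_file(ref) as path:
        return load_calibration_points(path)
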