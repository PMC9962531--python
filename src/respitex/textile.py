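"""Textile characterization formulas and replicate summary statistics.

Standard fabric-lab quantities used when qualifying a printed sensing
textile: surface mass (areal density), air permeability from a fixed-head
flow test, thermal resistance from a guarded hot plate, and the
mean / standard deviation / coefficient-of-variation summary applied to
replicate measurements (e.g. repeated sensory-coefficient cycles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurfaceMassInput",
    "AirPermInput",
    "ThermalResInput",
    "SummaryStats",
    "surface_mass",
    "air_permeability",
    "thermal_resistance",
    "summarize",
    "summarize_replicates",
]


@dataclass(frozen=True)
class SurfaceMassInput:
    """Acclimatized sample mass ``m`` (g) over a ``la`` × ``sa`` (m) cut."""

    m: float
    la: float
    sa: float

    def __post_init__(self) -> None:
        if self.m <= 0 or self.la <= 0 or self.sa <= 0:
            raise ValueError("mass and both dimensions must be positive")


@dataclass(frozen=True)
class AirPermInput:
    """Mean air flow ``qv_mean`` (dm³/min) through test area ``a`` (cm²)."""

    qv_mean: float
    a: float

    def __post_init__(self) -> None:
        if self.qv_mean < 0:
            raise ValueError("mean flow must be non-negative")
        if self.a <= 0:
            raise ValueError("test area must be positive")


@dataclass(frozen=True)
class ThermalResInput:
    """Guarded-hot-plate inputs.

    ``tm``/``ta``: plate and air temperatures (°C); ``a``: plate area (m²);
    ``h``: heating power (W); ``dhc``: heating-power correction (W);
    ``rct0``: thermal resistance of the uninsulated plate (m²·K/W).
    """

    tm: float
    ta: float
    a: float
    h: float
    dhc: float = 0.0
    rct0: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("plate area must be positive")
        if self.h - self.dhc <= 0:
            raise ValueError("corrected heating power H - dHc must be positive")


@dataclass(frozen=True)
class SummaryStats:
    """Sample mean, sample standard deviation (n−1) and cv = sd/mean."""

    mean: float
    sd: float
    cv: float


def surface_mass(x: SurfaceMassInput) -> float:
    """Areal density ``m / (La × Sa)`` in g/m²."""
    return x.m / (x.la * x.sa)


def air_permeability(x: AirPermInput) -> float:
    """Air permeability ``(qv_mean / A) × 167`` in mm/s.

    167 converts dm³/min per cm² to mm/s.
    """
    return x.qv_mean / x.a * 167.0


def thermal_resistance(x: ThermalResInput) -> float:
    """Thermal resistance ``(Tm − Ta)·A / (H − ΔHc) − Rct0`` in m²·K/W."""
    return (x.tm - x.ta) * x.a / (x.h - x.dhc) - x.rct0


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, sample sd (n−1 denominator) and cv of replicate measurements.

    Raises
    ------
    ValueError
        For fewer than two values, or a zero mean (cv undefined).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values to summarize")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1))
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return SummaryStats(mean=mean, sd=sd, cv=sd / mean)


def summarize_replicates(path_or_df) -> pd.DataFrame:
    """Summarize a replicate table CSV (``sample_id,value``) per sample.

    Returns a DataFrame indexed by sample id with columns mean, sd, cv —
    the layout of a typical fabric-lab results table.
    """
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df)
    )
    rows = {}
    for sample_id, group in df.groupby("sample_id"):
        stats = summarize(group["value"].to_numpy())
        rows[sample_id] = {"mean": stats.mean, "sd": stats.sd, "cv": stats.cv}
    return pd.DataFrame.from_dict(rows, orient="index")
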