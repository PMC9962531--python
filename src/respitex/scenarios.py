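"""End-to-end experiment orchestration and device-agreement analysis.

A :class:`ScenarioConfig` bundles one stimulus (a tensile-machine protocol
or a breathing profile) with sensor, acquisition and detector settings;
:func:`run_scenario` drives the full chain

    stimulus → sensor resistance → divider/ADC → reconstruction →
    breath detection → rate → clinical label

and optionally writes every intermediate trace as CSV.  The four packaged
breath-simulator scenarios (:func:`builtin_scenarios`) sweep the beam speed
160/240/400/480 mm/min over a 10 mm stretch, i.e. 8/12/20/24 cycles per
minute.  :func:`agreement` computes mean absolute error and mean bias for
paired device-versus-reference breath counts, as used to compare a sensing
shirt against a clinical reference system.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .waveform import (
    DEFAULT_DT,
    BreathingProfile,
    InstronProtocol,
    StrainTrace,
    breathing_waveform,
    instron_waveform,
)
from .sensor import (
    DEFAULT_R0_KOHM,
    CalibrationPoint,
    GaugeResponse,
    NoiseSpec,
    ResistanceTrace,
    default_calibration_points,
    fit_gauge_response,
    resistance_at,
)
from .acquisition import AcquisitionConfig, AcquisitionResult, acquire
from .detect import (
    BreathEvents,
    DetectorConfig,
    RateClassification,
    breaths_per_minute,
    classify_rate,
    detect_breaths,
)

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "AgreementResult",
    "run_scenario",
    "builtin_scenarios",
    "agreement",
    "load_agreement_pairs",
    "default_agreement_pairs",
]

log = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """Self-describing configuration of one simulated monitoring session.

    Exactly one of ``instron`` / ``breathing`` must be set.  Sensor
    calibration defaults to the packaged cotton/MWCNT/PPy table.
    """

    name: str = "scenario"
    instron: InstronProtocol | None = None
    breathing: BreathingProfile | None = None
    duration: float = 60.0
    dt: float = DEFAULT_DT
    r0: float = DEFAULT_R0_KOHM
    calibration: list[CalibrationPoint] | None = None
    hysteresis_ratio: float = 1.0
    relaxation_tau: float = 5.0
    resistance_noise_sd: float = 0.0
    noise_seed: int = 0
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    age_group: str = "adult"
    expected_rate: float | None = None

    def __post_init__(self) -> None:
        if (self.instron is None) == (self.breathing is None):
            raise ValueError(
                "config must define exactly one stimulus: 'instron' or 'breathing'"
            )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        kwargs = dict(raw)
        try:
            if "instron" in kwargs and kwargs["instron"] is not None:
                kwargs["instron"] = InstronProtocol(**kwargs["instron"])
            if "breathing" in kwargs and kwargs["breathing"] is not None:
                br = dict(kwargs["breathing"])
                if "rate_schedule" in br:
                    br["rate_schedule"] = tuple(
                        (float(s), float(r)) for s, r in br["rate_schedule"]
                    )
                kwargs["breathing"] = BreathingProfile(**br)
            if "calibration" in kwargs and kwargs["calibration"] is not None:
                kwargs["calibration"] = [
                    CalibrationPoint(**p) if isinstance(p, dict) else CalibrationPoint(*p)
                    for p in kwargs["calibration"]
                ]
            if "acquisition" in kwargs and kwargs["acquisition"] is not None:
                kwargs["acquisition"] = AcquisitionConfig(**kwargs["acquisition"])
            if "detector" in kwargs and kwargs["detector"] is not None:
                kwargs["detector"] = DetectorConfig(**kwargs["detector"])
            return cls(**kwargs)
        except TypeError as exc:
            raise ValueError(f"invalid scenario config: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.calibration is not None:
            d["calibration"] = [asdict(p) for p in self.calibration]
        if self.breathing is not None:
            d["breathing"]["rate_schedule"] = [
                list(pair) for pair in self.breathing.rate_schedule
            ]
        return d


@dataclass
class ScenarioResult:
    """Everything :func:`run_scenario` produces, intermediates included."""

    config: ScenarioConfig
    strain: StrainTrace
    sensor_trace: ResistanceTrace
    acquired: AcquisitionResult
    events: BreathEvents
    rate: float
    classification: RateClassification

    @property
    def matches_expected(self) -> bool | None:
        if self.config.expected_rate is None:
            return None
        return self.rate == self.config.expected_rate

    def write(self, out_dir) -> None:
        """Dump all intermediate traces, events and a summary as CSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.strain.to_csv(out / "strain.csv")
        self.sensor_trace.to_csv(out / "sensor_resistance.csv")
        self.acquired.adc.to_csv(out / "adc_counts.csv")
        self.acquired.trace.to_csv(out / "reconstructed_resistance.csv")
        self.events.to_csv(out / "breath_events.csv")
        pd.DataFrame(
            self.events.counts_per_window, columns=["window_start_s", "count"]
        ).to_csv(out / "window_counts.csv", index=False)
        summary = {
            "name": [self.config.name],
            "rate_bpm": [self.rate],
            "label": [self.classification.label],
            "age_group": [self.classification.age_group],
            "expected_rate_bpm": [self.config.expected_rate],
            "matches_expected": [self.matches_expected],
        }
        pd.DataFrame(summary).to_csv(out / "summary.csv", index=False)


def run_scenario(cfg: ScenarioConfig, out_dir=None) -> ScenarioResult:
    """Run the full sensing chain for one scenario.

    Deterministic for a given config (all random elements are seeded inside
    the config).  When ``out_dir`` is given, all intermediate CSVs and a
    summary are written there.
    """
    if cfg.instron is not None:
        strain = instron_waveform(cfg.instron, cfg.dt)
    else:
        strain = breathing_waveform(cfg.breathing, cfg.duration, cfg.dt)
    log.info("scenario %s: generated %d strain samples", cfg.name, strain.t.size)

    points = cfg.calibration or default_calibration_points()
    response = fit_gauge_response(
        points,
        cfg.r0,
        hysteresis_ratio=cfg.hysteresis_ratio,
        relaxation_tau=cfg.relaxation_tau,
    )
    noise = NoiseSpec(resistance_sd=cfg.resistance_noise_sd, seed=cfg.noise_seed)
    sensor_trace = resistance_at(response, strain, noise)

    acquired = acquire(sensor_trace, cfg.acquisition)
    events = detect_breaths(acquired.trace, cfg.detector)
    rate = breaths_per_minute(events)
    classification = classify_rate(rate, cfg.age_group)
    log.info(
        "scenario %s: %d peaks -> %.3g breaths/min (%s)",
        cfg.name,
        events.n_peaks,
        rate,
        classification.label,
    )
    for start, n in events.counts_per_window:
        log.debug("scenario %s: window %.1f s -> %d peaks", cfg.name, start, n)

    result = ScenarioResult(
        config=cfg,
        strain=strain,
        sensor_trace=sensor_trace,
        acquired=acquired,
        events=events,
        rate=rate,
        classification=classification,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


#: (name, beam speed mm/min, expected breaths/min) of the packaged
#: breath-simulator sweep over a 10 mm stretch at 100 mm gauge length.
_BUILTIN_SWEEP = (
    ("bradypnea", 160.0, 8.0),
    ("normal", 240.0, 12.0),
    ("hyperpnea", 400.0, 20.0),
    ("tachypnea", 480.0, 24.0),
)


def builtin_scenarios() -> dict[str, ScenarioConfig]:
    """The four packaged tensile-machine breath-simulation scenarios."""
    out = {}
    for name, speed, expected in _BUILTIN_SWEEP:
        out[name] = ScenarioConfig(
            name=name,
            instron=InstronProtocol(
                gauge_length=100.0,
                stretch_distance=10.0,
                beam_speed=speed,
                duration=60.0,
            ),
            expected_rate=expected,
        )
    return out


@dataclass
class AgreementResult:
    """Paired-count agreement summary.

    ``pairs`` holds ``(label, device_count, reference_count)`` triples;
    ``mean_absolute_error`` and ``mean_bias`` are in breaths/min, with
    bias = mean(device − reference).
    """

    pairs: list[tuple[str, float, float]]
    mean_absolute_error: float
    mean_bias: float


def agreement(pairs: Sequence[tuple]) -> AgreementResult:
    """MAE and bias over paired device/reference breath counts.

    Accepts ``(device, reference)`` pairs or ``(label, device, reference)``
    triples.  Raises ``ValueError`` on empty input or negative counts.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one device/reference pair")
    norm: list[tuple[str, float, float]] = []
    for i, p in enumerate(pairs):
        if len(p) == 2:
            label, dev, ref = str(i), float(p[0]), float(p[1])
        else:
            label, dev, ref = str(p[0]), float(p[1]), float(p[2])
        if dev < 0 or ref < 0:
            raise ValueError("counts must be non-negative")
        norm.append((label, dev, ref))
    diffs = np.array([d - r for _, d, r in norm])
    return AgreementResult(
        pairs=norm,
        mean_absolute_error=float(np.mean(np.abs(diffs))),
        mean_bias=float(np.mean(diffs)),
    )


def load_agreement_pairs(path) -> list[tuple[str, float, float]]:
    """Read paired counts from a CSV with a label column and two count columns.

    Expects columns ``device_count`` and ``reference_count``; the first
    remaining column (e.g. ``met``) is used as the pair label.
    """
    df = pd.read_csv(path)
    label_cols = [c for c in df.columns if c not in ("device_count", "reference_count")]
    labels = df[label_cols[0]].astype(str) if label_cols else df.index.astype(str)
    return list(
        zip(labels, df["device_count"].astype(float), df["reference_count"].astype(float))
    )


def default_agreement_pairs() -> list[tuple[str, float, float]]:
    """Packaged shirt-versus-reference paired counts (MET-labelled)."""
    ref = importlib.resources.files("respitex.data") / "respiratory_agreement.csv"
    with importlib.resources.as_file(ref) as path:
        return load_agreement_pairs(path)
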