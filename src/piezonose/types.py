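"""Core domain types for piezoelectric sensor-array measurements of milk headspace.

Sign convention: a mass load on a quartz resonator *lowers* its oscillation
frequency, so sorption curves are negative-going.  ``ChronoCurve.delta_f``
stores the signed shift in Hz; analytical responses (the ``-dF_max`` signal)
are reported as positive magnitudes everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Volatile-compound classes carried by the emission model.  "water" is the
#: matrix component; the rest are the microbial / native aroma classes.
VOC_CLASSES = ("acids", "alcohols", "ketones", "aldehydes", "esters", "water")

MODES = ("injected", "frontal")

N_SENSORS = 8

#: Duration of the sorption branch in both gas-input modes, seconds.
SORPTION_SECONDS = 40.0
#: Total record length for the injected (closed-cell) mode, seconds.
INJECTED_SECONDS = 80.0
#: Total record length for the frontal (open-cell) mode: 40 s sorption
#: followed by 80 s desorption.
FRONTAL_SECONDS = 120.0

_SPAN_TOL = 1e-6


def lg(count: float) -> float:
    """Decimal logarithm of a colony count with the floor rule.

    Counts below 1 CFU/cm3 (including zero) map to lg = 0, so that sterile
    specimens have a well-defined regression target.
    """
    if count < 0:
        raise ValueError("colony count must be non-negative")
    return float(np.log10(count)) if count >= 1.0 else 0.0


@dataclass
class MilkSpecimen:
    """One milk specimen (or artificial standard) with its reference assays."""

    specimen_id: str
    farm_id: str
    qmafanm: float  # total viable count, CFU/cm3
    yeast: float  # CFU/cm3
    mold: float  # CFU/cm3
    fat: float  # mass fraction, %
    protein: float  # mass fraction, %
    lactose: float = 4.7  # mass fraction, %
    ultrasound_treated: bool = False

    def __post_init__(self) -> None:
        for name in ("qmafanm", "yeast", "mold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("fat", "protein", "lactose"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a mass fraction in [0, 100]")

    @property
    def lg_qmafanm(self) -> float:
        return lg(self.qmafanm)

    @property
    def lg_yeast(self) -> float:
        return lg(self.yeast)

    @property
    def lg_mold(self) -> float:
        return lg(self.mold)


@dataclass
class SensorSpec:
    """Static description of one coated quartz-microbalance sensor.

    ``class_sensitivity`` maps each VOC class to a response slope in
    Hz per (mmol/dm3); ``mode_gain_frontal`` is the signal amplification of
    the frontal (open, continuously fed) cell relative to the injected one.
    """

    sensor_index: int
    coating_name: str
    base_frequency: float  # Hz
    coating_mass: float  # micrograms
    noise_level: float  # Hz, SD of the point noise on the curve
    drift_rate: float  # kHz per 180 days of operation
    class_sensitivity: Mapping[str, float]  # Hz per (mmol/dm3)
    sorption_time_constant: float  # s
    desorption_time_constant: float  # s
    mode_gain_frontal: float  # dimensionless, in [3, 6]

    def __post_init__(self) -> None:
        if not 1 <= self.sensor_index <= N_SENSORS:
            raise ValueError("sensor_index must be in 1..8")
        if not np.isfinite(self.noise_level):
            raise ValueError("noise_level must be finite")
        if self.sorption_time_constant <= 0 or self.desorption_time_constant <= 0:
            raise ValueError("time constants must be positive")
        if not 3.0 <= self.mode_gain_frontal <= 6.0:
            raise ValueError("mode_gain_frontal must lie in [3, 6]")
        missing = [c for c in VOC_CLASSES if c not in self.class_sensitivity]
        if missing:
            raise ValueError(f"class_sensitivity missing classes: {missing}")


@dataclass
class VOCProfile:
    """Headspace concentrations per VOC class, mmol/dm3."""

    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [c for c in VOC_CLASSES if c not in self.concentrations]
        if missing:
            raise ValueError(f"profile missing classes: {missing}")
        if any(v < 0 for v in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")

    def __getitem__(self, key: str) -> float:
        return float(self.concentrations[key])


@dataclass
class ChronoCurve:
    """One sensor's frequency-shift record for one measurement.

    ``delta_f`` is the signed shift (negative-going under sorption).
    Injected curves span 80 s; frontal curves span 120 s with the
    sorption/desorption breakpoint at 40 s.
    """

    sensor_index: int
    times: np.ndarray  # s, strictly increasing from 0
    delta_f: np.ndarray  # Hz, signed
    mode: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.times.ndim != 1 or self.times.shape != self.delta_f.shape:
            raise ValueError("times and delta_f must be 1-D and equal length")
        if len(self.times) < 2:
            raise ValueError("curve needs at least 2 samples")
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must increase strictly from 0")
        span = INJECTED_SECONDS if self.mode == "injected" else FRONTAL_SECONDS
        if abs(self.times[-1] - span) > _SPAN_TOL:
            raise ValueError(
                f"{self.mode} curve must span {span:g} s, got {self.times[-1]:g} s"
            )

    @property
    def response(self) -> np.ndarray:
        """Positive response magnitude, -dF(t)."""
        return -self.delta_f

    def copy_with(self, delta_f: np.ndarray) -> "ChronoCurve":
        return ChronoCurve(self.sensor_index, self.times.copy(), delta_f, self.mode)


@dataclass
class Measurement:
    """One gas-phase measurement: 8 simultaneous sensor curves."""

    measurement_id: str
    specimen_id: str
    replicate: int
    day: int
    mode: str
    curves: Sequence[ChronoCurve]
    is_water_reference: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        indices = sorted(c.sensor_index for c in self.curves)
        if indices != list(range(1, N_SENSORS + 1)):
            raise ValueError("measurement needs exactly 8 curves, one per sensor")
        self.curves = sorted(self.curves, key=lambda c: c.sensor_index)

    def curve(self, sensor_index: int) -> ChronoCurve:
        return self.curves[sensor_index - 1]


@dataclass
class CalibrationSeries:
    """Concentration/signal pairs for one sensor and analyte, plus blanks."""

    analyte: str
    sensor_index: int
    concentrations: np.ndarray  # mmol/dm3
    signals: np.ndarray  # Hz
    blank_signals: np.ndarray  # Hz, water-vapor reference replicates

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        self.blank_signals = np.asarray(self.blank_signals, dtype=float)
        if self.concentrations.shape != self.signals.shape:
            raise ValueError("concentrations and signals must match in length")
        if len(np.unique(self.concentrations)) < 2:
            raise ValueError("need at least 2 distinct concentrations")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if len(self.blank_signals) < 3:
            raise ValueError("need at least 3 blank replicates")
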