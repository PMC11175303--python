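"""Synthetic study generator: specimens, VOC emission, sensor-array curves.

Emulates the raw-milk e-nose study design: 14 raw-milk specimens from five
farms plus two artificial standards, each measured in triplicate on an
8-sensor array in two gas-input modes (injected, 80 s; frontal, 40 s sorption
+ 80 s desorption), with daily triplicate water-vapor references.

The emission model is deliberately simple: each VOC class concentration is
log-linear in the decimal logarithms of the microbial counts with additive
fat/protein terms and multiplicative lognormal scatter,

    c_class = max(0, c0 + a*lgQ + b*lgY + d*lgM + e*fat + f*protein)
              * exp(N(0, s^2)).

Ultrasound treatment of the specimen boosts the yeast/mold coefficients
(b, d), standing in for the increased emission of volatiles after cell
disruption.  Sensor plateaus follow first-order sorption kinetics with the
per-sensor time constants and frontal-mode gains of the array description.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from . import sensors as sensor_defaults
from .types import (
    FRONTAL_SECONDS,
    INJECTED_SECONDS,
    MODES,
    N_SENSORS,
    SORPTION_SECONDS,
    CalibrationSeries,
    ChronoCurve,
    Measurement,
    MilkSpecimen,
    SensorSpec,
    VOCProfile,
    VOC_CLASSES,
)

# ---------------------------------------------------------------------------
# Specimen inventory
# ---------------------------------------------------------------------------

#: (specimen_id, farm_id, QMAFAnM, yeast, mold, fat %, protein %, lactose %)
#: Counts are the study's reference microbiology; fat/protein/lactose are
#: plausible raw-milk compositions (specimens 7, 9, 11-13 deliberately below
#: the 2.8 % protein minimum, as in the study).
_DEFAULT_INVENTORY = (
    ("1", "farm_1", 1.0e7, 1.0e4, 0.0, 3.9, 3.1, 4.7),
    ("4", "farm_1", 3.4e5, 0.0, 0.0, 4.1, 3.0, 4.8),
    ("14", "farm_1", 3.9e7, 1.0e4, 0.0, 3.7, 2.9, 4.6),
    ("2", "farm_2", 4.0e6, 1.0e3, 6.6e2, 3.6, 3.0, 4.7),
    ("6", "farm_2", 5.9e5, 6.5e2, 9.0e2, 4.2, 3.2, 4.8),
    ("8", "farm_2", 9.8e7, 8.0e3, 60.0, 3.8, 2.9, 4.6),
    ("11", "farm_2", 3.5e7, 1.8e3, 1.4e3, 3.5, 2.7, 4.5),
    ("3", "farm_3", 4.5e6, 1.0e3, 10.0, 4.0, 3.1, 4.7),
    ("9", "farm_3", 4.8e5, 0.0, 10.0, 3.9, 2.6, 4.6),
    ("13", "farm_3", 3.4e6, 1.7e4, 10.0, 3.6, 2.7, 4.5),
    ("5", "farm_4", 2.4e6, 1.5e3, 1.6e2, 4.3, 3.3, 4.9),
    ("10", "farm_4", 5.7e6, 3.4e4, 3.0e2, 4.0, 3.0, 4.7),
    ("7", "farm_5", 4.6e6, 5.7e3, 0.0, 3.8, 2.7, 4.6),
    ("12", "farm_5", 2.0e6, 2.3e3, 10.0, 3.7, 2.6, 4.5),
    ("std_2", "standard", 1.7e4, 0.0, 0.0, 4.07, 3.42, 5.0),
    ("std_1", "standard", 6.3e3, 0.0, 0.0, 4.05, 3.05, 4.68),
)

#: Four held-out specimens whose counts equal the study's test-set reference
#: values (lg QMAFAnM 6.30, 6.38, 5.77, 7.99 etc.), used for the prediction
#: table of the end-to-end pipeline.
_TEST_INVENTORY = (
    ("T1", "farm_1", 10**6.30, 10**3.36, 10**1.05, 3.8, 3.0, 4.7),
    ("T2", "farm_2", 10**6.38, 10**3.18, 10**2.20, 3.9, 2.9, 4.6),
    ("T3", "farm_3", 10**5.77, 10**2.81, 10**2.95, 4.0, 3.1, 4.7),
    ("T4", "farm_2", 10**7.99, 10**3.91, 10**1.77, 3.7, 2.8, 4.6),
)


def _rows_to_specimens(rows, ultrasound: bool = False) -> List[MilkSpecimen]:
    return [
        MilkSpecimen(
            specimen_id=sid,
            farm_id=farm,
            qmafanm=q,
            yeast=y,
            mold=m,
            fat=fat,
            protein=protein,
            lactose=lactose,
            ultrasound_treated=ultrasound,
        )
        for sid, farm, q, y, m, fat, protein, lactose in rows
    ]


def generate_specimen_inventory(
    config: Optional[Mapping] = None, seed: Optional[int] = None
) -> List[MilkSpecimen]:
    """Specimen inventory: the default 16-specimen fixture or a random draw.

    With ``config=None`` returns the study fixture: 14 raw-milk specimens
    with the reference colony counts plus two artificial standards.  A config
    mapping with ``n`` and per-indicator lg ranges instead draws lg counts
    uniformly (seeded), for stress-testing downstream stages.
    """
    if config is None or config == "default":
        return _rows_to_specimens(_DEFAULT_INVENTORY)
    rng = np.random.default_rng(seed)
    n = int(config.get("n", 16))
    ranges = {
        "qmafanm": config.get("lg_qmafanm_range", (3.5, 8.0)),
        "yeast": config.get("lg_yeast_range", (0.0, 4.5)),
        "mold": config.get("lg_mold_range", (0.0, 3.2)),
    }
    for name, (lo, hi) in ranges.items():
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid lg range for {name}: ({lo}, {hi})")
    fat_lo, fat_hi = config.get("fat_range", (3.4, 4.4))
    prot_lo, prot_hi = config.get("protein_range", (2.6, 3.4))
    out = []
    for i in range(n):
        out.append(
            MilkSpecimen(
                specimen_id=f"R{i + 1}",
                farm_id=f"farm_{1 + i % 5}",
                qmafanm=10 ** rng.uniform(*ranges["qmafanm"]),
                yeast=10 ** rng.uniform(*ranges["yeast"]),
                mold=10 ** rng.uniform(*ranges["mold"]),
                fat=rng.uniform(fat_lo, fat_hi),
                protein=rng.uniform(prot_lo, prot_hi),
            )
        )
    return out


def generate_test_specimens() -> List[MilkSpecimen]:
    """The four held-out specimens used for the prediction table."""
    return _rows_to_specimens(_TEST_INVENTORY)


# ---------------------------------------------------------------------------
# VOC emission
# ---------------------------------------------------------------------------


@dataclass
class ClassEmission:
    """Log-linear emission coefficients for one VOC class (mmol/dm3 units)."""

    c0: float
    a: float = 0.0  # per lg QMAFAnM
    b: float = 0.0  # per lg yeast
    d: float = 0.0  # per lg mold
    e: float = 0.0  # per % fat
    f: float = 0.0  # per % protein


@dataclass
class EmissionParams:
    """Emission coefficients for all classes plus scatter and ultrasound boost.

    ``noise_sigma`` is the SD of the lognormal replicate scatter per class;
    ``water_sigma`` the (tighter) scatter of the water class, which also
    governs the water-vapor reference replicates so that day-normalized
    reference signals stay within a few percent of unity.
    """

    coefficients: Dict[str, ClassEmission]
    noise_sigma: float = 0.08
    water_sigma: float = 0.01
    ultrasound_boost: float = 2.0

    def __post_init__(self) -> None:
        missing = [c for c in VOC_CLASSES if c not in self.coefficients]
        if missing:
            raise ValueError(f"emission coefficients missing classes: {missing}")


def default_emission_params() -> EmissionParams:
    """Default emission model.

    Acids and aldehydes track total bacterial load, alcohols and esters the
    yeasts, ketones the molds; fat/protein contribute small matrix terms.
    Magnitudes are set so that microbially driven signal changes per lg unit
    are an order of magnitude above sensor point noise, and replicate-level
    scatter puts the calculated-parameter CVs in the 5-20 % range.
    """
    coeff = {
        "acids": ClassEmission(c0=0.02, a=0.08, b=0.01, d=0.01, e=0.002),
        "alcohols": ClassEmission(c0=0.02, a=0.02, b=0.10, d=0.02, f=0.003),
        "ketones": ClassEmission(c0=0.05, a=0.03, b=0.02, d=0.10, e=0.004),
        "aldehydes": ClassEmission(c0=0.03, a=0.05, b=0.01, d=0.06, f=0.002),
        "esters": ClassEmission(c0=0.01, a=0.01, b=0.06, d=0.03),
        "water": ClassEmission(c0=2.0),
    }
    return EmissionParams(coefficients=coeff)


def emit_voc_profile(
    specimen: MilkSpecimen,
    emission_params: EmissionParams,
    rng: np.random.Generator,
) -> VOCProfile:
    """Draw the headspace VOC profile of one specimen."""
    conc = {}
    for cls in VOC_CLASSES:
        p = emission_params.coefficients[cls]
        b, d = p.b, p.d
        if specimen.ultrasound_treated:
            b *= emission_params.ultrasound_boost
            d *= emission_params.ultrasound_boost
        mean = (
            p.c0
            + p.a * specimen.lg_qmafanm
            + b * specimen.lg_yeast
            + d * specimen.lg_mold
            + p.e * specimen.fat
            + p.f * specimen.protein
        )
        sigma = emission_params.water_sigma if cls == "water" else emission_params.noise_sigma
        scatter = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
        conc[cls] = max(0.0, mean) * scatter
    return VOCProfile(concentrations=conc)


def water_voc_profile(
    emission_params: EmissionParams, rng: np.random.Generator
) -> VOCProfile:
    """Water-only profile for the daily reference measurement."""
    conc = {cls: 0.0 for cls in VOC_CLASSES}
    c_water = emission_params.coefficients["water"].c0
    sigma = emission_params.water_sigma
    scatter = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
    conc["water"] = c_water * scatter
    return VOCProfile(concentrations=conc)


# ---------------------------------------------------------------------------
# Curve synthesis
# ---------------------------------------------------------------------------

#: Slow closed-cell relaxation after the injected-mode quasi-plateau, s.
INJECTED_RELAXATION_TAU = 400.0

#: Day-to-day multiplicative sensitivity wobble per sensor (lognormal SD);
#: shared by every measurement of a day, hence removed exactly by the daily
#: water normalization.
DAY_GAIN_SIGMA = 0.03

_SAMPLING_HZ = 1.0  # 1 Hz grid: 81 points injected, 121 points frontal


def generate_day_gains(
    n_days: int, rng: np.random.Generator, sigma: float = DAY_GAIN_SIGMA
) -> np.ndarray:
    """Per (day, sensor) multiplicative sensitivity factors."""
    if sigma <= 0:
        return np.ones((n_days, N_SENSORS))
    return np.exp(rng.normal(0.0, sigma, size=(n_days, N_SENSORS)))


def _plateau_response(
    sensor: SensorSpec, profile: VOCProfile, mode: str, day_gain: float
) -> float:
    resp = sum(sensor.class_sensitivity[c] * profile[c] for c in VOC_CLASSES)
    if mode == "frontal":
        resp *= sensor.mode_gain_frontal
    return resp * day_gain


def _synth_curve(
    sensor: SensorSpec,
    plateau: float,
    mode: str,
    day: int,
    rng: np.random.Generator,
) -> ChronoCurve:
    total = INJECTED_SECONDS if mode == "injected" else FRONTAL_SECONDS
    times = np.arange(0.0, total + 0.5 / _SAMPLING_HZ, 1.0 / _SAMPLING_HZ)
    tau_s = sensor.sorption_time_constant
    resp = plateau * (1.0 - np.exp(-times / tau_s))
    after = times > SORPTION_SECONDS
    at_break = plateau * (1.0 - np.exp(-SORPTION_SECONDS / tau_s))
    tau_off = (
        INJECTED_RELAXATION_TAU if mode == "injected" else sensor.desorption_time_constant
    )
    resp[after] = at_break * np.exp(-(times[after] - SORPTION_SECONDS) / tau_off)
    delta_f = -resp
    # In-record baseline ramp from long-term drift, scaled by operation day.
    drift_hz_per_s = sensor.drift_rate * 1e3 / 180.0 * day / 86400.0
    delta_f = delta_f + drift_hz_per_s * times
    if sensor.noise_level > 0:
        delta_f = delta_f + rng.normal(0.0, sensor.noise_level, size=times.shape)
    return ChronoCurve(sensor.sensor_index, times, delta_f, mode)


def simulate_measurement(
    specimen: MilkSpecimen,
    sensor_array: Sequence[SensorSpec],
    mode: str,
    day: int,
    replicate: int,
    rng: np.random.Generator,
    *,
    emission: Optional[EmissionParams] = None,
    day_gains: Optional[np.ndarray] = None,
    measurement_id: Optional[str] = None,
) -> Measurement:
    """Simulate one triplicate member of a specimen's gas-phase measurement."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if len(sensor_array) != N_SENSORS:
        raise ValueError("sensor_array must contain 8 sensors")
    emission = emission or default_emission_params()
    gains = np.ones(N_SENSORS) if day_gains is None else np.asarray(day_gains, float)
    profile = emit_voc_profile(specimen, emission, rng)
    curves = [
        _synth_curve(
            s, _plateau_response(s, profile, mode, gains[s.sensor_index - 1]), mode, day, rng
        )
        for s in sensor_array
    ]
    mid = measurement_id or f"{specimen.specimen_id}_{mode}_d{day}_r{replicate}"
    return Measurement(
        measurement_id=mid,
        specimen_id=specimen.specimen_id,
        replicate=replicate,
        day=day,
        mode=mode,
        curves=curves,
    )


def simulate_water_reference(
    sensor_array: Sequence[SensorSpec],
    mode: str,
    day: int,
    rng: np.random.Generator,
    *,
    emission: Optional[EmissionParams] = None,
    day_gains: Optional[np.ndarray] = None,
    replicate: int = 1,
    measurement_id: Optional[str] = None,
) -> Measurement:
    """Simulate a double-distilled-water reference measurement."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    emission = emission or default_emission_params()
    gains = np.ones(N_SENSORS) if day_gains is None else np.asarray(day_gains, float)
    profile = water_voc_profile(emission, rng)
    curves = [
        _synth_curve(
            s, _plateau_response(s, profile, mode, gains[s.sensor_index - 1]), mode, day, rng
        )
        for s in sensor_array
    ]
    mid = measurement_id or f"water_{mode}_d{day}_r{replicate}"
    return Measurement(
        measurement_id=mid,
        specimen_id="water",
        replicate=replicate,
        day=day,
        mode=mode,
        curves=curves,
        is_water_reference=True,
    )


# ---------------------------------------------------------------------------
# Calibration series
# ---------------------------------------------------------------------------


def simulate_calibration_series(
    analyte: str,
    concentrations: Sequence[float],
    sensor: SensorSpec,
    n_blanks: int,
    rng: np.random.Generator,
    *,
    slope: Optional[float] = None,
    blank_level: Optional[float] = None,
) -> CalibrationSeries:
    """Signal-vs-concentration series with water-vapor blanks for LOD fitting.

    The true slope defaults to the LOD-anchored value for the sensor/analyte
    pair, so the fitted 3.3-sigma limit of determination recovers the
    characterisation table within noise.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    if n_blanks < 3:
        raise ValueError("need at least 3 blank replicates")
    if slope is None:
        slope = sensor_defaults.analyte_slope(sensor.sensor_index, analyte)
    if blank_level is None:
        water_c = default_emission_params().coefficients["water"].c0
        blank_level = sensor.class_sensitivity["water"] * water_c
    noise = sensor.noise_level
    signals = blank_level + slope * conc
    blanks = np.full(n_blanks, blank_level, dtype=float)
    if noise > 0:
        signals = signals + rng.normal(0.0, noise, size=conc.shape)
        blanks = blanks + rng.normal(0.0, noise, size=n_blanks)
    return CalibrationSeries(
        analyte=analyte,
        sensor_index=sensor.sensor_index,
        concentrations=conc,
        signals=signals,
        blank_signals=blanks,
    )
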