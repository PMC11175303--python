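"""Default 8-sensor array: coatings, noise, drift and sensitivity anchors.

The array mirrors a published raw-milk e-nose: eight 14.0 MHz quartz
resonators coated with chitosan composites, chromatographic phases and deep
eutectic solvents (DES).  Coating masses, point-noise levels and six-month
drift figures are the instrument's characterisation data; per-analyte
sensitivities are reconstructed from the characterisation limits of
determination (LOD) via ``slope = k * sigma_blank / LOD`` with k = 3.3, and
water-vapor slopes from the specific selectivity coefficients Ks.

The LOD-derived and Ks-derived slope tables are kept as *separate* anchors:
a single linear response with one blank SD cannot reproduce both printed
tables at once, so each drives the simulation of the quantity it calibrates.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .types import N_SENSORS, SensorSpec, VOC_CLASSES

BASE_FREQUENCY_HZ = 14.0e6

#: (coating, coating mass ug, point noise Hz, drift kHz per 180 days)
COATINGS = (
    ("18C6/chitosan", 28.7, 2.0, 2.58),
    ("DHC/chitosan", 14.7, 5.0, 1.818),
    ("chitosan/CMC", 12.5, 11.0, 1.41),
    ("choline+sorbitol", 15.2, 2.0, -0.736),
    ("choline+erythritol+ASO", 5.29, 3.0, 0.519),
    ("PVP/chitosan", 12.0, 2.0, 1.123),
    ("PEG2000/chitosan", 3.41, 3.0, -2.454),
    ("erythritol+ASO", 7.97, 1.0, 0.945),
)

CALIBRATION_ANALYTES = ("acetic_acid", "butyric_acid", "isopentanol", "butanone_2")

#: Limits of determination in aqueous solution, mmol/dm3, per sensor (rows)
#: and analyte (columns follow CALIBRATION_ANALYTES).
LOD_TABLE = np.array(
    [
        [1.8, 1.0, 0.094, 0.56],
        [0.17, 10.8, 0.92, 1.11],
        [17.4, 10.6, 9.3, 11.3],
        [2.5, 1.10, 0.91, 0.12],
        [0.16, 0.11, 0.10, 0.11],
        [17.2, 0.12, 0.94, 0.53],
        [1.16, 0.13, 1.10, 0.11],
        [0.18, 0.12, 0.11, 0.12],
    ]
)

#: Specific selectivity coefficients relative to water vapor, same layout.
KS_TABLE = np.array(
    [
        [1.02, 24.9, 1.60, 1.46],
        [1.92, 0.24, 0.89, 0.39],
        [1.44, 1.36, 0.34, 0.07],
        [1.04, 0.94, 0.33, 0.15],
        [1.02, 3.71, 1.11, 0.49],
        [1.13, 0.49, 0.35, 0.12],
        [1.06, 2.07, 1.17, 0.11],
        [0.87, 12.5, 1.53, 1.42],
    ]
)

LOD_SIGMA_FACTOR = 3.3

#: Water-class response slopes for the milk-headspace simulation, Hz per
#: (mmol/dm3).  Ordered by coating hydrophilicity (choline+sorbitol and
#: chitosan/CMC strongest); these set the magnitude of the daily water-vapor
#: reference signals that all milk signals are normalized against.
WATER_SENSITIVITY = (100.0, 120.0, 180.0, 200.0, 150.0, 130.0, 110.0, 120.0)

#: First-order sorption / desorption time constants, s.
SORPTION_TAU = (10.0, 12.0, 8.0, 15.0, 18.0, 9.0, 11.0, 14.0)
DESORPTION_TAU = (20.0, 25.0, 18.0, 30.0, 35.0, 20.0, 22.0, 28.0)

#: Frontal-cell gain relative to injected input, dimensionless in [3, 6].
MODE_GAIN_FRONTAL = (3.5, 4.2, 5.0, 3.8, 4.5, 5.5, 3.2, 6.0)


def analyte_slope(sensor_index: int, analyte: str, k: float = LOD_SIGMA_FACTOR) -> float:
    """Response slope, Hz per (mmol/dm3), implied by the sensor's LOD.

    Inverts the LOD definition ``LOD = k * sigma_blank / slope`` using the
    sensor's point-noise level as the blank SD.
    """
    col = CALIBRATION_ANALYTES.index(analyte)
    noise = abs(COATINGS[sensor_index - 1][2])
    return k * noise / LOD_TABLE[sensor_index - 1, col]


def water_slope_from_ks(sensor_index: int, analyte: str) -> float:
    """Water-vapor slope implied by the selectivity coefficient for *analyte*.

    Ks is the ratio of specific responses (signal per concentration) of the
    analyte and of water vapor, so water slope = analyte slope / Ks.
    """
    col = CALIBRATION_ANALYTES.index(analyte)
    return analyte_slope(sensor_index, analyte) / KS_TABLE[sensor_index - 1, col]


def default_class_sensitivity(sensor_index: int) -> Dict[str, float]:
    """Per-VOC-class slopes for one sensor, Hz per (mmol/dm3).

    Acids, alcohols and ketones come from the acetic-acid, isopentanol and
    butanone-2 LODs.  Aldehydes are assigned the ketone (carbonyl) slopes and
    esters half the mean of the alcohol and ketone slopes, absent dedicated
    calibration data for those classes.
    """
    acids = analyte_slope(sensor_index, "acetic_acid")
    alcohols = analyte_slope(sensor_index, "isopentanol")
    ketones = analyte_slope(sensor_index, "butanone_2")
    return {
        "acids": acids,
        "alcohols": alcohols,
        "ketones": ketones,
        "aldehydes": ketones,
        "esters": 0.5 * (alcohols + ketones) / 2.0,
        "water": WATER_SENSITIVITY[sensor_index - 1],
    }


def default_sensor_array() -> List[SensorSpec]:
    """The 8-sensor array with all defaults wired in."""
    array = []
    for i in range(1, N_SENSORS + 1):
        coating, mass, noise, drift = COATINGS[i - 1]
        array.append(
            SensorSpec(
                sensor_index=i,
                coating_name=coating,
                base_frequency=BASE_FREQUENCY_HZ,
                coating_mass=mass,
                noise_level=abs(noise),
                drift_rate=drift,
                class_sensitivity=default_class_sensitivity(i),
                sorption_time_constant=SORPTION_TAU[i - 1],
                desorption_time_constant=DESORPTION_TAU[i - 1],
                mode_gain_frontal=MODE_GAIN_FRONTAL[i - 1],
            )
        )
    return array


__all__ = [
    "BASE_FREQUENCY_HZ",
    "CALIBRATION_ANALYTES",
    "COATINGS",
    "KS_TABLE",
    "LOD_SIGMA_FACTOR",
    "LOD_TABLE",
    "MODE_GAIN_FRONTAL",
    "WATER_SENSITIVITY",
    "analyte_slope",
    "default_class_sensitivity",
    "default_sensor_array",
    "water_slope_from_ks",
]
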