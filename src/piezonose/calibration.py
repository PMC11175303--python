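"""Sensor-characterization math: Sauerbrey mass, calibration fits, LOD, Ks.

The limit of determination (LOD) follows the 3.3-sigma convention: the
analyte concentration whose predicted signal exceeds the water-vapor blank
mean by 3.3 blank standard deviations, i.e. ``LOD = k * sigma_blank / slope``
for a calibration line anchored at the blank mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import CalibrationSeries

#: Standard AT-cut quartz constants (CGS units).
QUARTZ_DENSITY = 2.648  # g/cm3
QUARTZ_SHEAR_MODULUS = 2.947e11  # g/(cm s^2)
DEFAULT_ELECTRODE_AREA_CM2 = 0.2

DEFAULT_LOD_K = 3.3


def sauerbrey_mass(
    delta_f: float,
    base_frequency: float,
    electrode_area: float = DEFAULT_ELECTRODE_AREA_CM2,
    quartz_density: float = QUARTZ_DENSITY,
    shear_modulus: float = QUARTZ_SHEAR_MODULUS,
) -> float:
    """Coating mass (micrograms) from the loading-induced frequency shift.

    Sauerbrey relation: dm = -df * A * sqrt(rho_q * mu_q) / (2 * F0^2),
    with the shift ``delta_f`` in Hz (negative under loading), electrode
    area in cm2, and quartz constants in CGS units.
    """
    if electrode_area <= 0:
        raise ValueError("electrode_area must be positive")
    grams = (
        -delta_f * electrode_area * np.sqrt(quartz_density * shear_modulus)
        / (2.0 * base_frequency**2)
    )
    return float(grams * 1e6)


def sauerbrey_shift(
    mass_ug: float,
    base_frequency: float,
    electrode_area: float = DEFAULT_ELECTRODE_AREA_CM2,
    quartz_density: float = QUARTZ_DENSITY,
    shear_modulus: float = QUARTZ_SHEAR_MODULUS,
) -> float:
    """Inverse of :func:`sauerbrey_mass`: the shift (Hz) for a given mass."""
    if electrode_area <= 0:
        raise ValueError("electrode_area must be positive")
    return float(
        -mass_ug * 1e-6 * 2.0 * base_frequency**2
        / (electrode_area * np.sqrt(quartz_density * shear_modulus))
    )


@dataclass
class CalibrationFit:
    """OLS line of signal on concentration, plus blank statistics."""

    slope: float  # Hz per (mmol/dm3)
    intercept: float  # Hz
    blank_mean: float  # Hz
    blank_sd: float  # Hz
    r_squared: float


def fit_calibration(series: CalibrationSeries) -> CalibrationFit:
    """Ordinary least squares of signal on concentration; blanks give sigma."""
    c, s = series.concentrations, series.signals
    if len(c) == 2:
        slope = (s[1] - s[0]) / (c[1] - c[0])
        intercept = s[0] - slope * c[0]
        r2 = 1.0
    else:
        res = stats.linregress(c, s)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        blank_mean=float(np.mean(series.blank_signals)),
        blank_sd=float(np.std(series.blank_signals, ddof=1)),
        r_squared=r2,
    )


def lod(fit: CalibrationFit, k: float = DEFAULT_LOD_K) -> float:
    """Limit of determination, mmol/dm3: concentration at blank_mean + k*sigma.

    Intersects the signal threshold with the calibration line anchored at the
    blank mean, which reduces to ``k * sigma / slope``.
    """
    if fit.slope <= 0:
        raise ValueError("LOD undefined for a non-positive calibration slope")
    if k <= 0:
        raise ValueError("k must be positive")
    return k * fit.blank_sd / fit.slope


def selectivity_coefficient(
    response_analyte: float,
    c_analyte: float,
    response_water: float,
    c_water: float,
) -> float:
    """Specific selectivity Ks: analyte specific response over water's."""
    if c_analyte <= 0 or c_water <= 0:
        raise ValueError("concentrations must be positive")
    if response_water == 0:
        raise ValueError("water response must be nonzero")
    return (response_analyte / c_analyte) / (response_water / c_water)


def lg_to_cfu_interval(lg_value: float, lg_sd: float) -> tuple[float, float]:
    """Back-transform a lg-scale value +/- SD to CFU/cm3 center and half-range.

    The interval symmetric on the lg scale is asymmetric in CFU; its
    asymmetry is collapsed to the half-range
    ``(10**(lg+sd) - 10**(lg-sd)) / 2``.
    """
    if lg_sd < 0:
        raise ValueError("lg_sd must be non-negative")
    center = 10.0**lg_value
    half = (10.0 ** (lg_value + lg_sd) - 10.0 ** (lg_value - lg_sd)) / 2.0
    return center, half
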