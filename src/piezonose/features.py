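"""Sorption-kinetics feature catalogue, 701-element assembly and profiles.

The calculated-parameter catalogue (version ``v1``) holds 69 entries per
measurement:

* 28 pairwise max-signal efficiency ratios ``A_i/j`` (unordered sensor pairs,
  i < j) — qualitative composition descriptors,
* 28 pairwise sorption-area ratios ``S_i/j``,
* 8 per-sensor kinetic shape parameters ``beta_i`` (response at half the
  sorption window over the maximal response),
* 5 array aggregates: summed response, summed area, mean beta, max/min
  response ratio, and the similarity of the (shape-normalized) response
  profile to the flat water-vapor profile.

Ratios and betas are invariant to a common multiplicative gain across all
sensors of a measurement, which is what makes the two gas-input modes
(whose signals differ by per-sensor factors of 3-6) comparable at the
calculated-parameter level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .preprocessing import (
    BLOCK_CURVE,
    BLOCK_MAX,
    BLOCK_PARAM,
    max_signal,
    resample_curve,
    smooth_measurement,
)
from .signal_io import RunConfig
from .types import ChronoCurve, Measurement, N_SENSORS, SORPTION_SECONDS

CATALOGUE_VERSION = "v1"

_PAIRS: List[Tuple[int, int]] = [
    (i, j) for i in range(1, N_SENSORS + 1) for j in range(i + 1, N_SENSORS + 1)
]

_AGGREGATES = ("sum_response", "sum_area", "mean_beta", "range_ratio", "delta_to_water")


def catalogue_names() -> List[str]:
    """Ordered names of the 69 calculated parameters."""
    names = [f"A{i}_{j}" for i, j in _PAIRS]
    names += [f"S{i}_{j}" for i, j in _PAIRS]
    names += [f"beta{i}" for i in range(1, N_SENSORS + 1)]
    names += list(_AGGREGATES)
    return names


CATALOGUE_SIZE = len(catalogue_names())  # 69


# ---------------------------------------------------------------------------
# Elementary parameters
# ---------------------------------------------------------------------------


def curve_area(
    curve: ChronoCurve, window: Tuple[float, float] = (0.0, SORPTION_SECONDS)
) -> float:
    """Trapezoidal integral of the response magnitude over a time window, Hz*s."""
    lo, hi = window
    mask = (curve.times >= lo - 1e-9) & (curve.times <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than 2 samples")
    return float(np.trapezoid(np.abs(curve.delta_f[mask]), curve.times[mask]))


def efficiency_ratio(
    measurement: Measurement, i: int, j: int, *, ratio_floor_hz: float = 1.0
) -> float:
    """Max-signal ratio A_i/j; NaN when the denominator response is below the floor."""
    ri = max_signal(measurement.curve(i))
    rj = max_signal(measurement.curve(j))
    if rj < ratio_floor_hz:
        return float("nan")
    return ri / rj


def area_ratio(
    measurement: Measurement, i: int, j: int, *, ratio_floor_hz: float = 1.0
) -> float:
    """Sorption-area ratio S_i/j over the sorption window; NaN on a weak denominator."""
    if max_signal(measurement.curve(j)) < ratio_floor_hz:
        return float("nan")
    ai = curve_area(measurement.curve(i))
    aj = curve_area(measurement.curve(j))
    if aj == 0:
        return float("nan")
    return ai / aj


def beta(curve: ChronoCurve, *, ratio_floor_hz: float = 0.0) -> float:
    """Kinetic shape parameter: response at half the sorption window over the max.

    Lies in [0, 1] for any monotone sorption branch; 1 for an instantaneous
    step, 0.5 for a linear ramp.  NaN when the maximal response vanishes
    (or sits below the floor).
    """
    peak = max_signal(curve)
    if peak <= max(ratio_floor_hz, 0.0) or peak == 0.0:
        return float("nan")
    half = float(np.interp(SORPTION_SECONDS / 2.0, curve.times, np.abs(curve.delta_f)))
    return half / peak


# ---------------------------------------------------------------------------
# Similarity and coincidence
# ---------------------------------------------------------------------------

ProfileLike = Union[pd.Series, Mapping[str, float], np.ndarray, Sequence[float]]


def _align(a: ProfileLike, b: ProfileLike) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(a, Mapping):
        a = pd.Series(a)
    if isinstance(b, Mapping):
        b = pd.Series(b)
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        common = a.index.intersection(b.index)
        if len(common) == 0:
            raise ValueError("profiles share no parameter names")
        return a[common].to_numpy(float), b[common].to_numpy(float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    return a, b


def similarity_delta(profile_a: ProfileLike, profile_b: ProfileLike) -> float:
    """L1-overlap similarity between two profiles, in percent.

    delta = 100 * (1 - sum|a-b| / sum(|a|+|b|)); symmetric, bounded in
    [0, 100], and 100 only for identical profiles.
    """
    a, b = _align(profile_a, profile_b)
    denom = float(np.sum(np.abs(a) + np.abs(b)))
    if denom == 0:
        raise ValueError("profiles need at least one nonzero entry")
    return 100.0 * (1.0 - float(np.sum(np.abs(a - b))) / denom)


def coincidence(
    param_value: float, reference_value: float, reference_cv: float, k: float = 3.0
) -> bool:
    """Identification criterion: parameter within k reference CVs of the reference."""
    if reference_cv < 0:
        raise ValueError("reference_cv must be non-negative")
    if k <= 0:
        raise ValueError("k must be positive")
    return abs(param_value - reference_value) <= k * reference_cv * abs(reference_value)


# ---------------------------------------------------------------------------
# Catalogue and feature assembly
# ---------------------------------------------------------------------------


def compute_catalogue(
    measurement: Measurement,
    water_means: np.ndarray,
    *,
    ratio_floor_hz: float = 1.0,
) -> pd.Series:
    """The 69 calculated parameters of one (smoothed) measurement.

    ``water_means`` are the same-day mean water-vapor signals used to
    normalize responses and areas sensor-wise.  Ratio parameters with a raw
    denominator response below ``ratio_floor_hz`` propagate as NaN.
    """
    water_means = np.asarray(water_means, dtype=float)
    if water_means.shape != (N_SENSORS,) or np.any(water_means <= 0):
        raise ValueError("water_means must be 8 positive values")
    raw_resp = np.array([max_signal(c) for c in measurement.curves])
    raw_area = np.array([curve_area(c) for c in measurement.curves])
    nresp = raw_resp / water_means
    narea = raw_area / water_means
    betas = np.array([beta(c) for c in measurement.curves])

    values: Dict[str, float] = {}
    for i, j in _PAIRS:
        ok = raw_resp[j - 1] >= ratio_floor_hz
        values[f"A{i}_{j}"] = nresp[i - 1] / nresp[j - 1] if ok else float("nan")
        values[f"S{i}_{j}"] = (
            narea[i - 1] / narea[j - 1] if ok and narea[j - 1] > 0 else float("nan")
        )
    for i in range(1, N_SENSORS + 1):
        values[f"beta{i}"] = betas[i - 1]
    values["sum_response"] = float(nresp.sum())
    values["sum_area"] = float(narea.sum())
    values["mean_beta"] = float(np.nanmean(betas)) if not np.all(np.isnan(betas)) else float("nan")
    if np.all(raw_resp >= ratio_floor_hz) and nresp.min() > 0:
        values["range_ratio"] = float(nresp.max() / nresp.min())
    else:
        values["range_ratio"] = float("nan")
    mean_nresp = nresp.mean()
    if mean_nresp > 0:
        values["delta_to_water"] = similarity_delta(nresp / mean_nresp, np.ones(N_SENSORS))
    else:
        values["delta_to_water"] = float("nan")
    return pd.Series(values, index=catalogue_names(), dtype=float)


def feature_names(config: Optional[RunConfig] = None) -> List[str]:
    config = config or RunConfig()
    names = [
        f"s{i}_t{k}"
        for i in range(1, N_SENSORS + 1)
        for k in range(1, config.resample_points + 1)
    ]
    names += [f"s{i}_dFmax" for i in range(1, N_SENSORS + 1)]
    names += [f"p{n:02d}_{name}" for n, name in enumerate(catalogue_names(), start=1)]
    return names


def block_label(name: str) -> str:
    if name.startswith("p"):
        return BLOCK_PARAM
    if name.endswith("_dFmax"):
        return BLOCK_MAX
    return BLOCK_CURVE


def feature_block_labels(config: Optional[RunConfig] = None) -> Dict[str, str]:
    return {name: block_label(name) for name in feature_names(config)}


def assemble_feature_vector(
    measurement: Measurement,
    water_means: np.ndarray,
    config: Optional[RunConfig] = None,
) -> pd.Series:
    """One measurement's full feature assembly.

    Concatenates [8 x resample_points water-normalized smoothed curve points |
    8 normalized max signals | 69 calculated parameters]; 701 entries with
    the default configuration.
    """
    config = config or RunConfig()
    water_means = np.asarray(water_means, dtype=float)
    if water_means.shape != (N_SENSORS,) or np.any(water_means <= 0):
        raise ValueError("water_means must be 8 positive values")
    sm = smooth_measurement(measurement, config.sg_window, config.sg_degree)
    parts = []
    for c in sm.curves:
        parts.append(resample_curve(c, config.resample_points) / water_means[c.sensor_index - 1])
    maxes = np.array([max_signal(c) for c in sm.curves]) / water_means
    catalogue = compute_catalogue(sm, water_means, ratio_floor_hz=config.ratio_floor_hz)
    values = np.concatenate(parts + [maxes, catalogue.to_numpy()])
    return pd.Series(values, index=feature_names(config), name=measurement.measurement_id)


def assemble_feature_matrix(
    measurements: Sequence[Measurement],
    water_means_by_day: Mapping[int, np.ndarray],
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Stack feature vectors for many measurements, normalizing day by day."""
    config = config or RunConfig()
    rows = []
    for m in measurements:
        if m.day not in water_means_by_day:
            raise ValueError(f"no water reference for day {m.day}")
        rows.append(assemble_feature_vector(m, water_means_by_day[m.day], config))
    matrix = pd.DataFrame(rows)
    matrix.index.name = "measurement_id"
    return matrix


# ---------------------------------------------------------------------------
# Parameter profiles
# ---------------------------------------------------------------------------

#: Default profiling subset: kinetic shape parameters plus the efficiency
#: ratios of the most hydrophilic sensor (4) against the class-discriminating
#: sensors, the descriptors least tied to bulk milk composition.
DEFAULT_PROFILE_PARAMS = (
    "beta1", "beta2", "beta3", "beta4", "beta5", "beta6", "beta7", "beta8",
    "A3_4", "A4_5", "A4_7", "A1_4", "A2_4", "A4_6", "A4_8", "A5_7",
)


@dataclass
class ParameterProfile:
    """Replicate-averaged calculated-parameter profile with per-parameter CVs."""

    label: str
    values: pd.Series
    cv: pd.Series  # SD / |mean| per parameter, NaN where undefined


def parameter_profile(
    measurements: Sequence[Measurement],
    water_means_by_day: Mapping[int, np.ndarray],
    label: str,
    param_names: Optional[Sequence[str]] = None,
    config: Optional[RunConfig] = None,
) -> ParameterProfile:
    """Average the calculated parameters of replicate measurements into a profile."""
    config = config or RunConfig()
    param_names = list(param_names or DEFAULT_PROFILE_PARAMS)
    unknown = set(param_names) - set(catalogue_names())
    if unknown:
        raise ValueError(f"unknown catalogue parameters: {sorted(unknown)}")
    rows = []
    for m in measurements:
        sm = smooth_measurement(m, config.sg_window, config.sg_degree)
        cat = compute_catalogue(
            sm, water_means_by_day[m.day], ratio_floor_hz=config.ratio_floor_hz
        )
        rows.append(cat[param_names])
    table = pd.DataFrame(rows)
    mean = table.mean(axis=0, skipna=True)
    sd = table.std(axis=0, ddof=1)
    cv = sd / mean.abs()
    return ParameterProfile(label=label, values=mean, cv=cv)
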