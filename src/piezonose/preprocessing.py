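"""Signal conditioning: smoothing, water normalization, resampling, scaling.

The conditioning chain applied before multivariate modelling is:

1. Savitzky-Golay smoothing of each chronofrequency curve (default 3-point,
   degree 1, i.e. a centered moving average; endpoints mirrored).
2. Extraction of the analytical signal -dF_max (positive magnitude of the
   maximal shift over the sorption branch).
3. Division by the same-day, same-sensor mean water-vapor signal, which
   removes day-level sensitivity drift.
4. Linear resampling of each curve onto a fixed grid (default 78 points, so
   that 8 curves + 8 max signals + 69 calculated parameters give the
   701-element assembly).
5. Block scaling of the assembled matrix: curve-point and max-signal columns
   are autoscaled (centered, unit SD); calculated-parameter columns are only
   mean-centered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .types import ChronoCurve, Measurement, N_SENSORS, SORPTION_SECONDS

BLOCK_CURVE = "curve_point"
BLOCK_MAX = "max_signal"
BLOCK_PARAM = "calc_param"


def smooth_curve(curve: ChronoCurve, window: int = 3, degree: int = 1) -> ChronoCurve:
    """Savitzky-Golay smoothing with polynomial-fit endpoint handling.

    Endpoints are handled by fitting the edge polynomial to the terminal
    window, which keeps the filter an exact identity on polynomials up to
    its degree over the whole record (mirror padding would distort the
    ends of any non-even signal).
    """
    n = len(curve.delta_f)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > n:
        raise ValueError(f"window {window} exceeds curve length {n}")
    if degree >= window:
        raise ValueError("degree must be smaller than window")
    smoothed = savgol_filter(curve.delta_f, window, degree, mode="interp")
    return curve.copy_with(smoothed)


def smooth_measurement(m: Measurement, window: int = 3, degree: int = 1) -> Measurement:
    return Measurement(
        measurement_id=m.measurement_id,
        specimen_id=m.specimen_id,
        replicate=m.replicate,
        day=m.day,
        mode=m.mode,
        curves=[smooth_curve(c, window, degree) for c in m.curves],
        is_water_reference=m.is_water_reference,
    )


def max_signal(curve: ChronoCurve, sorption_seconds: float = SORPTION_SECONDS) -> float:
    """Analytical signal -dF_max: peak response magnitude over the sorption branch.

    Responses are defined on the negative-going branch and reported as
    positive magnitudes; the magnitude convention makes the value invariant
    to an overall sign flip of the record.
    """
    window = curve.times <= sorption_seconds + 1e-9
    if not window.any():
        raise ValueError("sorption window contains no samples")
    return float(np.max(np.abs(curve.delta_f[window])))


def normalize_to_water(
    value_or_curve: Union[float, np.ndarray], water_day_mean: float
) -> Union[float, np.ndarray]:
    """Divide a signal (or whole curve) by the day's mean water-vapor signal."""
    if not water_day_mean > 0:
        raise ValueError("water_day_mean must be positive")
    if np.isscalar(value_or_curve):
        return float(value_or_curve) / water_day_mean
    return np.asarray(value_or_curve, dtype=float) / water_day_mean


def water_day_means(measurements: Iterable[Measurement]) -> Dict[int, np.ndarray]:
    """Per-day mean water-vapor -dF_max for each sensor.

    Returns ``{day: array of 8 means}`` computed from the water-reference
    measurements only (smoothing is the caller's responsibility).
    """
    per_day: Dict[int, list] = {}
    for m in measurements:
        if not m.is_water_reference:
            continue
        per_day.setdefault(m.day, []).append(
            [max_signal(c) for c in m.curves]
        )
    if not per_day:
        raise ValueError("no water-reference measurements supplied")
    return {day: np.asarray(rows, dtype=float).mean(axis=0) for day, rows in per_day.items()}


def resample_curve(curve: ChronoCurve, n_points: int = 78) -> np.ndarray:
    """Linear interpolation of the response magnitude onto an even grid.

    The grid spans the curve's full record (endpoints preserved exactly), so
    piecewise-linear inputs are reproduced without error.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if len(curve.times) < 2:
        raise ValueError("curve too short to resample")
    grid = np.linspace(curve.times[0], curve.times[-1], n_points)
    return np.interp(grid, curve.times, np.abs(curve.delta_f))


# ---------------------------------------------------------------------------
# Block scaling
# ---------------------------------------------------------------------------


@dataclass
class ScalingRecipe:
    """Learned column-wise transform: impute -> center -> (scale for non-parameter blocks).

    ``keep`` masks out columns whose SD vanished in a scaled block; those are
    excluded from the model rather than divided by zero.
    """

    columns: pd.Index
    blocks: pd.Series  # block label per column
    means: pd.Series
    sds: pd.Series  # 1.0 for center-only (calc_param) columns
    keep: pd.Series  # bool per column

    @property
    def kept_columns(self) -> pd.Index:
        return self.columns[self.keep.to_numpy()]


def fit_block_scaling(matrix: pd.DataFrame, block_labels: Mapping[str, str]) -> ScalingRecipe:
    """Learn the block-scaling recipe on (training) rows.

    Curve-point and max-signal columns are autoscaled; calculated-parameter
    columns are centered only.  Missing entries (NaN) are imputed with the
    training column mean before statistics are taken, and a zero-SD column in
    a scaled block is flagged, excluded and reported with a warning.
    """
    unlabeled = [c for c in matrix.columns if c not in block_labels]
    if unlabeled:
        raise ValueError(f"columns without block label: {unlabeled[:5]}")
    blocks = pd.Series({c: block_labels[c] for c in matrix.columns})
    means = matrix.mean(axis=0, skipna=True)
    means = means.fillna(0.0)  # all-NaN column: impute zeros, will be dropped
    filled = matrix.fillna(means)
    sds = filled.std(axis=0, ddof=1)
    keep = pd.Series(True, index=matrix.columns)
    scale = pd.Series(1.0, index=matrix.columns)
    scaled_blocks = blocks.isin([BLOCK_CURVE, BLOCK_MAX])
    degenerate = scaled_blocks & (sds <= 0)
    if degenerate.any():
        bad = list(matrix.columns[degenerate])
        warnings.warn(
            f"{len(bad)} zero-variance column(s) excluded from scaled blocks: {bad[:5]}",
            stacklevel=2,
        )
        keep[degenerate] = False
    scale[scaled_blocks & ~degenerate] = sds[scaled_blocks & ~degenerate]
    return ScalingRecipe(
        columns=matrix.columns, blocks=blocks, means=means, sds=scale, keep=keep
    )


def apply_block_scaling(matrix: pd.DataFrame, recipe: ScalingRecipe) -> pd.DataFrame:
    """Apply a learned recipe (impute, center, scale); drops excluded columns."""
    missing = [c for c in recipe.columns if c not in matrix.columns]
    if missing:
        raise ValueError(f"matrix missing recipe columns: {missing[:5]}")
    out = matrix[recipe.columns].fillna(recipe.means)
    out = (out - recipe.means) / recipe.sds
    return out.loc[:, recipe.keep.to_numpy()]


def invert_block_scaling(matrix: pd.DataFrame, recipe: ScalingRecipe) -> pd.DataFrame:
    """Inverse of :func:`apply_block_scaling` on the kept columns."""
    cols = recipe.kept_columns
    return matrix[cols] * recipe.sds[cols] + recipe.means[cols]
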