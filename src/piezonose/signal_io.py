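"""Readers/writers for curve files, feature matrices and run configuration.

Dialect: plain CSV with "." decimal separator and "," delimiter.  Curve
files carry a metadata block of "#"-prefixed ``key: value`` lines before the
header row ``time_s,sensor_1,...,sensor_8``.  Floats are written with
``repr``-style shortest round-trip formatting, so write -> read -> write is
bitwise stable.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import ChronoCurve, Measurement, N_SENSORS

PathLike = Union[str, Path]

_SENSOR_COLUMNS = [f"sensor_{i}" for i in range(1, N_SENSORS + 1)]


class CurveFormatError(ValueError):
    """Raised when a curve file violates the dialect."""


# ---------------------------------------------------------------------------
# Curve files
# ---------------------------------------------------------------------------


def write_curve_file(measurement: Measurement, path: PathLike) -> None:
    """Write one measurement (8 curves on a shared time grid) to CSV."""
    times = measurement.curves[0].times
    for c in measurement.curves[1:]:
        if not np.array_equal(c.times, times):
            raise ValueError("all curves of a measurement must share a time grid")
    meta = {
        "measurement_id": measurement.measurement_id,
        "specimen_id": measurement.specimen_id,
        "replicate": measurement.replicate,
        "day": measurement.day,
        "mode": measurement.mode,
        "is_water_reference": int(measurement.is_water_reference),
    }
    buf = io.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key}: {value}\n")
    buf.write("time_s," + ",".join(_SENSOR_COLUMNS) + "\n")
    for k, t in enumerate(times):
        row = [repr(float(t))] + [repr(float(c.delta_f[k])) for c in measurement.curves]
        buf.write(",".join(row) + "\n")
    Path(path).write_text(buf.getvalue(), newline="\n")


def read_curve_file(path: PathLike) -> Measurement:
    """Read a curve file back into a :class:`Measurement`.

    Raises :class:`CurveFormatError` with a distinct diagnostic for a
    malformed header, a missing sensor column, an empty table or a
    non-monotone time axis.
    """
    text = Path(path).read_text()
    meta: Dict[str, str] = {}
    lines = text.splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" not in line:
                raise CurveFormatError(f"malformed metadata line: {line!r}")
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
        else:
            body_start = i
            break
    else:
        raise CurveFormatError("no header row found")
    header = lines[body_start].split(",")
    if header[0] != "time_s":
        raise CurveFormatError(f"malformed header: first column must be time_s, got {header[0]!r}")
    missing = [c for c in _SENSOR_COLUMNS if c not in header]
    if missing:
        raise CurveFormatError(f"missing sensor column(s): {', '.join(missing)}")
    table = pd.read_csv(
        io.StringIO("\n".join(lines[body_start:])), float_precision="round_trip"
    )
    if table.empty:
        raise CurveFormatError("no samples in curve table")
    times = table["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise CurveFormatError("non-monotone time axis")
    required = {"measurement_id", "specimen_id", "replicate", "day", "mode"}
    if not required.issubset(meta):
        raise CurveFormatError(
            f"metadata block missing keys: {sorted(required - set(meta))}"
        )
    mode = meta["mode"]
    curves = [
        ChronoCurve(i, times, table[f"sensor_{i}"].to_numpy(dtype=float), mode)
        for i in range(1, N_SENSORS + 1)
    ]
    return Measurement(
        measurement_id=meta["measurement_id"],
        specimen_id=meta["specimen_id"],
        replicate=int(meta["replicate"]),
        day=int(meta["day"]),
        mode=mode,
        curves=curves,
        is_water_reference=bool(int(meta.get("is_water_reference", "0"))),
    )


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

FULL_FEATURE_WIDTH = 701


def write_feature_matrix(matrix: pd.DataFrame, path: PathLike) -> None:
    """Write a feature matrix (rows = measurements) with measurement_id first.

    Warns when the column count is not the full 701-element assembly, so
    partial matrices are visible but not forbidden.
    """
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate measurement_id(s): {dupes}")
    if matrix.shape[1] != FULL_FEATURE_WIDTH:
        import warnings

        warnings.warn(
            f"feature matrix has {matrix.shape[1]} columns, expected {FULL_FEATURE_WIDTH}",
            stacklevel=2,
        )
    out = matrix.copy()
    out.index.name = "measurement_id"
    out.to_csv(path, lineterminator="\n")


def read_feature_matrix(path: PathLike) -> pd.DataFrame:
    matrix = pd.read_csv(path, index_col="measurement_id", float_precision="round_trip")
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate measurement_id(s): {dupes}")
    return matrix


def write_specimen_table(specimens, path: PathLike) -> None:
    """Specimen inventory as a flat CSV table."""
    rows = [
        {
            "specimen_id": s.specimen_id,
            "farm_id": s.farm_id,
            "qmafanm": s.qmafanm,
            "yeast": s.yeast,
            "mold": s.mold,
            "fat": s.fat,
            "protein": s.protein,
            "ultrasound": int(s.ultrasound_treated),
        }
        for s in specimens
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def read_calibration_series(path: PathLike):
    """Read a calibration series CSV with columns concentration, signal, is_blank.

    Optional "#"-prefixed metadata lines may set ``analyte`` and
    ``sensor_index``.
    """
    from .types import CalibrationSeries

    text = Path(path).read_text()
    meta: Dict[str, str] = {}
    body = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
        else:
            body.append(line)
    table = pd.read_csv(io.StringIO("\n".join(body)))
    required = {"concentration", "signal", "is_blank"}
    if not required.issubset(table.columns):
        raise ValueError(f"calibration CSV needs columns {sorted(required)}")
    blanks = table[table["is_blank"].astype(bool)]
    points = table[~table["is_blank"].astype(bool)]
    return CalibrationSeries(
        analyte=meta.get("analyte", "unknown"),
        sensor_index=int(meta.get("sensor_index", "1")),
        concentrations=points["concentration"].to_numpy(float),
        signals=points["signal"].to_numpy(float),
        blank_signals=blanks["signal"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All tunables of the analysis pipeline, serializable as key = value text."""

    mode: str = "injected"
    resample_points: int = 78
    sg_window: int = 3
    sg_degree: int = 1
    pls_max_factors: int = 10
    vs_coef_quantile: float = 0.25
    vs_leverage_multiplier: float = 2.0
    vs_rmsep_tolerance: float = 0.15
    vs_max_iter: int = 12
    lod_k: float = 3.3
    ratio_floor_hz: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.resample_points < 2:
            raise ValueError("resample_points must be >= 2")
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_degree >= self.sg_window:
            raise ValueError("sg_degree must be smaller than sg_window")
        if self.lod_k <= 0:
            raise ValueError("lod_k must be positive")
        if not 0.0 <= self.vs_coef_quantile < 1.0:
            raise ValueError("vs_coef_quantile must be in [0, 1)")

    def to_file(self, path: PathLike) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: PathLike) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"mode": str}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key: {key}")
            if key in casts:
                kwargs[key] = casts[key](value)
            elif types[key] in ("int", int):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)
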