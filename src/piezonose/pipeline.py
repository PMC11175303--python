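"""End-to-end orchestration: simulate -> featurize -> train -> predict -> profile.

``run_study_fixture`` reproduces the study design in silico: 16 specimens
measured in triplicate (48 measurements), the same specimens after
ultrasound treatment (used for the yeast/mold models), daily water-vapor
references, a four-specimen held-out test set, per-farm calculated-parameter
profiles and their similarity matrix.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import (
    DEFAULT_PROFILE_PARAMS,
    ParameterProfile,
    assemble_feature_matrix,
    parameter_profile,
    similarity_delta,
)
from .preprocessing import smooth_measurement, water_day_means
from .regression import IndicatorModel, predict, train_indicator
from .sensors import default_sensor_array
from .signal_io import (
    RunConfig,
    write_feature_matrix,
    write_specimen_table,
)
from .synthetic_data import (
    default_emission_params,
    generate_day_gains,
    generate_specimen_inventory,
    generate_test_specimens,
    simulate_measurement,
    simulate_water_reference,
)
from .types import Measurement, MilkSpecimen

logger = logging.getLogger("piezonose")

INDICATORS = ("qmafanm", "yeast", "mold")

#: replicates per specimen and water references per day, as in the study
N_REPLICATES = 3
N_WATER_REPLICATES = 3


@dataclass
class RunManifest:
    """Traceability record for one pipeline run."""

    seed: int
    config: Dict
    artifacts: Dict[str, str] = field(default_factory=dict)
    timings_s: Dict[str, float] = field(default_factory=dict)
    version: str = "piezonose-0.1.0"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


@dataclass
class StudyResult:
    manifest: RunManifest
    specimens: List[MilkSpecimen]
    feature_matrix: pd.DataFrame  # 48 x 701, untreated milk
    feature_matrix_us: pd.DataFrame  # 48 x 701, after ultrasound
    targets: pd.DataFrame  # lg targets per untreated measurement
    models: Dict[str, IndicatorModel]
    test_table: pd.DataFrame  # per held-out specimen: predicted +/- dev vs reference
    profiles: List[ParameterProfile]
    delta_matrix: pd.DataFrame
    closest_pair: Tuple[str, str, float]


def _simulate_set(
    specimens: Sequence[MilkSpecimen],
    sensor_array,
    mode: str,
    rng: np.random.Generator,
    day_gains: np.ndarray,
    emission,
    day_of: Mapping[str, int],
    tag: str = "",
) -> List[Measurement]:
    out = []
    for spec in specimens:
        day = day_of[spec.specimen_id]
        for rep in range(1, N_REPLICATES + 1):
            out.append(
                simulate_measurement(
                    spec,
                    sensor_array,
                    mode,
                    day,
                    rep,
                    rng,
                    emission=emission,
                    day_gains=day_gains[day],
                    measurement_id=f"{spec.specimen_id}{tag}_{mode}_d{day}_r{rep}",
                )
            )
    return out


def _targets(measurements: Sequence[Measurement], by_id: Mapping[str, MilkSpecimen]) -> pd.DataFrame:
    rows = {
        m.measurement_id: {
            "specimen_id": m.specimen_id,
            "qmafanm": by_id[m.specimen_id].lg_qmafanm,
            "yeast": by_id[m.specimen_id].lg_yeast,
            "mold": by_id[m.specimen_id].lg_mold,
        }
        for m in measurements
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def run_study_fixture(
    config: Optional[RunConfig] = None,
    seed: int = 1,
    out_dir: Optional[str] = None,
) -> StudyResult:
    """Run the full synthetic study and train all three indicator models."""
    config = config or RunConfig()
    t0 = time.perf_counter()
    manifest = RunManifest(seed=seed, config=config.__dict__.copy())
    ss = np.random.SeedSequence(seed)
    rng_gain, rng_water, rng_milk, rng_us, rng_test = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    sensor_array = default_sensor_array()
    emission = default_emission_params()

    logger.info("[simulate] generating specimen inventory and measurements")
    specimens = generate_specimen_inventory()
    test_specimens = generate_test_specimens()
    n_days = (len(specimens) + 2) // 3  # three specimens measured per day
    day_of = {s.specimen_id: i // 3 for i, s in enumerate(specimens)}
    day_of.update({s.specimen_id: k % n_days for k, s in enumerate(test_specimens)})
    day_gains = generate_day_gains(n_days, rng_gain)

    water_refs = [
        simulate_water_reference(
            sensor_array,
            config.mode,
            day,
            rng_water,
            emission=emission,
            day_gains=day_gains[day],
            replicate=rep,
        )
        for day in range(n_days)
        for rep in range(1, N_WATER_REPLICATES + 1)
    ]
    milk = _simulate_set(
        specimens, sensor_array, config.mode, rng_milk, day_gains, emission, day_of
    )
    us_specimens = [replace(s, ultrasound_treated=True) for s in specimens]
    milk_us = _simulate_set(
        us_specimens, sensor_array, config.mode, rng_us, day_gains, emission, day_of, tag="u"
    )
    test = _simulate_set(
        test_specimens, sensor_array, config.mode, rng_test, day_gains, emission, day_of
    )
    us_test = [replace(s, ultrasound_treated=True) for s in test_specimens]
    test_us = _simulate_set(
        us_test, sensor_array, config.mode, rng_test, day_gains, emission, day_of, tag="u"
    )
    manifest.timings_s["simulate"] = time.perf_counter() - t0

    logger.info("[featurize] assembling feature matrices")
    t1 = time.perf_counter()
    smoothed_refs = [
        smooth_measurement(m, config.sg_window, config.sg_degree) for m in water_refs
    ]
    wm = water_day_means(smoothed_refs)
    X = assemble_feature_matrix(milk, wm, config)
    X_us = assemble_feature_matrix(milk_us, wm, config)
    X_test = assemble_feature_matrix(test, wm, config)
    X_test_us = assemble_feature_matrix(test_us, wm, config)
    by_id = {s.specimen_id: s for s in specimens + test_specimens}
    y = _targets(milk, by_id)
    y_us = _targets(milk_us, by_id)
    manifest.timings_s["featurize"] = time.perf_counter() - t1

    logger.info("[train] fitting PLS models with variable selection")
    t2 = time.perf_counter()
    models: Dict[str, IndicatorModel] = {}
    models["qmafanm"] = train_indicator(
        X, y["qmafanm"].to_numpy(), "qmafanm", config, groups=y["specimen_id"]
    )
    models["yeast"] = train_indicator(
        X_us, y_us["yeast"].to_numpy(), "yeast", config, groups=y_us["specimen_id"]
    )
    models["mold"] = train_indicator(
        X_us, y_us["mold"].to_numpy(), "mold", config, groups=y_us["specimen_id"]
    )
    manifest.timings_s["train"] = time.perf_counter() - t2

    logger.info("[predict] held-out test specimens")
    t3 = time.perf_counter()
    rows = []
    for spec in test_specimens:
        row: Dict[str, float] = {"specimen_id": spec.specimen_id}
        for indicator in INDICATORS:
            im = models[indicator]
            matrix = X_test if indicator == "qmafanm" else X_test_us
            tag = "" if indicator == "qmafanm" else "u"
            ids = [
                f"{spec.specimen_id}{tag}_{config.mode}_d{day_of[spec.specimen_id]}_r{r}"
                for r in range(1, N_REPLICATES + 1)
            ]
            yhat, dev = predict(im.model, matrix.loc[ids])
            row[f"{indicator}_pred"] = float(np.mean(yhat))
            row[f"{indicator}_dev"] = float(np.mean(dev))
            row[f"{indicator}_ref"] = getattr(by_id[spec.specimen_id], f"lg_{indicator}")
        rows.append(row)
    test_table = pd.DataFrame(rows).set_index("specimen_id")
    manifest.timings_s["predict"] = time.perf_counter() - t3

    logger.info("[profile] per-farm calculated-parameter profiles")
    t4 = time.perf_counter()
    farms = sorted({s.farm_id for s in specimens if s.farm_id != "standard"})
    profiles = []
    for farm in farms:
        farm_ids = {s.specimen_id for s in specimens if s.farm_id == farm}
        farm_measurements = [m for m in milk if m.specimen_id in farm_ids]
        profiles.append(
            parameter_profile(farm_measurements, wm, farm, DEFAULT_PROFILE_PARAMS, config)
        )
    delta_matrix, closest = compare_profiles(profiles)
    manifest.timings_s["profile"] = time.perf_counter() - t4

    result = StudyResult(
        manifest=manifest,
        specimens=specimens,
        feature_matrix=X,
        feature_matrix_us=X_us,
        targets=y,
        models=models,
        test_table=test_table,
        profiles=profiles,
        delta_matrix=delta_matrix,
        closest_pair=closest,
    )
    if out_dir is not None:
        _write_artifacts(result, config, out_dir)
    return result


def compare_profiles(
    profiles: Sequence[ParameterProfile],
) -> Tuple[pd.DataFrame, Tuple[str, str, float]]:
    """Pairwise similarity matrix of profiles and the most similar pair."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to compare")
    labels = [p.label for p in profiles]
    n = len(profiles)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            d = similarity_delta(profiles[i].values, profiles[j].values)
            mat[i, j] = mat[j, i] = d
    frame = pd.DataFrame(mat, index=labels, columns=labels)
    best = (None, None, -np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] > best[2]:
                best = (labels[i], labels[j], float(mat[i, j]))
    return frame, best


def _write_artifacts(result: StudyResult, config: RunConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "specimens": out / "specimens.csv",
        "feature_matrix": out / "feature_matrix.csv",
        "feature_matrix_us": out / "feature_matrix_ultrasound.csv",
        "targets": out / "targets.csv",
        "model_reports": out / "model_reports.csv",
        "test_predictions": out / "test_predictions.csv",
        "profiles": out / "farm_profiles.csv",
        "profile_similarity": out / "profile_similarity.csv",
        "config": out / "run_config.txt",
        "manifest": out / "manifest.json",
    }
    write_specimen_table(result.specimens, paths["specimens"])
    write_feature_matrix(result.feature_matrix, paths["feature_matrix"])
    write_feature_matrix(result.feature_matrix_us, paths["feature_matrix_us"])
    result.targets.rename_axis("measurement_id").to_csv(paths["targets"], lineterminator="\n")
    reports = pd.DataFrame(
        {
            name: {
                "rmsep": m.report.rmsep,
                "r_squared": m.report.r_squared,
                "delta_pct": m.report.delta_pct,
                "n_factors": m.report.n_factors,
                "n_curve_points": m.report.n_curve_points,
                "n_calc_params": m.report.n_calc_params,
            }
            for name, m in result.models.items()
        }
    ).T.rename_axis("indicator")
    reports.to_csv(paths["model_reports"], lineterminator="\n")
    result.test_table.to_csv(paths["test_predictions"], lineterminator="\n")
    prof = pd.DataFrame({p.label: p.values for p in result.profiles}).rename_axis("parameter")
    prof.to_csv(paths["profiles"], lineterminator="\n")
    result.delta_matrix.rename_axis("farm").to_csv(
        paths["profile_similarity"], lineterminator="\n"
    )
    config.to_file(paths["config"])
    result.manifest.artifacts = {k: str(v) for k, v in paths.items()}
    result.manifest.to_json(paths["manifest"])
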