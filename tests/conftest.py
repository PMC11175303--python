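import numpy as np
import pytest

from piezonose.pipeline import run_study_fixture
from piezonose.sensors import default_sensor_array
from piezonose.synthetic_data import (
    ClassEmission,
    EmissionParams,
    default_emission_params,
)
from piezonose.types import ChronoCurve, Measurement, VOC_CLASSES


@pytest.fixture(scope="session")
def sensor_array():
    return default_sensor_array()


@pytest.fixture()
def noiseless_array(sensor_array):
    """The default array with point noise switched off."""
    from dataclasses import replace

    return [replace(s, noise_level=0.0) for s in sensor_array]


@pytest.fixture()
def silent_emission():
    """Default emission coefficients with all scatter switched off."""
    p = default_emission_params()
    return EmissionParams(
        coefficients=p.coefficients,
        noise_sigma=0.0,
        water_sigma=0.0,
        ultrasound_boost=p.ultrasound_boost,
    )


@pytest.fixture(scope="session")
def study():
    """One full seeded study run, shared across tests (seconds to build)."""
    return run_study_fixture(seed=1)


def make_curve(sensor_index=1, mode="injected", fn=None, dt=1.0):
    """Helper: build a curve from a response-magnitude function of time."""
    from piezonose.types import FRONTAL_SECONDS, INJECTED_SECONDS

    total = INJECTED_SECONDS if mode == "injected" else FRONTAL_SECONDS
    times = np.arange(0.0, total + dt / 2, dt)
    resp = np.zeros_like(times) if fn is None else np.asarray([fn(t) for t in times])
    return ChronoCurve(sensor_index, times, -resp, mode)


def make_measurement(resp_fns, mode="injected", **kwargs):
    """Helper: 8-curve measurement from per-sensor response functions."""
    curves = [make_curve(i, mode, resp_fns.get(i)) for i in range(1, 9)]
    defaults = dict(
        measurement_id="m", specimen_id="s", replicate=1, day=0, mode=mode, curves=curves
    )
    defaults.update(kwargs)
    return Measurement(**defaults)
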