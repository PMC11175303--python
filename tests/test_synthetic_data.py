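"""Generator tests: inventory, emission model, curve synthesis, calibration series."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from piezonose.preprocessing import max_signal
from piezonose.sensors import WATER_SENSITIVITY, default_sensor_array
from piezonose.synthetic_data import (
    ClassEmission,
    EmissionParams,
    default_emission_params,
    emit_voc_profile,
    generate_specimen_inventory,
    simulate_calibration_series,
    simulate_measurement,
    simulate_water_reference,
)
from piezonose.types import (
    FRONTAL_SECONDS,
    INJECTED_SECONDS,
    MilkSpecimen,
    SORPTION_SECONDS,
    VOC_CLASSES,
    lg,
)


def flat_emission(c0=1.0):
    return EmissionParams(
        coefficients={c: ClassEmission(c0=c0) for c in VOC_CLASSES},
        noise_sigma=0.0,
        water_sigma=0.0,
    )


class TestInventory:
    def test_default_fixture_has_16_specimens(self):
        specs = generate_specimen_inventory()
        assert len(specs) == 16
        assert sum(s.farm_id == "standard" for s in specs) == 2

    def test_specimen_8_counts_and_lg(self):
        specs = {s.specimen_id: s for s in generate_specimen_inventory()}
        assert specs["8"].qmafanm == 9.8e7
        assert round(specs["8"].lg_qmafanm, 2) == 7.99

    def test_zero_count_lg_floor_rule(self):
        specs = {s.specimen_id: s for s in generate_specimen_inventory()}
        assert specs["4"].yeast == 0.0
        assert specs["4"].lg_yeast == 0.0
        assert lg(0.0) == 0.0
        assert lg(0.5) == 0.0

    def test_randomized_mode_respects_ranges(self):
        cfg = {"n": 10, "lg_qmafanm_range": (4.0, 6.0)}
        specs = generate_specimen_inventory(cfg, seed=3)
        assert len(specs) == 10
        assert all(4.0 <= s.lg_qmafanm <= 6.0 for s in specs)

    def test_negative_range_rejected(self):
        with pytest.raises(ValueError):
            generate_specimen_inventory({"lg_yeast_range": (-1.0, 2.0)}, seed=0)

    def test_specimen_invariants_enforced(self):
        with pytest.raises(ValueError):
            MilkSpecimen("x", "f", qmafanm=-1, yeast=0, mold=0, fat=4, protein=3)
        with pytest.raises(ValueError):
            MilkSpecimen("x", "f", qmafanm=1, yeast=0, mold=0, fat=104, protein=3)


class TestEmission:
    def test_constant_intercept_only(self):
        spec = MilkSpecimen("x", "f", 1e6, 1e3, 10, fat=4.0, protein=3.0)
        profile = emit_voc_profile(spec, flat_emission(c0=1.0), np.random.default_rng(0))
        assert all(profile[c] == 1.0 for c in VOC_CLASSES)

    def test_linear_form(self):
        params = flat_emission(c0=0.0)
        params.coefficients["acids"] = ClassEmission(c0=0.0, a=0.05)
        spec = MilkSpecimen("x", "f", 10**6, 0, 0, fat=0.0, protein=0.0)
        profile = emit_voc_profile(spec, params, np.random.default_rng(0))
        assert profile["acids"] == pytest.approx(0.30)

    def test_monotone_in_bacterial_load(self):
        params = flat_emission(c0=0.0)
        params.coefficients["acids"] = ClassEmission(c0=0.1, a=0.05)
        rng = np.random.default_rng(0)
        low = MilkSpecimen("a", "f", 10**4, 0, 0, fat=0, protein=0)
        high = MilkSpecimen("b", "f", 10**8, 0, 0, fat=0, protein=0)
        assert emit_voc_profile(high, params, rng)["acids"] > emit_voc_profile(
            low, params, rng
        )["acids"]

    def test_ultrasound_boosts_yeast_and_mold_classes(self):
        params = flat_emission(c0=0.0)
        params.coefficients["alcohols"] = ClassEmission(c0=0.0, b=0.1)
        spec = MilkSpecimen("x", "f", 0, 10**3, 0, fat=0, protein=0)
        from dataclasses import replace

        rng = np.random.default_rng(0)
        plain = emit_voc_profile(spec, params, rng)["alcohols"]
        boosted = emit_voc_profile(
            replace(spec, ultrasound_treated=True), params, rng
        )["alcohols"]
        assert boosted == pytest.approx(2.0 * plain)

    def test_missing_class_coefficient_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            EmissionParams(coefficients={"acids": ClassEmission(c0=1.0)})


class TestCurves:
    def test_zero_concentration_gives_flat_curves(self, noiseless_array):
        spec = MilkSpecimen("x", "f", 0, 0, 0, fat=0, protein=0)
        m = simulate_measurement(
            spec, noiseless_array, "injected", 0, 1,
            np.random.default_rng(0), emission=flat_emission(c0=0.0),
        )
        for c in m.curves:
            assert np.allclose(c.delta_f, 0.0)

    def test_frontal_sorption_fraction_matches_first_order_kinetics(self, noiseless_array):
        from dataclasses import replace

        arr = [replace(s, sorption_time_constant=20.0) for s in noiseless_array]
        spec = MilkSpecimen("x", "f", 1e6, 0, 0, fat=4, protein=3)
        m = simulate_measurement(
            spec, arr, "frontal", 0, 1, np.random.default_rng(0),
            emission=flat_emission(c0=1.0),
        )
        for c in m.curves:
            at_40 = -np.interp(40.0, c.times, c.delta_f)
            plateau_inf = at_40 / (1 - np.exp(-2.0))
            assert at_40 / plateau_inf == pytest.approx(1 - np.exp(-2.0), rel=1e-12)

    def test_mode_gain_is_exact_ratio_of_max_signals(self, noiseless_array):
        spec = MilkSpecimen("x", "f", 1e6, 1e3, 10, fat=4, protein=3)
        emission = flat_emission(c0=0.5)
        inj = simulate_measurement(
            spec, noiseless_array, "injected", 0, 1, np.random.default_rng(0),
            emission=emission,
        )
        fro = simulate_measurement(
            spec, noiseless_array, "frontal", 0, 1, np.random.default_rng(0),
            emission=emission,
        )
        for s, ci, cf in zip(noiseless_array, inj.curves, fro.curves):
            assert max_signal(cf) / max_signal(ci) == pytest.approx(
                s.mode_gain_frontal, rel=1e-12
            )

    def test_unknown_mode_rejected(self, sensor_array):
        spec = MilkSpecimen("x", "f", 1e6, 0, 0, fat=4, protein=3)
        with pytest.raises(ValueError, match="mode"):
            simulate_measurement(spec, sensor_array, "sideways", 0, 1, np.random.default_rng(0))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        mode=st.sampled_from(["injected", "frontal"]),
        lgq=st.floats(min_value=0, max_value=8),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_generated_curves_satisfy_span_invariants(self, mode, lgq, seed):
        spec = MilkSpecimen("x", "f", 10**lgq, 0, 0, fat=4, protein=3)
        m = simulate_measurement(
            spec, default_sensor_array(), mode, 0, 1, np.random.default_rng(seed)
        )
        span = INJECTED_SECONDS if mode == "injected" else FRONTAL_SECONDS
        for c in m.curves:
            assert c.times[0] == 0.0 and c.times[-1] == span
            assert np.all(np.diff(c.times) > 0)


class TestWaterReference:
    def test_noiseless_water_signal_equals_sensitivity_times_concentration(
        self, noiseless_array, silent_emission
    ):
        m = simulate_water_reference(
            noiseless_array, "injected", 0, np.random.default_rng(0),
            emission=silent_emission,
        )
        assert m.is_water_reference
        c_water = silent_emission.coefficients["water"].c0
        for s, c in zip(noiseless_array, m.curves):
            expected = s.class_sensitivity["water"] * c_water * (
                1 - np.exp(-SORPTION_SECONDS / s.sorption_time_constant)
            )
            assert max_signal(c) == pytest.approx(expected, rel=1e-9)

    def test_same_seed_reproduces_reference(self, sensor_array):
        a = simulate_water_reference(sensor_array, "frontal", 0, np.random.default_rng(5))
        b = simulate_water_reference(sensor_array, "frontal", 0, np.random.default_rng(5))
        for ca, cb in zip(a.curves, b.curves):
            assert np.array_equal(ca.delta_f, cb.delta_f)

    def test_daily_replicates_cv_within_5_percent(self, sensor_array):
        rng = np.random.default_rng(2)
        sigs = np.array(
            [
                [max_signal(c) for c in simulate_water_reference(
                    sensor_array, "injected", 0, rng, replicate=r
                ).curves]
                for r in range(1, 9)
            ]
        )
        cv = sigs.std(axis=0, ddof=1) / sigs.mean(axis=0)
        assert np.all(cv <= 0.05)


class TestFixtureShape:
    def test_48_measurements_per_mode(self, sensor_array):
        rng = np.random.default_rng(0)
        specs = generate_specimen_inventory()
        ms = [
            simulate_measurement(s, sensor_array, "injected", i // 3, r, rng)
            for i, s in enumerate(specs)
            for r in (1, 2, 3)
        ]
        assert len(ms) == 48
        assert len({m.measurement_id for m in ms}) == 48


class TestCalibrationSeries:
    def test_noiseless_line(self, noiseless_array):
        series = simulate_calibration_series(
            "acetic_acid", [0.1, 1.0, 10.0], noiseless_array[0], 3,
            np.random.default_rng(0), slope=100.0, blank_level=0.0,
        )
        assert np.allclose(series.signals, [10.0, 100.0, 1000.0])
        assert np.allclose(series.blank_signals, 0.0)

    def test_zero_noise_blank_sd_gives_zero_lod(self, noiseless_array):
        from piezonose.calibration import fit_calibration, lod

        series = simulate_calibration_series(
            "acetic_acid", [1.0, 2.0, 3.0], noiseless_array[0], 3, np.random.default_rng(0)
        )
        assert lod(fit_calibration(series)) == 0.0

    def test_too_few_concentrations_rejected(self, sensor_array):
        with pytest.raises(ValueError, match="distinct"):
            simulate_calibration_series(
                "acetic_acid", [1.0, 1.0], sensor_array[0], 3, np.random.default_rng(0)
            )

    def test_too_few_blanks_rejected(self, sensor_array):
        with pytest.raises(ValueError, match="blank"):
            simulate_calibration_series(
                "acetic_acid", [1.0, 2.0], sensor_array[0], 2, np.random.default_rng(0)
            )
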