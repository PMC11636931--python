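"""Array geometry, the ray/phase-screen forward model and time reversal."""

import numpy as np
import pytest

from prfocus.array_acoustics import (
    ArrayGeometry,
    SourceSignal,
    TransferMatrix,
    aperture_permutation,
    compute_tm,
    field_map,
    make_hemisphere_array,
    time_reversal,
)
from prfocus.skull_model import AcousticHeadModel, PropertyMap

WATER = PropertyMap()
SIGNAL = SourceSignal(frequency=250e3)


def water_model(shape=(60, 60, 60), spacing=4.0):
    return AcousticHeadModel.uniform_water(shape, spacing, (0, 0, 0), WATER)


class TestHemisphereArray:
    def test_single_element_sits_at_apex(self):
        arr = make_hemisphere_array(1, radius=0.1, centre=(0, 0, 0))
        np.testing.assert_allclose(arr.element_positions, [[0, 0, 0.1]])

    def test_all_elements_on_sphere_radius(self):
        arr = make_hemisphere_array(128, radius=0.1, centre=(0.11, 0.11, 0.08))
        d = np.linalg.norm(arr.element_positions - np.array([0.11, 0.11, 0.08]), axis=1)
        np.testing.assert_allclose(d, 0.1, atol=1e-12)
        assert np.all(arr.element_positions[:, 2] >= 0.08 - 1e-12)  # upper hemisphere

    def test_elements_distinct_and_seed_deterministic(self):
        a = make_hemisphere_array(64, seed=5)
        b = make_hemisphere_array(64, seed=5)
        np.testing.assert_array_equal(a.element_positions, b.element_positions)
        diff = a.element_positions[:, None] - a.element_positions[None]
        pairwise = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(pairwise, np.inf)
        assert pairwise.min() > 0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_hemisphere_array(0)
        with pytest.raises(ValueError):
            make_hemisphere_array(4, radius=-1.0)

    def test_aperture_permutation_is_a_permutation(self):
        arr = make_hemisphere_array(128)
        perm = aperture_permutation(arr, (16, 8))
        assert sorted(perm) == list(range(128))


class TestForwardModel:
    def test_uniform_water_matches_greens_function(self):
        model = water_model()
        arr = make_hemisphere_array(16, radius=0.08, centre=(0.12, 0.12, 0.1))
        targets = np.array([[0.12, 0.12, 0.1], [0.1, 0.13, 0.09]])
        tm = compute_tm(model, arr, targets, SIGNAL)
        r = np.linalg.norm(
            targets[:, None, :] - arr.element_positions[None, :, :], axis=-1
        )
        expected = (1.0 / r) * np.exp(-WATER.alpha_water * r) * np.exp(
            -2j * np.pi * SIGNAL.frequency * r / WATER.c_water
        )
        # phase must be exact to machine precision in a homogeneous medium
        np.testing.assert_allclose(
            np.angle(tm.values / expected), 0.0, atol=1e-9
        )
        np.testing.assert_allclose(np.abs(tm.values), np.abs(expected), rtol=1e-9)

    def test_slab_adds_two_layer_analytic_delay(self):
        shape, spacing = (60, 60, 60), 4.0
        model = water_model(shape, spacing)
        slab_speed = 2600.0
        # slab spanning z voxel indices 20..29 (40 mm thick), normal incidence
        model.speed[:, :, 20:30] = slab_speed
        d = 10 * spacing / 1000.0
        arr = ArrayGeometry([[0.118, 0.118, 0.22]], radius=0.1, centre=(0.118, 0.118, 0.12))
        target = [[0.118, 0.118, 0.02]]
        h_water = compute_tm(water_model(shape, spacing), arr, target, SIGNAL).values[0, 0]
        h_slab = compute_tm(model, arr, target, SIGNAL).values[0, 0]
        expected_delta = -2 * np.pi * SIGNAL.frequency * d * (1 / slab_speed - 1 / WATER.c_water)
        measured_delta = np.angle(h_slab / h_water)
        wrapped_error = (measured_delta - expected_delta + np.pi) % (2 * np.pi) - np.pi
        assert wrapped_error == pytest.approx(0.0, abs=1e-6)

    def test_zero_attenuation_gives_inverse_distance_amplitude(self):
        model = water_model()
        model.attenuation[:] = 0.0
        arr = make_hemisphere_array(12, radius=0.06, centre=(0.12, 0.12, 0.1))
        tm = compute_tm(model, arr, [[0.1, 0.1, 0.08]], SIGNAL)
        r = np.linalg.norm(arr.element_positions - np.array([0.1, 0.1, 0.08]), axis=1)
        np.testing.assert_allclose(np.abs(tm.values[0]) * r, 1.0, rtol=1e-12)

    def test_reciprocity_swapping_endpoints(self):
        model = water_model()
        model.speed[:, :, 25:35] = 2400.0  # heterogeneous region
        p_a = np.array([0.04, 0.12, 0.2])
        p_b = np.array([0.16, 0.1, 0.04])
        arr_a = ArrayGeometry([p_a], radius=0.1, centre=p_a - [0, 0, 0.1])
        arr_b = ArrayGeometry([p_b], radius=0.1, centre=p_b - [0, 0, 0.1])
        h_ab = compute_tm(model, arr_a, [p_b], SIGNAL).values[0, 0]
        h_ba = compute_tm(model, arr_b, [p_a], SIGNAL).values[0, 0]
        assert h_ab == pytest.approx(h_ba, rel=1e-12)

    def test_ray_leaving_grid_is_an_error(self):
        model = water_model((30, 30, 30), 4.0)
        arr = ArrayGeometry([[0.06, 0.06, 0.3]], radius=0.1, centre=(0.06, 0.06, 0.2))
        with pytest.raises(ValueError, match="exits the model grid"):
            compute_tm(model, arr, [[0.06, 0.06, 0.05]], SIGNAL)

    def test_target_on_element_is_an_error(self):
        model = water_model()
        arr = ArrayGeometry([[0.1, 0.1, 0.1]], radius=0.05, centre=(0.1, 0.1, 0.05))
        with pytest.raises(ValueError, match="coincides"):
            compute_tm(model, arr, [[0.1, 0.1, 0.1]], SIGNAL)


class TestTimeReversal:
    def test_hand_computed_conjugate_row(self):
        tm = TransferMatrix([[1.0, 1j]], [[0, 0, 0]], "true_model")
        e0 = time_reversal(tm, 0, normalize=False)
        np.testing.assert_array_equal(e0, [1.0, -1j])
        # induced target magnitude equals sum |h|^2 before normalization
        assert abs(tm.values[0] @ e0) == pytest.approx(2.0)

    def test_single_element_row_recovers_full_pressure(self):
        tm = TransferMatrix([[3.0 - 4.0j]], [[0, 0, 0]], "true_model")
        e0 = time_reversal(tm, 0)
        assert abs(tm.values[0] @ e0) == pytest.approx(5.0)  # = ||h|| = GS

    def test_zero_row_rejected(self):
        tm = TransferMatrix([[0.0, 0.0]], [[0, 0, 0]], "true_model")
        with pytest.raises(ValueError, match="zero"):
            time_reversal(tm, 0)

    def test_cauchy_schwarz_optimality_brute_force(self, rng):
        h = rng.standard_normal(32) + 1j * rng.standard_normal(32)
        tm = TransferMatrix([h], [[0, 0, 0]], "true_model")
        e0 = time_reversal(tm, 0)
        best = abs(h @ e0)
        for _ in range(10_000):
            e = rng.standard_normal(32) + 1j * rng.standard_normal(32)
            e /= np.linalg.norm(e)
            assert abs(h @ e) <= best + 1e-9


class TestFieldMap:
    def test_water_tr_focus_lands_on_target(self):
        model = water_model()
        arr = make_hemisphere_array(32, radius=0.08, centre=(0.12, 0.12, 0.1))
        target = np.array([0.12, 0.12, 0.1])
        tm = compute_tm(model, arr, [target], SIGNAL)
        e0 = time_reversal(tm, 0)
        fm = field_map(model, arr, e0, target, shape=(9, 9, 9), spacing_mm=4.0, signal=SIGNAL)
        assert fm.argmax_index() == (4, 4, 4)
        np.testing.assert_allclose(fm.argmax_position_m(), target, atol=1e-12)

    def test_map_value_consistent_with_tm_prediction(self, rng):
        model = water_model()
        arr = make_hemisphere_array(16, radius=0.08, centre=(0.12, 0.12, 0.1))
        target = np.array([0.1, 0.12, 0.08])
        e = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        tm = compute_tm(model, arr, [target], SIGNAL)
        fm = field_map(model, arr, e, target, shape=(3, 3, 3), spacing_mm=4.0, signal=SIGNAL)
        assert fm.pressure[1, 1, 1] == pytest.approx(abs(tm.values[0] @ e), rel=1e-6)

    def test_zero_drive_gives_zero_field(self):
        model = water_model()
        arr = make_hemisphere_array(8, radius=0.08, centre=(0.12, 0.12, 0.1))
        fm = field_map(model, arr, np.zeros(8), (0.12, 0.12, 0.1), shape=(3, 3, 3), spacing_mm=4.0)
        assert np.all(fm.pressure == 0)

    def test_empty_region_rejected(self):
        model = water_model()
        arr = make_hemisphere_array(8, radius=0.08, centre=(0.12, 0.12, 0.1))
        with pytest.raises(ValueError, match="empty"):
            field_map(model, arr, np.ones(8), (0.12, 0.12, 0.1), shape=(0, 3, 3))


def test_transfer_matrix_hdf5_roundtrip(tmp_path, rng):
    vals = rng.standard_normal((2, 8)) + 1j * rng.standard_normal((2, 8))
    tm = TransferMatrix(vals, [[0.1, 0.1, 0.1], [0.1, 0.09, 0.1]], "degraded_model", 250e3)
    path = tmp_path / "tm.h5"
    tm.to_hdf5(path)
    back = TransferMatrix.from_hdf5(path)
    np.testing.assert_array_equal(back.values, tm.values)
    np.testing.assert_array_equal(back.targets, tm.targets)
    assert back.provenance == "degraded_model"
    assert back.frequency == 250e3


def test_array_json_roundtrip(tmp_path):
    arr = make_hemisphere_array(16, radius=0.1, centre=(0.11, 0.11, 0.08))
    path = tmp_path / "array.json"
    arr.to_json(path)
    back = ArrayGeometry.from_json(path)
    np.testing.assert_allclose(back.element_positions, arr.element_positions)
    assert back.radius == arr.radius
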