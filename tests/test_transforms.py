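"""Rigid transform algebra: parameterization, composition, resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headreg import (
    RegistrationParams,
    RigidTransform,
    Volume,
    apply_transform,
    compose,
    compose_ground_truth,
    invert,
    params_to_transform,
    transform_to_params,
)
from headreg.transforms import load_params, load_transform, save_params, save_transform


@pytest.fixture
def ref_volume():
    return Volume(np.zeros((16, 16, 8)), spacing=(1.0, 1.0, 2.0))


class TestParameterization:
    def test_zero_params_give_identity(self, ref_volume):
        T = params_to_transform(RegistrationParams(), ref_volume)
        np.testing.assert_allclose(T.matrix, np.eye(4), atol=1e-15)

    def test_pure_x_rotation_matches_trig_evaluation(self, ref_volume):
        # Z-Y-X with only rx = 90: R = Rx(90)
        T = params_to_transform(RegistrationParams(rx=90.0), ref_volume)
        expected = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        np.testing.assert_allclose(T.rotation, expected, atol=1e-12)

    def test_pure_translation_unit_spacing(self):
        v = Volume(np.zeros((8, 8, 8)))
        T = params_to_transform(RegistrationParams(0, 0, 0, 1, 2, 3), v)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-15)
        np.testing.assert_allclose(T.translation, [1, 2, 3], atol=1e-15)

    def test_translation_converts_voxels_to_mm(self, ref_volume):
        T = params_to_transform(RegistrationParams(0, 0, 0, 0, 0, 1.5), ref_volume)
        np.testing.assert_allclose(T.translation, [0, 0, 3.0], atol=1e-15)  # spacing z = 2

    def test_round_trip_random_params(self, ref_volume, rng):
        worst = 0.0
        for _ in range(1000):
            p = RegistrationParams(*rng.uniform(-15, 15, 3), *rng.uniform(-5, 5, 3))
            T = params_to_transform(p, ref_volume)
            T2 = params_to_transform(transform_to_params(T, ref_volume), ref_volume)
            worst = max(worst, np.abs(T.matrix - T2.matrix).max())
        assert worst < 1e-9

    def test_identity_maps_to_zero_params(self, ref_volume):
        p = transform_to_params(RigidTransform.identity(), ref_volume)
        np.testing.assert_allclose(p.as_array(), np.zeros(6), atol=1e-12)

    def test_gimbal_lock_fixes_rz_and_regenerates(self, ref_volume):
        T = params_to_transform(RegistrationParams(rx=33.0, ry=90.0, rz=21.0), ref_volume)
        p = transform_to_params(T, ref_volume)
        assert p.rz == 0.0
        np.testing.assert_allclose(
            params_to_transform(p, ref_volume).matrix, T.matrix, atol=1e-9
        )

    def test_non_rigid_matrix_rejected(self):
        m = np.eye(4)
        m[0, 0] = 2.0
        with pytest.raises(ValueError):
            RigidTransform(m)


angles = st.floats(-179.0, 179.0, allow_nan=False)
shifts = st.floats(-20.0, 20.0, allow_nan=False)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(rx=angles, ry=st.floats(-89.0, 89.0), rz=angles, tx=shifts, ty=shifts, tz=shifts)
def test_parameterization_round_trip_property(rx, ry, rz, tx, ty, tz):
    """Any rigid transform away from gimbal lock round-trips through params."""
    ref = Volume(np.zeros((16, 16, 8)), spacing=(1.0, 1.0, 2.0))
    p = RegistrationParams(rx, ry, rz, tx, ty, tz)
    T = params_to_transform(p, ref)
    T2 = params_to_transform(transform_to_params(T, ref), ref)
    assert np.abs(T.matrix - T2.matrix).max() < 1e-9


class TestGroupAlgebra:
    def test_identity_is_neutral(self, ref_volume, random_rigid_params):
        T = params_to_transform(random_rigid_params(), ref_volume)
        np.testing.assert_allclose(compose(RigidTransform.identity(), T).matrix, T.matrix)

    def test_two_quarter_turns_make_half_turn(self, ref_volume):
        q = params_to_transform(RegistrationParams(rz=90.0), ref_volume)
        h = params_to_transform(RegistrationParams(rz=-180.0), ref_volume)
        np.testing.assert_allclose(compose(q, q).matrix, h.matrix, atol=1e-12)

    def test_compose_matches_sequential_point_mapping(self, ref_volume, random_rigid_params, rng):
        for _ in range(200):
            T1 = params_to_transform(random_rigid_params(), ref_volume)
            T2 = params_to_transform(random_rigid_params(), ref_volume)
            pts = rng.uniform(-30, 30, (5, 3))
            np.testing.assert_allclose(
                compose(T1, T2).apply_points(pts),
                T1.apply_points(T2.apply_points(pts)),
                atol=1e-9,
            )

    def test_inversion(self, ref_volume, random_rigid_params):
        T = params_to_transform(random_rigid_params(), ref_volume)
        np.testing.assert_allclose(compose(T, invert(T)).matrix, np.eye(4), atol=1e-9)
        t = RigidTransform.from_rotation_translation(np.eye(3), [3, -1, 2])
        np.testing.assert_allclose(invert(t).translation, [-3, 1, -2], atol=1e-15)

    def test_double_inversion_is_identity(self, ref_volume, random_rigid_params):
        T = params_to_transform(random_rigid_params(), ref_volume)
        np.testing.assert_allclose(invert(invert(T)).matrix, T.matrix, atol=1e-12)


class TestGroundTruthComposition:
    def test_all_identity(self):
        I = RigidTransform.identity()
        np.testing.assert_allclose(compose_ground_truth(I, I, I).matrix, np.eye(4))

    def test_reduces_to_t_reg_when_symmetry_identity(self, ref_volume, random_rigid_params):
        I = RigidTransform.identity()
        T_reg = params_to_transform(random_rigid_params(), ref_volume)
        np.testing.assert_allclose(compose_ground_truth(I, T_reg, I).matrix, T_reg.matrix)
        T_mov = params_to_transform(random_rigid_params(), ref_volume)
        np.testing.assert_allclose(compose_ground_truth(I, I, T_mov).matrix, T_mov.matrix)

    def test_matches_sequential_application(self, ref_volume, random_rigid_params, rng):
        for _ in range(100):
            T_fix = params_to_transform(random_rigid_params(), ref_volume)
            T_reg = params_to_transform(random_rigid_params(), ref_volume)
            T_mov = params_to_transform(random_rigid_params(), ref_volume)
            pts = rng.uniform(-20, 20, (4, 3))
            via_stages = invert(T_fix).apply_points(T_reg.apply_points(T_mov.apply_points(pts)))
            via_comp = compose_ground_truth(T_fix, T_reg, T_mov).apply_points(pts)
            np.testing.assert_allclose(via_stages, via_comp, atol=1e-9)


class TestApplyTransform:
    def test_identity_resampling_is_exact(self, small_volume):
        out = apply_transform(small_volume, RigidTransform.identity())
        np.testing.assert_array_equal(out.voxels, small_volume.voxels)

    def test_half_turn_equals_index_reversal(self, rng):
        v = Volume(rng.random((12, 10, 8)))
        T = params_to_transform(RegistrationParams(rz=-180.0), v)
        out = apply_transform(v, T)
        np.testing.assert_allclose(out.voxels, v.voxels[::-1, ::-1, :], atol=1e-12)

    def test_huge_translation_gives_fill(self, small_volume):
        T = params_to_transform(RegistrationParams(0, 0, 0, 100, 0, 0), small_volume)
        out = apply_transform(small_volume, T)
        assert np.all(out.voxels == 0)

    def test_round_trip_small_on_smooth_volume(self):
        x, y, z = np.meshgrid(*(np.linspace(-1, 1, 24),) * 3, indexing="ij")
        smooth = Volume(np.exp(-(x**2 + y**2 + z**2) * 3))
        p = RegistrationParams(4.0, -3.0, 5.0, 1.0, -1.0, 0.5)
        T = params_to_transform(p, smooth)
        back = apply_transform(apply_transform(smooth, T), invert(T))
        core = (slice(4, -4),) * 3
        assert np.mean(np.abs(back.voxels[core] - smooth.voxels[core])) < 5e-3


class TestSerialization:
    def test_matrix_text_round_trip(self, ref_volume, random_rigid_params, tmp_path):
        T = params_to_transform(random_rigid_params(), ref_volume)
        path = tmp_path / "T.txt"
        save_transform(T, path)
        np.testing.assert_array_equal(load_transform(path).matrix, T.matrix)

    def test_params_text_round_trip(self, tmp_path):
        p = RegistrationParams(1.5, -2.25, 3.0, 0.5, -4.75, 5.0)
        path = tmp_path / "p.txt"
        save_params(p, path)
        np.testing.assert_array_equal(load_params(path).as_array(), p.as_array())
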