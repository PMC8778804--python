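"""Mass models, tensors, principal axes and their closed-form oracles."""

import numpy as np
import pytest

from ctinertia._util import fsum, random_rotation_matrix
from ctinertia.calibration import DensityCalibration, apply_calibration
from ctinertia.errors import EmptyInputError, RankError, SymmetryError
from ctinertia.grid import VoxelGrid
from ctinertia.inertial import (
    AxisSpec,
    MassModel,
    build_mass_model,
    centre_of_mass,
    compute_inertial_properties,
    fit_board_plane,
    inertia_tensor,
    moi_about_axis,
    principal_decomposition,
    translate_tensor,
    uniform_density_comparison,
)
from ctinertia.synthetic import SceneSpec, Shape, rasterize_scene

IDENTITY_CAL = DensityCalibration(slope=1.0, intercept=-1000.0, r_squared=1.0)


def voxelize(shape_obj, n, extent=0.064):
    """Voxelized mass model of one primitive plus its analytic truth."""
    h = extent * 1e3 / n
    scene = SceneSpec(
        shapes=[shape_obj], noise_sigma=0.0, spacing=(h, h, h), volume_shape=(n, n, n)
    )
    grid, labels, truth = rasterize_scene(scene)
    model = build_mass_model(apply_calibration(grid, IDENTITY_CAL), labels.labels > 0)
    return model, truth


def random_model(rng, n=400):
    return MassModel(
        masses=rng.uniform(1e-4, 1e-2, n),
        coords=rng.uniform(-0.2, 0.2, (n, 3)),
        voxel_volume=1e-9,
    )


class TestBuildMassModel:
    def test_single_voxel_unit_conversion(self):
        grid = VoxelGrid(np.full((1, 1, 1), 1000.0), spacing=(1.0, 1.0, 1.0))
        model = build_mass_model(grid, np.ones((1, 1, 1), bool))
        assert model.total_mass == pytest.approx(1e-6, rel=1e-12)  # 1 mm^3 of water

    def test_uniform_cube_total(self):
        grid = VoxelGrid(np.full((10, 10, 10), 1000.0), spacing=(1.0, 1.0, 1.0))
        model = build_mass_model(grid, np.ones((10, 10, 10), bool))
        assert model.total_mass == pytest.approx(1e-3, rel=1e-12)

    def test_negative_densities_clamped(self):
        vals = np.full((2, 2, 2), 5.0)
        vals[0, 0, 0] = -40.0
        grid = VoxelGrid(vals, spacing=(1, 1, 1))
        model = build_mass_model(grid, np.ones((2, 2, 2), bool))
        assert model.n_clamped == 1
        assert np.all(model.masses >= 0)

    def test_empty_mask_rejected(self):
        grid = VoxelGrid(np.zeros((2, 2, 2)), spacing=(1, 1, 1))
        with pytest.raises(EmptyInputError):
            build_mass_model(grid, np.zeros((2, 2, 2), bool))


class TestCentreOfMass:
    def test_lever_rule(self):
        model = MassModel(
            masses=[1.0, 3.0], coords=[[0, 0, 0], [1.0, 0, 0]], voxel_volume=1e-9
        )
        assert centre_of_mass(model)[0] == pytest.approx(0.75, rel=1e-15)

    def test_uniform_cuboid_geometric_centre(self):
        grid = VoxelGrid(np.full((4, 6, 8), 1000.0), spacing=(1.0, 1.0, 1.0))
        model = build_mass_model(grid, np.ones((4, 6, 8), bool))
        assert centre_of_mass(model) * 1e3 == pytest.approx([2.0, 3.0, 4.0], rel=1e-12)

    def test_mirror_symmetric_bird_com_on_midplane(self, bird_model, bird_study):
        com = centre_of_mass(bird_model)
        mid = 0.5 * bird_study["grid"].spacing[2] * bird_study["grid"].shape[2] * 1e-3
        # symmetric scene: mediolateral CoM on the centreline to sub-voxel
        assert abs(com[2] - mid) < 0.5 * bird_study["grid"].spacing[2] * 1e-3


class TestInertiaTensor:
    def test_point_mass_on_x_axis(self):
        model = MassModel(masses=[2.0], coords=[[0.3, 0.0, 0.0]], voxel_volume=1e-9)
        t = inertia_tensor(model, np.zeros(3))
        md2 = 2.0 * 0.3**2
        assert t[0, 0] == 0.0
        assert t[1, 1] == pytest.approx(md2, rel=1e-15)
        assert t[2, 2] == pytest.approx(md2, rel=1e-15)
        assert np.all(t[~np.eye(3, dtype=bool)] == 0.0)

    def test_voxelized_primitives_match_closed_forms_at_64(self):
        tilt = np.array(
            [
                [np.cos(0.12), -np.sin(0.12), 0.0],
                [np.sin(0.12), np.cos(0.12), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        shapes = [
            Shape("cuboid", (0.0323, 0.0317, 0.0321), (0.024, 0.018, 0.012), 1000.0, 1, "c"),
            Shape("sphere", (0.0323, 0.0317, 0.0321), (0.0215,), 1000.0, 1, "s"),
            Shape("cylinder", (0.0323, 0.0317, 0.0321), (0.0181, 0.0405), 1000.0, 1,
                  "cy", axis=0, rotation=tilt),
        ]
        for s in shapes:
            model, truth = voxelize(s, 64)
            got = np.linalg.eigvalsh(inertia_tensor(model, centre_of_mass(model)))
            want = np.linalg.eigvalsh(truth.tensor_about_com)
            assert np.all(np.abs(got / want - 1) < 0.01), s.primitive

    def test_parallel_axis_identity_exact(self, rng):
        model = random_model(rng)
        com = centre_of_mass(model)
        t_com = inertia_tensor(model, com)
        for _ in range(100):
            d = rng.uniform(-0.5, 0.5, 3)
            direct = inertia_tensor(model, com - d)
            shifted = translate_tensor(t_com, model.total_mass, d)
            assert np.allclose(direct, shifted, rtol=1e-12, atol=1e-12 * np.abs(direct).max())

    def test_trace_identity(self, rng):
        model = random_model(rng)
        com = centre_of_mass(model)
        t = inertia_tensor(model, com)
        r2 = np.einsum("ij,ij->i", model.coords - com, model.coords - com)
        assert np.trace(t) == pytest.approx(2 * fsum(model.masses * r2), rel=1e-13)

    def test_rotation_invariance_of_principal_moments(self, rng):
        model = random_model(rng)
        base, _ = principal_decomposition(
            inertia_tensor(model, centre_of_mass(model))
        )
        for _ in range(50):
            q = random_rotation_matrix(rng)
            rotated = MassModel(
                masses=model.masses,
                coords=model.coords @ q.T,
                voxel_volume=model.voxel_volume,
            )
            got, _ = principal_decomposition(
                inertia_tensor(rotated, centre_of_mass(rotated))
            )
            assert np.all(np.abs(got / base - 1) < 1e-8)


class TestPrincipalDecomposition:
    def test_diagonal_tensor_is_its_own_answer(self):
        moments, axes = principal_decomposition(np.diag([1.0, 2.0, 3.0]))
        assert np.allclose(moments, [1, 2, 3])
        assert np.allclose(axes, np.eye(3))

    def test_conjugated_tensor_recovers_rotation(self, rng):
        q = random_rotation_matrix(rng)
        t = q @ np.diag([1.0, 2.0, 3.0]) @ q.T
        moments, axes = principal_decomposition(t)
        assert np.allclose(moments, [1, 2, 3], rtol=1e-12)
        # columns equal q's columns up to the documented sign convention
        for k in range(3):
            assert min(
                np.linalg.norm(axes[:, k] - q[:, k]),
                np.linalg.norm(axes[:, k] + q[:, k]),
            ) < 1e-10
        assert np.linalg.det(axes) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_moments_reported_not_axes(self):
        # diag(2,2,5) is a valid tensor about a general origin (not a CoM)
        moments, axes = principal_decomposition(np.diag([2.0, 2.0, 5.0]), about_com=False)
        assert moments[0] == pytest.approx(moments[1])
        assert np.allclose(axes @ axes.T, np.eye(3), atol=1e-12)

    def test_asymmetric_input_rejected(self):
        t = np.diag([1.0, 2.0, 3.0])
        t[0, 1] = 0.5
        with pytest.raises(SymmetryError):
            principal_decomposition(t)


class TestMoiAboutAxis:
    def test_two_point_masses(self):
        model = MassModel(
            masses=[1.0, 2.0], coords=[[0, 0.3, 0], [0, -0.1, 0]], voxel_volume=1e-9
        )
        axis = AxisSpec.through([0, 0, 0], [1, 0, 0])
        assert moi_about_axis(model, axis) == pytest.approx(
            1.0 * 0.09 + 2.0 * 0.01, rel=1e-14
        )

    def test_equals_tensor_contraction(self, rng):
        model = random_model(rng)
        com = centre_of_mass(model)
        t = inertia_tensor(model, com)
        for _ in range(10):
            n = rng.standard_normal(3)
            n /= np.linalg.norm(n)
            axis = AxisSpec(com, n)
            assert moi_about_axis(model, axis) == pytest.approx(
                float(n @ t @ n), rel=1e-12
            )

    def test_voxelized_cylinder_longitudinal_oracle(self):
        s = Shape("cylinder", (0.032, 0.032, 0.032), (0.018, 0.04), 1000.0, 1, "cy", axis=0)
        model, truth = voxelize(s, 64)
        axis = AxisSpec.through(centre_of_mass(model), [1, 0, 0])
        want = truth.total_mass * 0.018**2 / 2
        assert moi_about_axis(model, axis) == pytest.approx(want, rel=0.01)


class TestBoardPlane:
    def test_exact_horizontal_plane(self, rng):
        pts = np.column_stack(
            [rng.uniform(0, 0.1, 50), rng.uniform(0, 0.1, 50), np.full(50, 0.005)]
        )
        normal, point = fit_board_plane(pts, toward=[0.05, 0.05, 0.06])
        assert np.allclose(normal, [0, 0, 1], atol=1e-12)
        assert point[2] == pytest.approx(0.005)

    def test_noisy_plane_normal_within_bound(self):
        rng = np.random.default_rng(5)
        n_true = np.array([0.1, 0.2, 0.97])
        n_true /= np.linalg.norm(n_true)
        u = np.array([1.0, 0, 0]) - n_true[0] * n_true
        u /= np.linalg.norm(u)
        v = np.cross(n_true, u)
        a = rng.uniform(-0.05, 0.05, 500)  # 100 mm board
        b = rng.uniform(-0.05, 0.05, 500)
        pts = np.outer(a, u) + np.outer(b, v) + rng.normal(0, 1e-4, (500, 1)) * n_true
        normal, _ = fit_board_plane(pts, toward=n_true)
        angle = np.degrees(np.arccos(np.clip(abs(normal @ n_true), -1, 1)))
        assert angle < 0.2

    def test_three_points_interpolating_plane(self):
        pts = [[0, 0, 0], [1, 0, 0], [0, 1, 1]]
        normal, point = fit_board_plane(pts)
        for p in pts:
            assert abs((np.asarray(p, float) - point) @ normal) < 1e-12

    def test_collinear_points_rejected(self):
        pts = [[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]]
        with pytest.raises(RankError):
            fit_board_plane(pts)


class TestTranslateTensor:
    def test_zero_displacement_identity(self, rng):
        t = np.diag([1.0, 2.0, 3.0])
        assert np.array_equal(translate_tensor(t, 5.0, np.zeros(3)), t)

    def test_scalar_parallel_axis_along_perpendicular(self):
        t = np.diag([1.0, 2.0, 3.0])
        out = translate_tensor(t, 2.0, [0.5, 0, 0])
        assert out[1, 1] == pytest.approx(2.0 + 2.0 * 0.25)
        assert out[2, 2] == pytest.approx(3.0 + 2.0 * 0.25)
        assert out[0, 0] == pytest.approx(1.0)

    def test_round_trip_invertible(self, rng):
        t = np.diag([1.0, 2.0, 3.0])
        d = rng.uniform(-0.1, 0.1, 3)
        out = translate_tensor(t, 1.7, d)
        back = out - 1.7 * (float(d @ d) * np.eye(3) - np.outer(d, d))
        assert np.allclose(back, t, rtol=1e-12)


class TestUniformDensityComparison:
    def _core_shell_scene(self):
        # dense core, light periphery: uniform density moves mass outward
        shapes = [
            Shape("sphere", (0.032, 0.032, 0.032), (0.020,), 300.0, 1, "shell"),
            Shape("sphere", (0.032, 0.032, 0.032), (0.010,), 2000.0, 2, "core"),
        ]
        scene = SceneSpec(
            shapes=shapes, noise_sigma=0.0, spacing=(1, 1, 1), volume_shape=(64, 64, 64)
        )
        return rasterize_scene(scene)

    @pytest.mark.filterwarnings("ignore:.*claimed by more than one shape")
    def test_uniform_assumption_inflates_central_moi(self):
        grid, labels, _ = self._core_shell_scene()
        mask = labels.labels > 0
        model = build_mass_model(apply_calibration(grid, IDENTITY_CAL), mask)
        calibrated = compute_inertial_properties(model)
        uniform = uniform_density_comparison(mask, calibrated.mass, grid)
        assert uniform.mass == calibrated.mass  # exact by construction
        assert np.all(uniform.principal_moments > calibrated.principal_moments)

    def test_truly_uniform_object_unchanged(self):
        s = Shape("cuboid", (0.032, 0.032, 0.032), (0.02, 0.03, 0.024), 1000.0, 1, "c")
        model, _ = voxelize(s, 32, extent=0.064)
        grid = VoxelGrid(
            np.full((32, 32, 32), 2000.0), spacing=(2, 2, 2)
        )
        # same voxel set, uniform masses: identical inertial properties
        mask = np.zeros((32, 32, 32), bool)
        mask[tuple(model.indices.T)] = True
        uniform = uniform_density_comparison(mask, model.total_mass, grid)
        calibrated_like = compute_inertial_properties(
            MassModel(
                masses=np.full(len(model), model.total_mass / len(model)),
                coords=grid.index_to_world(model.indices) * 1e-3,
                voxel_volume=grid.voxel_volume_m3,
            )
        )
        assert np.allclose(
            uniform.principal_moments, calibrated_like.principal_moments, rtol=1e-12
        )
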