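import numpy as np
import pytest
from scipy.stats import special_ortho_group

from spectseg.fourier_surface import (
    EllipsoidInit,
    FourierSurface,
    ObjectiveConfig,
    OptimizerConfig,
    ellipsoid_to_coefficients,
    estimate_initial_ellipsoid,
    evaluate_surface,
    fs_segment,
    n_coefficients,
    objective_B,
    optimize_surface,
    surface_area,
    surface_normal,
    voxelize_surface,
)
from spectseg.imaging_core import (
    BinaryMask3D,
    GridError,
    ScalarImage3D,
    VectorField3D,
    VoxelGrid,
    image_gradient,
    solidify,
)
from spectseg.phantom_sim import AcquisitionSpec, expected_image
from spectseg.threshold_seg import DegenerateHistogramError

from conftest import sphere_image


class TestEvaluateSurface:
    def test_constant_surface(self):
        c = np.zeros((3, n_coefficients(2)))
        c[:, 0] = [1.0, 2.0, 3.0]
        s = FourierSurface(2, c)
        pts = evaluate_surface(s, np.linspace(0, 6, 5), np.linspace(0, 3, 5))
        assert np.allclose(pts, [1.0, 2.0, 3.0])

    def test_unit_sphere_equator_point(self, unit_sphere_surface):
        r = 1.0
        p = evaluate_surface(unit_sphere_surface, 0.0, np.pi / 2)
        assert np.allclose(p, [r, 0.0, 0.0], atol=1e-12)

    def test_pole_independent_of_u(self, unit_sphere_surface):
        pts = evaluate_surface(unit_sphere_surface, np.linspace(0, 6, 9), 0.0)
        assert np.allclose(pts, [0.0, 0.0, 1.0], atol=1e-12)

    def test_pole_closure_random_surfaces(self, random_surfaces):
        us = np.linspace(0.0, 2 * np.pi, 13)
        for s in random_surfaces:
            for v in (0.0, np.pi):
                pts = evaluate_surface(s, us, v)
                assert np.ptp(pts, axis=0).max() < 1e-10

    def test_translation_equivariance(self, random_surfaces):
        delta = np.array([5.0, -3.0, 2.0])
        for s in random_surfaces[:5]:
            shifted = FourierSurface(s.order, s.coefficients.copy())
            shifted.coefficients[:, 0] += delta
            u, v = 1.2, 0.7
            assert np.allclose(
                evaluate_surface(shifted, u, v), evaluate_surface(s, u, v) + delta
            )


class TestSurfaceNormal:
    def test_sphere_normal_is_radial(self, unit_sphere_surface):
        rng = np.random.default_rng(0)
        u = rng.uniform(0, 2 * np.pi, 50)
        v = rng.uniform(0.1, np.pi - 0.1, 50)
        pts = evaluate_surface(unit_sphere_surface, u, v)
        n = surface_normal(unit_sphere_surface, u, v)
        nn = n / np.linalg.norm(n, axis=-1, keepdims=True)
        assert np.allclose(np.abs(np.einsum("ij,ij->i", nn, pts)), 1.0, atol=1e-9)
        # oriented outward
        assert np.all(np.einsum("ij,ij->i", nn, pts) > 0)

    def test_zero_at_poles(self, unit_sphere_surface):
        assert np.allclose(surface_normal(unit_sphere_surface, 0.3, 0.0), 0.0)

    def test_degenerate_surface_zero_normal(self):
        c = np.zeros((3, n_coefficients(2)))
        c[:, 0] = 1.0
        s = FourierSurface(2, c)
        assert np.allclose(surface_normal(s, 1.0, 1.0), 0.0)

    def test_area_of_unit_sphere(self, unit_sphere_surface):
        area = surface_area(unit_sphere_surface, 72, 72)
        assert area == pytest.approx(4 * np.pi, rel=0.01)


class TestEllipsoidToCoefficients:
    def test_unit_sphere_coefficients(self):
        e = EllipsoidInit((0, 0, 0), np.eye(3), (1.0, 1.0, 1.0))
        s = ellipsoid_to_coefficients(e)
        assert s.coefficients[2, 1] == pytest.approx(0.5)  # a_{z,0,1}
        assert s.coefficients[0, 3] == pytest.approx(0.25)  # c_{x,1,1}
        assert s.coefficients[1, 4] == pytest.approx(0.25)  # d_{y,1,1}

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rotated_ellipsoid_satisfies_implicit_equation(self, seed):
        rng = np.random.default_rng(seed)
        R = special_ortho_group.rvs(3, random_state=seed)
        centre = rng.uniform(-10, 10, 3)
        axes = rng.uniform(5, 30, 3)
        s = ellipsoid_to_coefficients(EllipsoidInit(centre, R, axes))
        u, v = np.meshgrid(
            np.linspace(0, 2 * np.pi, 36), np.linspace(0, np.pi, 36), indexing="ij"
        )
        pts = evaluate_surface(s, u.ravel(), v.ravel())
        local = (pts - centre) @ R
        q = np.sum((local / axes) ** 2, axis=-1)
        assert np.allclose(q, 1.0, atol=1e-9)

    def test_centre_shift_only_moves_a00(self):
        e0 = EllipsoidInit((0, 0, 0), np.eye(3), (2.0, 3.0, 4.0))
        e5 = EllipsoidInit((5, 0, 0), np.eye(3), (2.0, 3.0, 4.0))
        c0 = ellipsoid_to_coefficients(e0).coefficients
        c5 = ellipsoid_to_coefficients(e5).coefficients
        diff = c5 - c0
        assert diff[0, 0] == pytest.approx(5.0)
        diff[0, 0] = 0.0
        assert np.allclose(diff, 0.0)


class TestEstimateInitialEllipsoid:
    def test_binary_sphere_recovered(self):
        image, truth = sphere_image(radius_mm=15.0, n=32)
        voi = BinaryMask3D(image.grid, np.ones(image.grid.shape, dtype=bool))
        e = estimate_initial_ellipsoid(image, voi)
        centre_true = np.full(3, 2.5 * 31 / 2)
        assert np.all(np.abs(e.centre - centre_true) < 1.25)  # half a voxel
        assert np.all(np.abs(e.semi_axes - 15.0) < 1.5)  # within 10 %

    def test_axis_directions_from_pca(self):
        grid = VoxelGrid((40, 40, 40), (2.0, 2.0, 2.0))
        xs, ys, zs = grid.world_coordinates()
        c = 2.0 * 39 / 2
        inside = ((xs - c) / 30) ** 2 + ((ys - c) / 20) ** 2 + ((zs - c) / 10) ** 2 <= 1
        image = ScalarImage3D(grid, np.where(inside, 100.0, 0.0))
        voi = BinaryMask3D(grid, np.ones(grid.shape, dtype=bool))
        e = estimate_initial_ellipsoid(image, voi)
        # longest axis along x, shortest along z, within 5 degrees
        assert abs(e.rotation[:, 0] @ [1, 0, 0]) > np.cos(np.deg2rad(5))
        assert abs(e.rotation[:, 2] @ [0, 0, 1]) > np.cos(np.deg2rad(5))

    def test_uniform_voi_degenerate(self):
        grid = VoxelGrid((8, 8, 8))
        image = ScalarImage3D(grid, np.full(grid.shape, 4.0))
        voi = BinaryMask3D(grid, np.ones(grid.shape, dtype=bool))
        with pytest.raises(DegenerateHistogramError):
            estimate_initial_ellipsoid(image, voi)


class TestObjectiveB:
    def test_zero_gradient_gives_zero(self, unit_sphere_surface):
        grid = VoxelGrid((8, 8, 8), origin=(-3.5, -3.5, -3.5))
        field = VectorField3D(grid, np.zeros((3, 8, 8, 8)))
        assert objective_B(unit_sphere_surface, field) == 0.0

    def test_constant_field_flux_vanishes(self, random_surfaces):
        # discrete divergence theorem: signed flux of a uniform field
        # through any closed surface is ~0 when delta is disabled
        cfg = ObjectiveConfig(alpha=0.0, polarity="none")
        grid = VoxelGrid((4, 4, 4), (200.0, 200.0, 200.0), (-300.0, -300.0, -300.0))
        comps = np.zeros((3, 4, 4, 4))
        comps[0], comps[1], comps[2] = 1.0, -2.0, 0.5
        field = VectorField3D(grid, comps)
        for s in random_surfaces[:10]:
            area = surface_area(s, cfg.n1, cfg.n2)
            flux = objective_B(s, field, cfg)  # alpha=0: numerator itself
            assert abs(flux) < 1e-6 * area

    def test_maximal_on_true_edge_radius(self):
        image, _ = sphere_image(radius_mm=20.0, n=40)
        acq = AcquisitionSpec(fwhm_mm=8.0, count_scale=1.0)
        blurred = expected_image(image, acq)
        grad = image_gradient(blurred)
        centre = np.full(3, 2.5 * 39 / 2)
        scores = []
        for scale in (0.5, 1.0, 1.5):
            e = EllipsoidInit(centre, np.eye(3), np.full(3, 20.0 * scale))
            scores.append(objective_B(ellipsoid_to_coefficients(e), grad))
        assert scores[1] > scores[0] and scores[1] > scores[2]

    def test_degenerate_surface_rejected(self):
        c = np.zeros((3, n_coefficients(2)))
        s = FourierSurface(2, c)
        grid = VoxelGrid((4, 4, 4))
        field = VectorField3D(grid, np.ones((3, 4, 4, 4)))
        with pytest.raises(ValueError, match="degenerate"):
            objective_B(s, field)


class TestVoxelization:
    def test_sphere_volume(self):
        grid = VoxelGrid((48, 48, 48), (2.5, 2.5, 2.5))
        centre = np.full(3, 2.5 * 47 / 2)
        e = EllipsoidInit(centre, np.eye(3), (25.0, 25.0, 25.0))
        mask = voxelize_surface(ellipsoid_to_coefficients(e), grid)
        assert mask.volume_cm3 == pytest.approx(65.45, rel=0.02)

    def test_folded_surface_yields_solid_connected_mask(self):
        # order-4 layout: [a00, a01, c_{0,1..3}, c_{m,l} (9), d_{m,l} (9)]
        c = np.zeros((3, n_coefficients(4)))
        centre = np.full(3, 2.5 * 31 / 2)
        c[:, 0] = centre
        c[2, 1] = 5.0  # a_{z,0,1}: 10 mm z semi-axis
        c[0, 5] = 2.5  # c_{x,1,1}
        c[1, 14] = 2.5  # d_{y,1,1}
        c[1, 13] = 4.0  # c_{y,3,3}: large high-order term creating folds
        s = FourierSurface(4, c)
        grid = VoxelGrid((32, 32, 32), (2.5, 2.5, 2.5))
        mask = voxelize_surface(s, grid)
        again = solidify(mask, centre)
        assert np.array_equal(mask.member, again.member)
        from scipy import ndimage

        _, ncomp = ndimage.label(mask.member)
        assert ncomp == 1

    def test_subvoxel_surface_gives_single_voxel(self):
        grid = VoxelGrid((9, 9, 9), (2.5, 2.5, 2.5))
        e = EllipsoidInit((10.0, 10.0, 10.0), np.eye(3), (0.3, 0.3, 0.3))
        mask = voxelize_surface(ellipsoid_to_coefficients(e), grid)
        assert mask.voxel_count == 1
        assert mask.member[4, 4, 4]

    def test_surface_outside_grid_rejected(self):
        grid = VoxelGrid((9, 9, 9), (2.5, 2.5, 2.5))
        e = EllipsoidInit((500.0, 500.0, 500.0), np.eye(3), (5.0, 5.0, 5.0))
        with pytest.raises(GridError):
            voxelize_surface(ellipsoid_to_coefficients(e), grid)


class TestSurfaceSerialization:
    def test_json_round_trip(self, tmp_path, unit_sphere_surface):
        from spectseg.fourier_surface import surface_from_json, surface_to_json

        path = tmp_path / "surface.json"
        surface_to_json(unit_sphere_surface, path)
        back = surface_from_json(path)
        assert back.order == unit_sphere_surface.order
        assert np.allclose(back.coefficients, unit_sphere_surface.coefficients)

    def test_point_cloud_lies_on_surface(self, tmp_path, unit_sphere_surface):
        import csv

        from spectseg.fourier_surface import surface_point_cloud

        path = tmp_path / "cloud.csv"
        surface_point_cloud(unit_sphere_surface, path, 16, 16)
        with path.open() as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 16 * 16
        pts = np.array([[float(r["x"]), float(r["y"]), float(r["z"])] for r in rows])
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-5)


class TestOptimization:
    def test_objective_never_decreases(self):
        image, truth = sphere_image(radius_mm=20.0, n=32)
        acq = AcquisitionSpec(fwhm_mm=10.0, count_scale=1.0)
        blurred = expected_image(image, acq)
        grad = image_gradient(blurred)
        centre = np.full(3, 2.5 * 31 / 2)
        init = EllipsoidInit(centre, np.eye(3), np.full(3, 16.0))
        opt = OptimizerConfig(maxiter_factor=20, max_restarts=1)
        surface, history = optimize_surface(
            blurred, init, opt, gradient=grad, return_history=True
        )
        assert all(b - a > -1e-12 for a, b in zip(history, history[1:]))
        assert history[-1] >= history[0]

    def test_recovers_two_to_one_axis_ratio(self):
        grid = VoxelGrid((48, 48, 32), (2.5, 2.5, 2.5))
        xs, ys, zs = grid.world_coordinates()
        cx, cy, cz = 2.5 * 47 / 2, 2.5 * 47 / 2, 2.5 * 31 / 2
        inside = ((xs - cx) / 30) ** 2 + ((ys - cy) / 15) ** 2 + ((zs - cz) / 15) ** 2 <= 1
        act = ScalarImage3D(grid, np.where(inside, 100.0, 0.0))
        blurred = expected_image(act, AcquisitionSpec(fwhm_mm=10.0, count_scale=1.0))
        voi = BinaryMask3D(grid, np.ones(grid.shape, dtype=bool))
        mask = fs_segment(blurred, voi, OptimizerConfig(maxiter_factor=40, max_restarts=2))
        idx = np.argwhere(mask.member)
        extents = idx.max(axis=0) - idx.min(axis=0) + 1
        ratio = extents[0] / extents[1]
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_empty_voi_rejected(self):
        image, _ = sphere_image(n=16)
        empty = BinaryMask3D(image.grid, np.zeros(image.grid.shape, dtype=bool))
        with pytest.raises(ValueError):
            fs_segment(image, empty)
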