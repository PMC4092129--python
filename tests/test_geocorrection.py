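import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gyrospec.flight_dynamics import AhrsSolution, simulate_trajectory
from gyrospec.geocorrection import (EmptyOutputError, GcpSet,
                                    NoIntersectionError, OrthoImage,
                                    apply_warp, fit_warp, gcp_residual_correct,
                                    intersect_dtm, parametric_geocorrect,
                                    project_pixels)
from gyrospec.pushbroom import SensorModel, acquire_cube, realize_spectra
from gyrospec.spectral_scene import Scene, default_library

DEG = np.pi / 180.0


def scipy_flat_ground_oracle(pos, att, alpha, z_ground=0.0):
    """Independent flat-plane projection using scipy's rotation algebra."""
    body = np.array([0.0, np.sin(alpha), -np.cos(alpha)])
    R = Rotation.from_euler("ZYX", [att[2], att[1], att[0]]).as_matrix()
    d = R @ body
    t = (z_ground - pos[2]) / d[2]
    return pos + t * d


class TestIntersectDtm:
    def test_nadir_flat(self, flat_scene_factory):
        sc = flat_scene_factory()
        pt = intersect_dtm(np.array([0, 0, 300.0]), np.array([0, 0, -1.0]), sc)
        np.testing.assert_allclose(pt, [0, 0, 0], atol=1e-3)

    def test_tilted_ray_closed_form(self, flat_scene_factory):
        sc = flat_scene_factory()
        a = 5 * DEG
        d = np.array([0.0, np.sin(a), -np.cos(a)])
        pt = intersect_dtm(np.array([0, 0, 300.0]), d, sc)
        assert pt[1] == pytest.approx(300.0 * np.tan(a), abs=1e-2)
        assert pt[1] == pytest.approx(26.2467, abs=1e-2)

    def test_inclined_plane_analytic(self):
        # DTM is the plane z = s * x; compare to the exact ray-plane solution
        g = 0.5
        shape = (200, 200)
        s = 0.1
        xs = (np.arange(shape[1]) + 0.5) * g - 50.0
        dtm = np.broadcast_to(s * xs, shape).copy()
        sc = Scene(dtm=dtm, class_map=np.zeros(shape, np.int16),
                   class_names=["t"], g_fine=g, origin=(-50.0, 50.0))
        o = np.array([5.0, 3.0, 300.0])
        d = np.array([0.1, -0.05, -0.99])
        d = d / np.linalg.norm(d)
        t_exact = (s * o[0] - o[2]) / (d[2] - s * d[0])
        expected = o + t_exact * d
        pt = intersect_dtm(o, d, sc)
        np.testing.assert_allclose(pt, expected, atol=1e-2)

    def test_upward_ray_rejected(self, flat_scene_factory):
        with pytest.raises(ValueError, match="downward"):
            intersect_dtm(np.array([0, 0, 300.0]), np.array([0, 0, 1.0]),
                          flat_scene_factory())

    def test_ray_exits_extent(self, flat_scene_factory):
        sc = flat_scene_factory(width_m=10, height_m=10)
        # nearly horizontal ray leaves the 10 m extent long before ground
        d = np.array([0.999, 0.0, -0.04])
        d /= np.linalg.norm(d)
        with pytest.raises(NoIntersectionError):
            intersect_dtm(np.array([0, 0, 300.0]), d, sc)


def _geometry_sim(seed=5, sigma_att=1 * DEG, length=200.0):
    traj = simulate_trajectory(length, 18.06, 300.0, 0.0277,
                               dict(sigma_roll=sigma_att, sigma_pitch=sigma_att,
                                    sigma_yaw=sigma_att, rho=0.95), seed=seed)
    return traj


class TestProjectPixels:
    def test_ideal_flight_matches_closed_form(self, flat_scene_factory):
        sc = flat_scene_factory(width_m=260, height_m=240, g=1.0,
                                origin=(-20.0, 120.0))
        traj = _geometry_sim(sigma_att=0.0)
        sensor = SensorModel(n_detectors=21, fov=2 * np.arctan(110 / 300))
        dets = np.arange(21)
        lines = np.arange(0, traj.n_lines, 17)
        pts, ok = project_pixels(traj, sensor, sc, detectors=dets, lines=lines)
        assert np.all(ok)
        for k, i in enumerate(lines):
            for j, d in enumerate(dets):
                alpha = sensor.fov * (d / 20.0 - 0.5)
                expected = scipy_flat_ground_oracle(traj.pos[i], traj.att[i],
                                                    alpha)
                np.testing.assert_allclose(pts[k, j], expected, atol=0.05)

    def test_perturbed_true_pose_matches_oracle(self, flat_scene_factory):
        # geometry is exact regardless of perturbation when pose is true
        sc = flat_scene_factory(width_m=260, height_m=240, g=1.0,
                                origin=(-20.0, 120.0))
        traj = _geometry_sim(seed=9)
        sensor = SensorModel(n_detectors=11, fov=2 * np.arctan(110 / 300))
        lines = np.arange(0, traj.n_lines, 29)
        pts, ok = project_pixels(traj, sensor, sc, lines=lines)
        errs = []
        for k, i in enumerate(lines):
            for d in range(11):
                if not ok[k, d]:
                    continue
                alpha = sensor.fov * (d / 10.0 - 0.5)
                expected = scipy_flat_ground_oracle(traj.pos[i], traj.att[i],
                                                    alpha)
                errs.append(np.linalg.norm(pts[k, d, :2] - expected[:2]))
        assert np.mean(errs) < 0.05


def _tiny_cube_setup(library, seed=0):
    g = 0.05
    shape = (200, 400)        # 10 m x 20 m
    scene = Scene(dtm=np.zeros(shape),
                  class_map=np.zeros(shape, np.int16),
                  class_names=["carpobrotus", "pinus"], g_fine=g,
                  origin=(0.0, 10.0))
    scene.class_map[:, 200:] = 1
    traj = simulate_trajectory(20.0, 18.0, 300.0, 0.0277, None, seed=seed,
                               start=(0.0, 5.0))
    sensor = SensorModel(n_detectors=19,
                         fov=2 * np.arctan(4.75 / 300.0), n_bands=200)
    spectra = realize_spectra(scene, library, seed=seed, n_variants=1)
    cube = acquire_cube(scene, library, traj, sensor, snr=None,
                        spectra=spectra)
    return scene, traj, cube


class TestParametricGeocorrect:
    def test_spectra_bit_preserved(self, library):
        scene, traj, cube = _tiny_cube_setup(library)
        ortho = parametric_geocorrect(cube, traj, scene, pixel_size=0.5)
        cube_set = {c.tobytes() for c in cube.data.reshape(-1, 200)}
        for r, c in zip(*np.nonzero(~ortho.nodata)):
            assert ortho.data[r, c].tobytes() in cube_set

    def test_source_index_traceable(self, library):
        scene, traj, cube = _tiny_cube_setup(library)
        ortho = parametric_geocorrect(cube, traj, scene, pixel_size=0.5)
        src = ortho.source_index[~ortho.nodata]
        assert np.all(src >= 0)
        flat = cube.data.reshape(-1, 200)
        sample = list(zip(*np.nonzero(~ortho.nodata)))[:20]
        for r, c in sample:
            np.testing.assert_array_equal(ortho.data[r, c],
                                          flat[ortho.source_index[r, c]])

    def test_geotransform_roundtrip(self, library):
        scene, traj, cube = _tiny_cube_setup(library)
        ortho = parametric_geocorrect(cube, traj, scene, pixel_size=0.5)
        x, y = ortho.map_of(3, 7)
        assert ortho.index_of(x, y) == (3, 7)

    def test_requested_grid_alignment(self, library):
        scene, traj, cube = _tiny_cube_setup(library)
        ortho = parametric_geocorrect(cube, traj, scene, pixel_size=0.5,
                                      grid_origin=scene.origin,
                                      grid_shape=(20, 40))
        assert ortho.shape == (20, 40)
        assert ortho.origin == scene.origin

    def test_empty_overlap_raises(self, library):
        scene, traj, cube = _tiny_cube_setup(library)
        with pytest.raises(EmptyOutputError):
            parametric_geocorrect(cube, traj, scene, pixel_size=0.5,
                                  grid_origin=(1e5, 1e5), grid_shape=(10, 10))

    def test_pose_must_cover_lines(self, library):
        scene, traj, cube = _tiny_cube_setup(library)
        short = AhrsSolution(t=traj.t[:5], pos=traj.pos[:5], att=traj.att[:5],
                             cov=np.zeros((5, 12, 12)))
        with pytest.raises(ValueError, match="cover"):
            parametric_geocorrect(cube, short, scene, pixel_size=0.5)


def _random_gcps(rng, n=8):
    img = rng.uniform(0, 100, (n, 2))
    ref = img + rng.normal(0, 0.5, (n, 2))
    return GcpSet(image_xy=img, ref_xy=ref)


def _checker_ortho(rows=20, cols=20, bands=4):
    rng = np.random.default_rng(0)
    data = rng.random((rows, cols, bands)).astype(np.float32)
    return OrthoImage(data=data, pixel_size=0.5, origin=(0.0, 10.0),
                      nodata=np.zeros((rows, cols), bool),
                      source_index=np.arange(rows * cols).reshape(rows, cols))


class TestGcpResidualCorrect:
    def test_identity_when_already_aligned(self):
        ortho = _checker_ortho()
        xy = np.array([[1.0, 2.0], [8.0, 3.0], [4.0, 9.0], [2.0, 7.0]])
        gcps = GcpSet(image_xy=xy, ref_xy=xy.copy())
        out = gcp_residual_correct(ortho, gcps, "affine")
        np.testing.assert_array_equal(out.data, ortho.data)
        assert out.provenance["gcp_rms_after"] == pytest.approx(0.0, abs=1e-9)

    def test_translation_recovered(self):
        xy = np.array([[1.0, 2.0], [8.0, 3.0], [4.0, 9.0], [2.0, 7.0]])
        gcps = GcpSet(image_xy=xy, ref_xy=xy + np.array([3.0, -2.0]))
        coef = fit_warp(gcps, "affine")
        fitted = apply_warp(coef, xy, "affine")
        np.testing.assert_allclose(fitted, xy + np.array([3.0, -2.0]),
                                   atol=1e-6)
        out = gcp_residual_correct(_checker_ortho(), gcps, "affine")
        assert out.provenance["gcp_rms_after"] < 1e-6

    def test_shear_needs_affine_model(self):
        # translation-only fit (mean offset) cannot remove a shear; affine can
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 50, (10, 2))
        A = np.array([[1.0, 0.15], [0.0, 1.0]])
        ref = img @ A.T
        gcps = GcpSet(image_xy=img, ref_xy=ref)
        coef = fit_warp(gcps, "affine")
        affine_resid = apply_warp(coef, img, "affine") - ref
        shift = (ref - img).mean(axis=0)
        trans_resid = (img + shift) - ref
        assert np.sqrt((affine_resid ** 2).mean()) < 1e-9
        assert np.sqrt((trans_resid ** 2).mean()) > 0.1

    def test_rms_never_increases(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            gcps = _random_gcps(rng)
            out = gcp_residual_correct(_checker_ortho(), gcps, "affine")
            assert (out.provenance["gcp_rms_after"]
                    <= out.provenance["gcp_rms_before"] + 1e-12)

    def test_polynomial2_fits_quadratic(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(0, 20, (12, 2))
        ref = img + 0.01 * img ** 2
        gcps = GcpSet(image_xy=img, ref_xy=ref)
        coef = fit_warp(gcps, "polynomial-2")
        np.testing.assert_allclose(apply_warp(coef, img, "polynomial-2"), ref,
                                   atol=1e-8)

    def test_underdetermined_rejected(self):
        xy = np.array([[0.0, 0.0], [1.0, 1.0]])
        gcps = GcpSet(image_xy=xy, ref_xy=xy)
        with pytest.raises(ValueError, match="GCP"):
            fit_warp(gcps, "affine")
        xy5 = np.column_stack([np.arange(5.0), np.arange(5.0) ** 2])
        with pytest.raises(ValueError, match="GCP"):
            fit_warp(GcpSet(image_xy=xy5, ref_xy=xy5), "polynomial-2")

    def test_gcpset_validation(self):
        with pytest.raises(ValueError, match="finite"):
            GcpSet(image_xy=np.array([[0.0, np.nan]]),
                   ref_xy=np.array([[0.0, 0.0]]))
        with pytest.raises(ValueError, match="distinct"):
            GcpSet(image_xy=np.zeros((2, 2)), ref_xy=np.ones((2, 2)))
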