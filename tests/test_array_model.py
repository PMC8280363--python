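"""Radiometric model: emission profile, superposition, poses."""

import numpy as np
import pytest

from pdtplan import (
    LEDArray,
    LEDSpec,
    PointCloud,
    illumination_matrix,
    irradiance_field,
    lambert_exponent,
    make_plane,
    pose_from_lesion,
    ray_geometry,
    rotate_array,
    single_led_irradiance,
)


class TestLambertExponent:
    def test_sixty_degree_half_angle_is_ideal_lambertian(self):
        assert lambert_exponent(60.0) == pytest.approx(1.0, abs=1e-15)

    def test_device_half_angle(self):
        assert lambert_exponent(15.0) == pytest.approx(19.994, abs=1e-3)

    def test_monotone_decreasing_in_psi(self):
        psis = np.linspace(1.0, 89.0, 45)
        ms = [lambert_exponent(p) for p in psis]
        assert np.all(np.diff(ms) < 0)
        assert ms[-1] < 0.2  # m -> 0+ as psi -> 90-

    @pytest.mark.parametrize("psi", [0.0, -5.0, 90.0, 95.0])
    def test_domain_errors(self, psi):
        with pytest.raises(ValueError):
            lambert_exponent(psi)

    def test_half_intensity_by_construction(self):
        # cos^m(psi) = 1/2 for the m derived from psi
        for psi in (15.0, 30.0, 47.5, 60.0):
            m = lambert_exponent(psi)
            assert np.cos(np.radians(psi)) ** m == pytest.approx(0.5, abs=1e-9)


class TestRayGeometry:
    def test_on_axis(self):
        ray = ray_geometry([0, 0, 0], [0, 0, 1], [0, 0, 100], [0, 0, -1])
        assert ray.r_cm == pytest.approx(10.0)
        assert ray.cos_theta == pytest.approx(1.0)
        assert ray.cos_phi == pytest.approx(1.0)

    def test_forty_five_degrees_off_axis(self):
        ray = ray_geometry([0, 0, 0], [0, 0, 1], [100, 0, 100], [0, 0, -1])
        assert ray.cos_phi == pytest.approx(np.cos(np.radians(45.0)))

    def test_grazing_normal(self):
        ray = ray_geometry([0, 0, 0], [0, 0, 1], [0, 0, 100], [1, 0, 0])
        assert ray.cos_theta == pytest.approx(0.0, abs=1e-12)

    def test_coincident_point_rejected(self):
        with pytest.raises(ValueError, match="degenerate|coincid"):
            ray_geometry([1, 2, 3], [0, 0, 1], [1, 2, 3], [0, 0, -1])


class TestSingleLed:
    def test_on_axis_device_intensity(self):
        spec = LEDSpec(i0=372.0)
        ray = ray_geometry([0, 0, 0], [0, 0, 1], [0, 0, 100], [0, 0, -1])
        assert single_led_irradiance(spec, ray) == pytest.approx(3.72)

    def test_back_facing_surface_gets_zero(self):
        spec = LEDSpec()
        ray = ray_geometry([0, 0, 0], [0, 0, 1], [0, 0, 100], [0, 0, 1])
        assert single_led_irradiance(spec, ray) == 0.0

    def test_inverse_square_law(self):
        spec = LEDSpec(i0=372.0)
        near = ray_geometry([0, 0, 0], [0, 0, 1], [0, 0, 100], [0, 0, -1])
        far = ray_geometry([0, 0, 0], [0, 0, 1], [0, 0, 200], [0, 0, -1])
        assert single_led_irradiance(spec, near) == pytest.approx(4 * single_led_irradiance(spec, far))

    def test_cos_power_profile(self):
        # I(phi)/I0 follows cos^m at fixed radius
        spec = LEDSpec(i0=100.0, psi_deg=15.0)
        on = single_led_irradiance(spec, ray_geometry([0, 0, 0], [0, 0, 1], [0, 0, 100], [0, 0, -1]))
        for phi_deg in (5.0, 10.0, 15.0):
            a = np.radians(phi_deg)
            p = 100.0 * np.array([np.sin(a), 0.0, np.cos(a)])
            n = -p / np.linalg.norm(p)  # normal back along the ray: cos_theta = 1
            off = single_led_irradiance(spec, ray_geometry([0, 0, 0], [0, 0, 1], p, n))
            assert off / on == pytest.approx(np.cos(a) ** spec.m, rel=1e-9)


class TestIlluminationMatrix:
    def test_single_led_single_point(self):
        array = LEDArray.grid(rows=1, cols=1)
        cloud = PointCloud([[0.0, 0, 100]], [[0.0, 0, -1]])
        mat = illumination_matrix(array, cloud)
        assert mat.entries.shape == (1, 1)
        assert mat.entries[0, 0] == pytest.approx(0.01)

    def test_back_facing_cloud_all_zero(self, default_array):
        cloud = PointCloud([[0.0, 0, 100], [10.0, 0, 100]], [[0.0, 0, 1], [0.0, 0, 1]])
        mat = illumination_matrix(default_array, cloud)
        assert np.all(mat.entries == 0.0)

    def test_linearity_contract_with_field(self, default_array):
        cloud = make_plane(10.0, 12, 10.0)
        mat = illumination_matrix(default_array, cloud)
        field = irradiance_field(default_array.with_intensities(372.0), cloud)
        assert np.allclose(mat.entries @ np.full(225, 372.0), field.values, rtol=1e-9)

    def test_requires_normals(self, default_array):
        with pytest.raises(ValueError, match="normals"):
            illumination_matrix(default_array, PointCloud([[0.0, 0, 100]]))

    def test_coincident_point_named(self):
        array = LEDArray.grid(rows=1, cols=1)
        cloud = PointCloud([[5.0, 0, 100], [0.0, 0, 0]], [[0.0, 0, -1], [0.0, 0, -1]])
        with pytest.raises(ValueError, match="point 1"):
            illumination_matrix(array, cloud)


class TestIrradianceField:
    def test_scaling_and_superposition_oracle(self, default_array, rng):
        """The array field is linear in I0 and equals the sum of per-LED fields."""
        cloud = make_plane(10.0, 7, 10.0)
        i0 = rng.uniform(0.0, 750.0, 225)
        field = irradiance_field(default_array.with_intensities(i0), cloud)
        doubled = irradiance_field(default_array.with_intensities(2 * i0), cloud)
        assert np.allclose(doubled.values, 2 * field.values, rtol=1e-12)
        # brute force: one LED at a time through the scalar path
        led = default_array.unit_positions_world
        brute = np.zeros(len(cloud))
        for j in range(225):
            for i in range(len(cloud)):
                ray = ray_geometry(led[j], [0, 0, 1], cloud.positions[i], cloud.normals[i])
                spec = LEDSpec(i0=372.0)
                brute[i] += i0[j] / 372.0 * single_led_irradiance(spec, ray)
        assert np.allclose(field.values, brute, rtol=1e-9)

    def test_zero_drive_zero_field(self, default_array):
        cloud = make_plane(10.0, 5, 10.0)
        field = irradiance_field(default_array.with_intensities(0.0), cloud)
        assert np.all(field.values == 0.0)

    def test_values_non_negative(self, default_array, rng):
        pts = rng.uniform(-60, 60, (50, 3))
        pts[:, 2] = rng.uniform(50, 150, 50)
        normals = rng.normal(size=(50, 3))
        normals /= np.linalg.norm(normals, axis=1)[:, None]
        cloud = PointCloud(pts, normals)
        field = irradiance_field(default_array, cloud)
        assert np.all(field.values >= 0.0)


class TestPose:
    def test_pose_from_plane_cloud(self, default_array):
        cloud = PointCloud(
            [[0.0, 0, 0], [10.0, 0, 0], [0.0, 10, 0], [10.0, 10, 0]],
            np.tile([0.0, 0, -1], (4, 1)),
        )
        posed = pose_from_lesion(default_array, cloud, distance_cm=10.0)
        assert np.allclose(posed.panel_center_world, [5.0, 5.0, -100.0])
        assert np.allclose(posed.axis_world, [0.0, 0.0, 1.0])

    def test_posing_is_deterministic(self, default_array, lesion_cloud):
        a = pose_from_lesion(default_array, lesion_cloud, 10.0)
        b = pose_from_lesion(default_array, lesion_cloud, 10.0)
        assert np.array_equal(a.rotation, b.rotation)
        assert np.array_equal(a.translation_mm, b.translation_mm)

    def test_posed_centroid_irradiance_matches_scalar_stack(self, default_array, lesion_cloud):
        from pdtplan import average_normal

        posed = pose_from_lesion(default_array, lesion_cloud, 10.0)
        centre = PointCloud([lesion_cloud.centroid], [average_normal(lesion_cloud)])
        field = irradiance_field(posed.with_intensities(372.0), centre)
        led = posed.unit_positions_world
        axis = posed.axis_world
        total = sum(
            single_led_irradiance(
                LEDSpec(i0=372.0),
                ray_geometry(led[j], axis, centre.positions[0], centre.normals[0]),
            )
            for j in range(225)
        )
        assert field.values[0] == pytest.approx(total, rel=1e-6)

    def test_rotation_group_properties(self, default_array, lesion_cloud):
        posed = pose_from_lesion(default_array, lesion_cloud, 10.0)
        pivot = lesion_cloud.centroid
        assert np.allclose(rotate_array(posed, 0.0, pivot).rotation, posed.rotation)
        back = rotate_array(rotate_array(posed, 5.0, pivot), -5.0, pivot)
        assert np.allclose(back.rotation, posed.rotation, atol=1e-12)
        assert np.allclose(back.translation_mm, posed.translation_mm, atol=1e-12)
        for angle in (3.0, 45.0, 170.0):
            rot = rotate_array(posed, angle, pivot)
            assert np.linalg.norm(rot.panel_center_world - pivot) == pytest.approx(
                np.linalg.norm(posed.panel_center_world - pivot), rel=1e-12
            )
            # rigid motion: pairwise LED distances preserved
            d0 = np.linalg.norm(posed.unit_positions_world[0] - posed.unit_positions_world[-1])
            d1 = np.linalg.norm(rot.unit_positions_world[0] - rot.unit_positions_world[-1])
            assert d1 == pytest.approx(d0, abs=1e-12)


class TestSpecValidation:
    def test_ledspec_bounds(self):
        with pytest.raises(ValueError):
            LEDSpec(i0=800.0, hs=750.0)
        with pytest.raises(ValueError):
            LEDSpec(m=5.0)  # inconsistent with psi = 15

    def test_array_invariants(self):
        arr = LEDArray.grid()
        assert arr.n_units == 225
        # 10 mm pitch
        xs = np.unique(arr.unit_positions[:, 0])
        assert np.allclose(np.diff(xs), 10.0)
        with pytest.raises(ValueError):
            LEDArray(arr.unit_positions, rotation=np.diag([1.0, 1.0, -1.0]))
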