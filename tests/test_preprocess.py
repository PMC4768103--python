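"""Background-phase correction, VENC unwrapping and velocity interpolation."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from vortexlcs.exceptions import ConfigurationError, DomainError, FitError
from vortexlcs.flow_io import StationaryTissueMask, VelocityField4D
from vortexlcs.preprocess import (
    VelocityInterpolator,
    correct_background_phase,
    sample_velocity,
    unwrap_velocity,
)
from vortexlcs.synthetic_data import (
    GridSpec,
    hill_vortex_velocity,
    inject_wraps,
    sample_to_field,
)


def _hill_grid():
    return GridSpec(
        shape=(20, 20, 20),
        spacing=(4.0, 4.0, 4.0),
        origin=(-38.0, -38.0, -38.0),
        time_points=np.array([0.0, 100.0]),
    )


def _border_mask(shape_zyx, width=2):
    m = np.zeros(shape_zyx, dtype=bool)
    m[:width], m[-width:] = True, True
    m[:, :width], m[:, -width:] = True, True
    m[:, :, :width], m[:, :, -width:] = True, True
    return StationaryTissueMask(m)


class TestBackgroundCorrection:
    def test_zero_offset_identity(self):
        grid = _hill_grid()
        field = sample_to_field(
            lambda p, t: hill_vortex_velocity(p, t, a_mm=15.0, U_cm_s=10.0), grid
        )
        corrected, _ = correct_background_phase(field, _border_mask(field.shape_zyx))
        # far from the vortex the lab-frame flow is the ~zero dipole tail, so the
        # fitted plane over a symmetric border shell is essentially null
        assert np.max(np.abs(corrected.velocity - field.velocity)) < 0.1

    def test_constant_offset_removed(self):
        grid = _hill_grid()
        field = sample_to_field(lambda p, t: np.full((len(np.atleast_2d(p)), 3), 2.0), grid)
        mask = StationaryTissueMask(np.ones(field.shape_zyx, dtype=bool))
        corrected, model = correct_background_phase(field, mask)
        assert np.max(np.abs(corrected.velocity)) < 1e-10
        assert np.allclose(model.world_coefficients()[:, :, 0], 2.0)

    def test_injected_plane_recovered_against_normal_equations(self):
        grid = _hill_grid()
        plane_coeff = np.array([1.0, 0.05, -0.02, 0.0])  # c0, cx, cy, cz

        def velocity(p, t):
            p = np.atleast_2d(p)
            v = hill_vortex_velocity(p, t, a_mm=12.0, U_cm_s=10.0, translating=False)
            v = v + 10.0  # undo the free stream so the border is ~static
            offset = plane_coeff[0] + p @ plane_coeff[1:]
            v[:, 0] += offset
            return v

        def base(p, t):
            v = hill_vortex_velocity(
                np.atleast_2d(p), t, a_mm=12.0, U_cm_s=10.0, translating=False
            )
            return v + 10.0

        field = sample_to_field(velocity, grid)
        clean = sample_to_field(base, grid)
        # border shell where the Hill interior never reaches: treat the (small)
        # dipole tail as part of the background-free signal by masking on the
        # difference being exactly the plane -> use a wide border shell
        mask = _border_mask(field.shape_zyx, width=2)
        corrected, model = correct_background_phase(field, mask)

        # independent oracle: explicit normal-equations solve on masked voxels
        x = field.axis_coordinates(0)
        y = field.axis_coordinates(1)
        z = field.axis_coordinates(2)
        Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
        m = mask.mask
        A = np.column_stack([np.ones(m.sum()), X[m], Y[m], Z[m]])
        b = field.velocity[0, ..., 0][m]
        oracle = np.linalg.solve(A.T @ A, A.T @ b)

        recovered = model.world_coefficients()[0, 0]
        np.testing.assert_allclose(recovered, oracle, atol=1e-9)
        # the fitted plane includes the dipole-tail bias sampled on the border;
        # against the *injected* coefficients the residual plane is small but
        # the exact match is with the normal-equations oracle above
        resid = corrected.velocity[0, ..., 0] - clean.velocity[0, ..., 0]
        assert np.ptp(resid[m]) < 0.2

    def test_pure_plane_recovered_exactly(self):
        grid = _hill_grid()
        plane_coeff = np.array([1.0, 0.05, -0.02, 0.01])

        def velocity(p, t):
            p = np.atleast_2d(p)
            v = np.zeros_like(p)
            v[:, 1] = plane_coeff[0] + p @ plane_coeff[1:]
            return v

        field = sample_to_field(velocity, grid)
        corrected, model = correct_background_phase(field, _border_mask(field.shape_zyx))
        np.testing.assert_allclose(
            model.world_coefficients()[0, 1], plane_coeff, atol=1e-6
        )
        assert np.max(np.abs(corrected.velocity)) <= 1e-6

    def test_idempotent(self, random_field):
        mask = StationaryTissueMask(np.ones(random_field.shape_zyx, dtype=bool))
        once, _ = correct_background_phase(random_field, mask)
        twice, _ = correct_background_phase(once, mask)
        assert np.max(np.abs(twice.velocity - once.velocity)) <= 1e-8

    def test_degenerate_mask_raises(self, random_field):
        m = np.zeros(random_field.shape_zyx, dtype=bool)
        m[0, 0, :] = True  # coplanar voxels: rank-deficient design
        m[1, 0, :] = True
        with pytest.raises(FitError):
            correct_background_phase(random_field, StationaryTissueMask(m))


class TestUnwrap:
    def test_identity_below_venc(self, random_field):
        random_field.venc = 200.0
        out, n = unwrap_velocity(random_field)
        # smooth-ish noise below venc: nothing should change
        assert np.array_equal(out.velocity, random_field.velocity)

    def test_single_wrapped_voxel_shifted(self):
        venc = 100.0
        vel = np.full((2, 5, 5, 5, 3), 95.0)
        true_value = 1.2 * venc
        vel[0, 2, 2, 2, 0] = true_value - 2 * venc
        field = VelocityField4D(
            vel, (3, 3, 3), (0, 0, 0), np.array([0.0, 50.0]), venc=venc
        )
        out, n = unwrap_velocity(field)
        assert out.velocity[0, 2, 2, 2, 0] == pytest.approx(true_value)
        assert n == 1

    def test_smooth_jet_wraps_recovered_exactly(self):
        venc = 80.0
        grid = GridSpec(
            shape=(15, 15, 9), spacing=(3, 3, 3), origin=(-21, -21, -12),
            time_points=np.array([0.0, 50.0, 100.0]),
        )

        def jet(p, t):
            p = np.atleast_2d(p)
            v = np.zeros_like(p)
            envelope = np.exp(-(p[:, 0] ** 2 + p[:, 1] ** 2) / (2 * 8.0**2))
            v[:, 2] = 1.5 * venc * envelope * np.sin(np.pi * (t + 25.0) / 150.0)
            return v

        clean = sample_to_field(jet, grid)
        wrapped, record = inject_wraps(clean, venc)
        assert record.any()
        out, n = unwrap_velocity(wrapped)
        np.testing.assert_array_equal(out.velocity, clean.velocity)
        assert n == int(record.sum())

    def test_requires_venc(self, random_field):
        random_field.venc = None
        with pytest.raises(ConfigurationError):
            unwrap_velocity(random_field)

    def test_manual_override_applied(self, random_field):
        random_field.venc = 500.0
        out, n = unwrap_velocity(
            random_field,
            manual_overrides=[{"timeframe": 1, "voxel": [2, 3, 4], "component": 0, "wraps": 1}],
        )
        delta = out.velocity[1, 2, 3, 4, 0] - random_field.velocity[1, 2, 3, 4, 0]
        assert delta == pytest.approx(1000.0)


class TestSampling:
    def test_exact_at_voxel_center_and_timepoint(self, random_field):
        pos = random_field.grid_origin + np.array([2, 3, 1]) * random_field.grid_spacing
        vel, out = sample_velocity(random_field, pos, random_field.time_points[2])
        np.testing.assert_array_equal(vel, random_field.velocity[2, 1, 3, 2])
        assert not out

    def test_linear_field_exact_between_voxels(self, coarse_grid):
        k = 0.3  # cm/s per mm

        def linear(p, t):
            p = np.atleast_2d(p)
            v = np.zeros_like(p)
            v[:, 0] = k * p[:, 0]
            return v

        field = sample_to_field(linear, coarse_grid)
        vel, _ = sample_velocity(field, (7.3, -3.1, 12.9), 100.0)
        assert vel[0] == pytest.approx(k * 7.3, abs=1e-12)

    def test_affine_space_time_reproduced_exactly(self, coarse_grid, rng):
        c = np.array([3.0, -2.0, 1.0])

        def affine(p, t):
            p = np.atleast_2d(p)
            return np.outer(p @ c, [1.0, 0.5, -0.25]) * (1.0 + t / 400.0)

        field = sample_to_field(affine, coarse_grid)
        sampler = VelocityInterpolator(field)
        pts = rng.uniform(-35, 35, size=(200, 3))
        for t in (0.0, 137.0, 400.0):
            vel, out = sampler(pts, t)
            np.testing.assert_allclose(vel, affine(pts, t), atol=1e-9)
            assert not out.any()

    def test_random_queries_match_scipy_oracle(self, random_field, rng):
        sampler = VelocityInterpolator(random_field)
        x = random_field.axis_coordinates(0)
        y = random_field.axis_coordinates(1)
        z = random_field.axis_coordinates(2)
        t = random_field.time_points
        oracle = RegularGridInterpolator(
            (t, z, y, x), random_field.velocity, method="linear"
        )
        pts = np.column_stack(
            [
                rng.uniform(x[0], x[-1], 10_000),
                rng.uniform(y[0], y[-1], 10_000),
                rng.uniform(z[0], z[-1], 10_000),
            ]
        )
        for time in (0.0, 37.0, 120.0, 200.0):
            vel, out = sampler(pts, time)
            assert not out.any()
            query = np.column_stack(
                [np.full(len(pts), time), pts[:, 2], pts[:, 1], pts[:, 0]]
            )
            np.testing.assert_allclose(vel, oracle(query), atol=1e-8)

    def test_outside_grid_zero_and_flagged(self, random_field):
        vel, out = sample_velocity(random_field, (1e4, 0.0, 0.0), 0.0)
        assert out
        np.testing.assert_array_equal(vel, 0.0)

    def test_time_outside_span_raises(self, random_field):
        with pytest.raises(DomainError):
            sample_velocity(random_field, (0.0, 0.0, 0.0), 1e5)
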