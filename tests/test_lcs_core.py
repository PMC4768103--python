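"""Seeding, backward advection, FTLE and delineation geometry."""

import warnings

import numpy as np
import pytest

from vortexlcs.exceptions import ConfigurationError, DomainError
from vortexlcs.flow_io import ContourSet
from vortexlcs.geometry import circle_polygon, polygon_area, union_area
from vortexlcs.lcs_core import (
    FTLEField,
    ParticleGrid,
    SeedingPlane,
    advect_backward,
    compute_ftle,
    crop_to_endocardium,
    delineate_vortex,
    extract_lcs,
    seed_grid,
)
from vortexlcs.synthetic_data import (
    GridSpec,
    double_gyre_velocity,
    planar_strain_velocity,
    sample_to_field,
    solid_rotation_velocity,
    uniform_velocity,
)


def _plane(half=20.0, z=0.0):
    return SeedingPlane.short_axis((0.0, 0.0), z, half)


class TestSeeding:
    def test_40mm_plane_at_0p8_gives_2601_seeds(self):
        plane = SeedingPlane(
            origin=(0, 0, 0), axis_u=(1, 0, 0), axis_v=(0, 1, 0), extent_u=40.0, extent_v=40.0
        )
        grid = seed_grid(plane, 0.8)
        assert grid.shape == (51, 51)
        assert grid.n_seeds == 2601

    def test_zero_extent_degenerates_to_single_seed(self):
        plane = SeedingPlane(
            origin=(1, 2, 3), axis_u=(1, 0, 0), axis_v=(0, 1, 0), extent_u=0.0, extent_v=0.0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = seed_grid(plane, 0.8)
        assert grid.n_seeds == 1
        np.testing.assert_allclose(grid.positions[0, 0], (1, 2, 3))

    def test_oblique_plane_seeds_on_plane_with_exact_spacing(self):
        c, s = np.cos(np.pi / 6), np.sin(np.pi / 6)
        plane = SeedingPlane(
            origin=(5, -3, 2),
            axis_u=(c, s, 0),
            axis_v=(-s * 0.5, c * 0.5, np.sqrt(3) / 2),
            extent_u=16.0,
            extent_v=16.0,
        )
        grid = seed_grid(plane, 0.8)
        normal = plane.normal
        offsets = (grid.positions.reshape(-1, 3) - plane.origin) @ normal
        assert np.max(np.abs(offsets)) <= 1e-9
        row_spacing = np.linalg.norm(np.diff(grid.positions[:, 0, :], axis=0), axis=1)
        np.testing.assert_allclose(row_spacing, 0.8, atol=1e-9)

    def test_invalid_plane_axes_rejected(self):
        with pytest.raises(ConfigurationError):
            SeedingPlane(
                origin=(0, 0, 0), axis_u=(1, 0, 0), axis_v=(1, 0, 0), extent_u=1, extent_v=1
            )


class TestAdvection:
    def test_zero_field_identity(self, coarse_grid):
        field = sample_to_field(lambda p, t: np.zeros_like(np.atleast_2d(p)), coarse_grid)
        grid = seed_grid(_plane(15.0), 2.0)
        fmap = advect_backward(grid, field, 300.0, 100.0, 5.0)
        np.testing.assert_array_equal(fmap.end_positions, grid.positions)
        assert not fmap.out_of_domain.any()

    def test_uniform_field_closed_form(self, coarse_grid):
        c = 10.0  # cm/s along x
        field = sample_to_field(lambda p, t: uniform_velocity(p, t, (c, 0, 0)), coarse_grid)
        grid = seed_grid(_plane(10.0), 2.0)
        fmap = advect_backward(grid, field, 300.0, 100.0, 5.0)
        expected = grid.positions.copy()
        expected[..., 0] -= c * 0.01 * 200.0  # cm/s -> mm/ms over 200 ms
        np.testing.assert_allclose(fmap.end_positions, expected, atol=1e-12)

    def test_partial_final_step_lands_exactly(self, coarse_grid):
        field = sample_to_field(lambda p, t: uniform_velocity(p, t, (10, 0, 0)), coarse_grid)
        grid = seed_grid(_plane(5.0), 2.5)
        fmap = advect_backward(grid, field, 300.0, 107.0, 5.0)  # span not divisible by 5
        expected_shift = -10 * 0.01 * (300.0 - 107.0)
        np.testing.assert_allclose(
            fmap.end_positions[..., 0] - grid.positions[..., 0], expected_shift, atol=1e-12
        )

    def test_solid_rotation_fourth_order_convergence(self, coarse_grid):
        omega = 10.0  # rad/s
        field = sample_to_field(
            lambda p, t: solid_rotation_velocity(p, t, omega), coarse_grid
        )
        grid = seed_grid(SeedingPlane.short_axis((10.0, 0.0), 0.0, 10.0), 5.0)
        span = 200.0
        theta = -omega * span / 1000.0  # backward rotation
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        errors = []
        for step in (20.0, 10.0, 5.0, 2.5):
            fmap = advect_backward(grid, field, 250.0, 50.0, step)
            exact = grid.positions @ R.T
            errors.append(np.max(np.linalg.norm(fmap.end_positions - exact, axis=-1)))
        orders = np.log2(np.array(errors[:-1]) / np.array(errors[1:]))
        assert np.all(orders >= 3.5)

    def test_flow_map_composition(self):
        grid_spec = GridSpec(
            shape=(51, 26, 3),
            spacing=(4.0, 4.0, 10.0),
            origin=(0.0, 0.0, -10.0),
            time_points=np.arange(0.0, 2001.0, 100.0),
        )
        field = sample_to_field(double_gyre_velocity, grid_spec)
        plane = SeedingPlane(
            origin=(20, 20, 0), axis_u=(1, 0, 0), axis_v=(0, 1, 0), extent_u=160, extent_v=60
        )
        grid = seed_grid(plane, 4.0)
        t2, t1, t0 = 2000.0, 1000.0, 0.0
        direct = advect_backward(grid, field, t2, t0, 5.0)
        first = advect_backward(grid, field, t2, t1, 5.0)
        mid_grid = ParticleGrid(plane=plane, spacing=grid.spacing, positions=first.end_positions)
        second = advect_backward(mid_grid, field, t1, t0, 5.0)
        gap = np.linalg.norm(direct.end_positions - second.end_positions, axis=-1)
        assert np.max(gap) <= 0.1  # mm

    def test_invalid_step_and_times(self, coarse_grid):
        field = sample_to_field(lambda p, t: np.zeros_like(np.atleast_2d(p)), coarse_grid)
        grid = seed_grid(_plane(5.0), 2.5)
        with pytest.raises(ConfigurationError):
            advect_backward(grid, field, 300.0, 100.0, step=-5.0)
        with pytest.raises(DomainError):
            advect_backward(grid, field, 100.0, 300.0)
        with pytest.raises(DomainError):
            advect_backward(grid, field, 900.0, 100.0)  # beyond acquired span


class TestFTLE:
    def test_uniform_translation_zero_ftle(self, coarse_grid):
        field = sample_to_field(lambda p, t: uniform_velocity(p, t, (20, -10, 5)), coarse_grid)
        grid = seed_grid(_plane(8.0), 1.0)
        ftle = compute_ftle(advect_backward(grid, field, 300.0, 200.0), grid)
        assert np.max(np.abs(ftle.values[~ftle.flagged])) <= 1e-10

    @pytest.mark.parametrize("span", [100.0, 300.0])
    def test_planar_strain_ftle_equals_k_independent_of_span(self, coarse_grid, span):
        k = 3.0  # 1/s
        field = sample_to_field(lambda p, t: planar_strain_velocity(p, t, k), coarse_grid)
        grid = seed_grid(_plane(10.0), 1.0)
        fmap = advect_backward(grid, field, 350.0, 350.0 - span)
        ftle = compute_ftle(fmap, grid)
        vals = ftle.values[~ftle.flagged]
        np.testing.assert_allclose(vals, k, rtol=0.01)

    def test_backward_ftle_nonnegative_for_incompressible_2d(self):
        grid_spec = GridSpec(
            shape=(51, 26, 3),
            spacing=(4.0, 4.0, 10.0),
            origin=(0.0, 0.0, -10.0),
            time_points=np.arange(0.0, 1501.0, 100.0),
        )
        field = sample_to_field(double_gyre_velocity, grid_spec)
        plane = SeedingPlane(
            origin=(10, 10, 0), axis_u=(1, 0, 0), axis_v=(0, 1, 0), extent_u=180, extent_v=80
        )
        grid = seed_grid(plane, 2.0)
        ftle = compute_ftle(advect_backward(grid, field, 1500.0, 0.0), grid)
        # area preservation forces lambda_max >= 1, so FTLE >= -epsilon
        assert ftle.values[~ftle.flagged].min() >= -1e-6

    def test_small_grid_rejected(self, coarse_grid):
        field = sample_to_field(lambda p, t: np.zeros_like(np.atleast_2d(p)), coarse_grid)
        grid = seed_grid(_plane(1.0), 1.0)  # 3x3 ok
        fmap = advect_backward(grid, field, 300.0, 100.0)
        compute_ftle(fmap, grid)
        tiny = seed_grid(_plane(0.5), 1.0)  # 2x2
        with pytest.raises(DomainError):
            compute_ftle(advect_backward(tiny, field, 300.0, 100.0), tiny)


def _ftle_field(values, flagged=None, span=200.0):
    values = np.asarray(values, dtype=float)
    return FTLEField(
        values=values,
        flagged=np.zeros_like(values, dtype=bool) if flagged is None else flagged,
        t_seed=300.0,
        span_ms=span,
    )


class TestRidgeExtraction:
    def test_uniform_0_100_distribution(self):
        values = np.linspace(0.0, 100.0, 101 * 41).reshape(101, 41)
        ftle = _ftle_field(values)
        mask = extract_lcs(ftle)
        assert ftle.p95 == pytest.approx(95.0, abs=0.01)
        np.testing.assert_array_equal(mask, values > 0.5 * ftle.p95)

    def test_constant_positive_field_all_true(self):
        ftle = _ftle_field(np.full((10, 10), 4.0))
        assert extract_lcs(ftle).all()  # c > 0.5 c everywhere

    def test_degenerate_normalization_empty_mask(self):
        ftle = _ftle_field(np.zeros((10, 10)))
        with pytest.warns(UserWarning):
            mask = extract_lcs(ftle)
        assert not mask.any()

    def test_flagged_seeds_excluded(self):
        values = np.ones((10, 10))
        flagged = np.zeros((10, 10), dtype=bool)
        flagged[0] = True
        values[0] = 1e6  # would dominate p95 if not excluded
        mask = extract_lcs(_ftle_field(values, flagged))
        assert not mask[0].any()
        assert mask[1:].all()

    def test_threshold_fraction_validated(self):
        with pytest.raises(ConfigurationError):
            extract_lcs(_ftle_field(np.ones((5, 5))), threshold_fraction=1.5)


def _annulus_mask(n=81, r_in=22, r_out=26):
    idx = np.arange(n) - n // 2
    R = np.hypot(idx[:, None], idx[None, :])
    return (R >= r_in) & (R <= r_out)


class TestDelineation:
    def test_closed_annulus_single_polygon(self):
        grid = seed_grid(_plane(32.0), 0.8)
        mask = _annulus_mask(grid.shape[0])
        cs = delineate_vortex(mask, grid)
        polys = [p for pl in cs.contours.values() for p in pl]
        assert len(polys) == 1
        r_mid = 0.5 * (22 + 26) * 0.8
        assert polygon_area(polys[0]) == pytest.approx(np.pi * r_mid**2, rel=0.05)

    def test_gapped_annulus_bridged_to_within_2pct(self):
        grid = seed_grid(_plane(32.0), 0.8)
        full = _annulus_mask(grid.shape[0])
        gapped = full.copy()
        n = grid.shape[0]
        idx = np.arange(n) - n // 2
        theta = np.arctan2(idx[None, :], idx[:, None])
        for ang in (0.3, 2.4, -1.8):  # three gaps a few seeds wide
            gapped &= ~(np.abs(((theta - ang + np.pi) % (2 * np.pi)) - np.pi) < 0.12)
        ref = delineate_vortex(full, grid)
        cs = delineate_vortex(gapped, grid)
        a_ref = union_area([p for pl in ref.contours.values() for p in pl])
        a_gap = union_area([p for pl in cs.contours.values() for p in pl])
        assert a_gap == pytest.approx(a_ref, rel=0.02)

    def test_blobs_below_floor_discarded(self):
        grid = seed_grid(_plane(32.0), 0.8)
        mask = np.zeros(grid.shape, dtype=bool)
        mask[5:8, 5:8] = True
        mask[60:63, 60:63] = True
        with pytest.warns(UserWarning):
            cs = delineate_vortex(mask, grid, min_area_mm2=30.0)
        assert cs.n_polygons == 0

    def test_empty_mask_warns(self):
        grid = seed_grid(_plane(5.0), 0.8)
        with pytest.warns(UserWarning):
            cs = delineate_vortex(np.zeros(grid.shape, dtype=bool), grid)
        assert cs.n_polygons == 0

    def test_crest_path_recovers_annulus_centerline(self):
        grid = seed_grid(_plane(32.0), 0.8)
        mask = _annulus_mask(grid.shape[0])
        n = grid.shape[0]
        idx = np.arange(n) - n // 2
        R = np.hypot(idx[:, None], idx[None, :])
        values = np.where(mask, 10.0 - np.abs(R - 24.0), 0.0)  # crest at R=24 px
        cs = delineate_vortex(mask, grid, values=values, locator="crest")
        polys = [p for pl in cs.contours.values() for p in pl]
        assert len(polys) == 1
        r_eff = np.sqrt(polygon_area(polys[0]) / np.pi)
        assert r_eff == pytest.approx(24.0 * 0.8, rel=0.03)


class TestCropping:
    def test_lcs_inside_endocardium_unchanged(self):
        lcs = ContourSet(label="lcs")
        endo = ContourSet(label="endocardium")
        lcs.add(0, 0, circle_polygon((0, 0), 10.0, 0.0))
        endo.add(0, 0, circle_polygon((0, 0), 25.0, 0.0))
        out = crop_to_endocardium(lcs, endo)
        assert union_area(out.polygons(0, 0)) == pytest.approx(
            union_area(lcs.polygons(0, 0)), rel=1e-6
        )

    def test_half_overlapping_squares(self):
        lcs = ContourSet(label="lcs")
        endo = ContourSet(label="endocardium")
        sq = lambda x0: np.array(
            [[x0, 0, 0], [x0 + 20, 0, 0], [x0 + 20, 20, 0], [x0, 20, 0.0]]
        )
        lcs.add(0, 0, sq(0.0))
        endo.add(0, 0, sq(10.0))
        out = crop_to_endocardium(lcs, endo)
        assert union_area(out.polygons(0, 0)) == pytest.approx(200.0)

    def test_missing_endo_timeframe_skipped(self):
        lcs = ContourSet(label="lcs")
        lcs.add(0, 0, circle_polygon((0, 0), 10.0, 0.0))
        lcs.add(1, 0, circle_polygon((0, 0), 10.0, 0.0))
        endo = ContourSet(label="endocardium")
        endo.add(0, 0, circle_polygon((0, 0), 25.0, 0.0))
        with pytest.warns(UserWarning):
            out = crop_to_endocardium(lcs, endo)
        assert out.polygons(0, 0) and not out.polygons(1, 0)

    def test_random_convex_pairs_match_rasterization_oracle(self, rng):
        for _ in range(100):
            def convex():
                ang = np.sort(rng.uniform(0, 2 * np.pi, 12))
                r = rng.uniform(8, 20)
                cx, cy = rng.uniform(-6, 6, 2)
                return np.column_stack(
                    [cx + r * np.cos(ang), cy + r * np.sin(ang), np.zeros(len(ang))]
                )

            a, b = convex(), convex()
            lcs = ContourSet(label="lcs")
            endo = ContourSet(label="endocardium")
            lcs.add(0, 0, a)
            endo.add(0, 0, b)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = crop_to_endocardium(lcs, endo)
            area = union_area(out.polygons(0, 0)) if out.polygons(0, 0) else 0.0

            # rasterization oracle on a 0.2 mm lattice
            xs = np.arange(-30, 30, 0.2) + 0.1
            X, Y = np.meshgrid(xs, xs)
            from matplotlib.path import Path as MplPath

            inside_a = MplPath(a[:, :2]).contains_points(np.column_stack([X.ravel(), Y.ravel()]))
            inside_b = MplPath(b[:, :2]).contains_points(np.column_stack([X.ravel(), Y.ravel()]))
            oracle = float(np.count_nonzero(inside_a & inside_b)) * 0.04
            assert area == pytest.approx(oracle, abs=max(0.01 * max(oracle, 1.0), 1.5))
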