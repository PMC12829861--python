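import dataclasses
import math

import numpy as np
import pytest

from refugia import (
    GridSpec,
    ScenarioConfig,
    generate_environment,
    generate_habitat_preferences,
    generate_occupancy,
    generate_pas,
    generate_species_surfaces,
)


@pytest.fixture
def grid():
    return GridSpec(n_cols=12, n_rows=12, fine_factor=4)


class TestEnvironment:
    def test_seeded_reproducibility(self, grid, small_scenario):
        e1, l1 = generate_environment(grid, small_scenario)
        e2, l2 = generate_environment(grid, small_scenario)
        np.testing.assert_array_equal(e1.values, e2.values)
        np.testing.assert_array_equal(l1.values, l2.values)

    def test_zero_grf_amplitude_gives_pure_ramp(self, grid, small_scenario):
        sc = dataclasses.replace(
            small_scenario, grf_amplitude=0.0, grf_amplitude_fine=0.0
        )
        elev, _ = generate_environment(grid, sc)
        fine = grid.fine()
        _, ys = fine.cell_centers()
        expected = sc.elevation_ramp * (ys - fine.origin_y)
        np.testing.assert_allclose(elev.values, expected[:, None] * np.ones(fine.n_cols))

    def test_single_landcover_class(self, grid, small_scenario):
        sc = dataclasses.replace(small_scenario, n_landcover_classes=1)
        _, lc = generate_environment(grid, sc)
        assert set(np.unique(lc.values)) == {1}

    def test_physical_ranges(self, grid, small_scenario):
        elev, lc = generate_environment(grid, small_scenario)
        assert (elev.values >= 0).all()
        assert lc.values.min() >= 1
        assert lc.values.max() <= small_scenario.n_landcover_classes


class TestSpeciesSurfaces:
    def test_no_change_limit(self, grid, small_scenario):
        sc = dataclasses.replace(small_scenario, warming_shift=0.0, elevation_shift=0.0)
        cur, fut = generate_species_surfaces(grid, sc, 0)
        np.testing.assert_array_equal(cur.values, fut.values)

    def test_values_in_unit_interval(self, grid, small_scenario):
        cur, fut = generate_species_surfaces(grid, small_scenario, 1)
        for g in (cur, fut):
            assert g.values.min() >= 0.0 and g.values.max() <= 1.0

    def test_warming_shifts_weighted_mean_northing_poleward(self, grid, small_scenario):
        """Brute-force suitability-weighted mean northing must move north."""
        sc = dataclasses.replace(small_scenario, warming_shift=60_000.0)
        cur, fut = generate_species_surfaces(grid, sc, 0)
        _, ys = grid.cell_centers()
        yy = np.repeat(ys[:, None], grid.n_cols, axis=1)

        def weighted_mean_northing(g):
            return float((g.values * yy).sum() / g.values.sum())

        assert weighted_mean_northing(fut) > weighted_mean_northing(cur)

    def test_species_index_bound(self, grid, small_scenario):
        with pytest.raises(ValueError):
            generate_species_surfaces(grid, small_scenario, small_scenario.n_species)


class TestOccupancy:
    def test_rate_one_cut_zero_occupies_everything(self, grid, small_scenario):
        sc = dataclasses.replace(small_scenario, occupancy_rate=1.0, occupancy_cut=0.0)
        cur, _ = generate_species_surfaces(grid, sc, 0)
        assert cur.values.min() > 0  # inverse-logit never reaches 0
        occ = generate_occupancy(cur, sc)
        assert len(occ) == grid.n_cols * grid.n_rows

    def test_deterministic_limit_above_cut(self, small_scenario):
        from conftest import make_suitability

        vals = np.array([[0.1, 0.9], [0.6, 0.2], [0.95, 0.3]])
        cur = make_suitability(vals)
        sc = dataclasses.replace(small_scenario, occupancy_rate=1.0, occupancy_cut=0.5)
        occ = generate_occupancy(cur, sc)
        assert occ.cells == {(1, 0), (0, 1), (0, 2)}

    def test_occupied_cells_are_biased_to_high_suitability(self, grid, small_scenario):
        cur, _ = generate_species_surfaces(grid, small_scenario, 2)
        occ = generate_occupancy(cur, small_scenario)
        assert len(occ) > 0
        mask = occ.to_mask(grid)
        assert cur.values[mask].mean() >= cur.values.mean()

    def test_seeded_reproducibility(self, grid, small_scenario):
        cur, _ = generate_species_surfaces(grid, small_scenario, 0)
        occ1 = generate_occupancy(cur, small_scenario)
        occ2 = generate_occupancy(cur, small_scenario)
        assert occ1.cells == occ2.cells


class TestProtectedAreas:
    def test_polygons_within_grid_bounds(self, grid, small_scenario):
        from shapely.geometry import box

        extent = box(*grid.extent)
        pas = generate_pas(grid, small_scenario)
        assert len(pas) == small_scenario.n_pas
        assert len({pa.pa_id for pa in pas}) == small_scenario.n_pas
        for pa in pas:
            assert pa.geometry.within(extent.buffer(1e-6))

    def test_zero_log_sd_gives_equal_areas(self, grid, small_scenario):
        sc = dataclasses.replace(
            small_scenario, pa_area_log_sd=0.0, pa_area_log_mean=math.log(2.5e5)
        )
        pas = generate_pas(grid, sc)
        minx, miny, maxx, maxy = grid.extent
        for pa in pas:
            bx = pa.geometry.bounds
            clipped = (
                bx[0] <= minx or bx[1] <= miny or bx[2] >= maxx or bx[3] >= maxy
            )
            if not clipped:
                assert pa.area == pytest.approx(2.5e5, rel=1e-9)

    def test_lognormal_sizes_are_right_skewed(self, small_scenario):
        grid = GridSpec(n_cols=30, n_rows=30, fine_factor=2)
        sc = dataclasses.replace(small_scenario, n_pas=500, pa_area_log_sd=1.0)
        areas = np.array([pa.area for pa in generate_pas(grid, sc)])
        assert np.median(areas) < areas.mean()

    def test_seeded_reproducibility(self, grid, small_scenario):
        p1 = generate_pas(grid, small_scenario)
        p2 = generate_pas(grid, small_scenario)
        assert all(a.geometry.equals(b.geometry) for a, b in zip(p1, p2))


class TestHabitatPreferences:
    def test_classes_exist_and_counts_bounded(self, small_scenario):
        prefs = generate_habitat_preferences(small_scenario)
        assert len(prefs) == small_scenario.n_species
        for p in prefs:
            assert p.preferred_classes <= set(
                range(1, small_scenario.n_landcover_classes + 1)
            )
            assert (
                small_scenario.min_preferred_classes
                <= len(p.preferred_classes)
                <= small_scenario.max_preferred_classes
            )


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"occupancy_rate": 0.0},
            {"occupancy_rate": 1.5},
            {"n_pas": 0},
            {"warming_shift": -1.0},
            {"pa_quality_coupling": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioConfig(**kwargs)
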