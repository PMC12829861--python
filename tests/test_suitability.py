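import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import box

from conftest import make_raster, make_suitability
from refugia import (
    GridSpec,
    HabitatPreference,
    OccupancySet,
    PAOutsideDomainError,
    ProtectedArea,
    build_pa_suitability_table,
    compute_threshold,
    pa_max_suitability,
    refine_by_habitat,
)


def brute_force_percentile(scores, p):
    """Independent linear-interpolation percentile: position (n-1)*p/100."""
    xs = sorted(scores)
    pos = (len(xs) - 1) * p / 100.0
    lo, hi = int(np.floor(pos)), int(np.ceil(pos))
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


class TestRefineByHabitat:
    def grid_pair(self):
        suit = make_suitability([[0.8, 0.5]], fine_factor=2)
        # fine land cover 2x4: cell 0 contains class 2 once, cell 1 never
        lc = make_raster(
            np.array([[1, 1, 3, 3], [1, 2, 3, 3]], dtype=np.int16),
            suit.grid.fine(),
        )
        return suit, lc

    def test_cell_with_one_preferred_fine_cell_retains_score(self):
        suit, lc = self.grid_pair()
        out = refine_by_habitat(suit, lc, HabitatPreference("spX", frozenset({2})))
        assert out.values[0, 0] == 0.8
        assert out.values[0, 1] == 0.0

    def test_all_classes_preferred_is_identity(self):
        suit, lc = self.grid_pair()
        out = refine_by_habitat(suit, lc, HabitatPreference("spX", frozenset({1, 2, 3})))
        np.testing.assert_array_equal(out.values, suit.values)

    def test_unknown_class_code_is_named_in_error(self):
        suit, lc = self.grid_pair()
        with pytest.raises(ValueError, match=r"\[9\]"):
            refine_by_habitat(suit, lc, HabitatPreference("spX", frozenset({9})))

    def test_never_increases_scores(self):
        rng = np.random.default_rng(3)
        suit = make_suitability(rng.uniform(0, 1, (4, 4)), fine_factor=2)
        lc = make_raster(
            rng.integers(1, 4, (8, 8)).astype(np.int16), suit.grid.fine()
        )
        out = refine_by_habitat(suit, lc, HabitatPreference("spX", frozenset({1})))
        assert (out.values <= suit.values).all()


class TestComputeThreshold:
    def test_decile_example(self):
        scores = np.array([np.arange(0.1, 1.05, 0.1)])
        suit = make_suitability(scores)
        occ = OccupancySet.from_cells("spX", [(c, 0) for c in range(10)])
        t = compute_threshold(suit, occ, percentile=10)
        assert t.tau == pytest.approx(0.19)
        assert t.n_occupied_cells == 10

    def test_constant_scores(self):
        suit = make_suitability([[0.5, 0.5, 0.5]])
        occ = OccupancySet.from_cells("spX", [(0, 0), (1, 0), (2, 0)])
        assert compute_threshold(suit, occ).tau == 0.5

    def test_single_cell(self):
        suit = make_suitability([[0.7]])
        occ = OccupancySet.from_cells("spX", [(0, 0)])
        assert compute_threshold(suit, occ).tau == 0.7

    def test_empty_occupancy_rejected(self):
        suit = make_suitability([[0.7]])
        with pytest.raises(ValueError, match="no occupied cells"):
            compute_threshold(suit, OccupancySet.from_cells("spX", []))

    def test_all_occupied_cells_missing_rejected(self):
        suit = make_suitability([[np.nan, 0.4]])
        occ = OccupancySet.from_cells("spX", [(0, 0)])
        with pytest.raises(ValueError, match="no occupied cells"):
            compute_threshold(suit, occ)

    def test_occupied_cells_outside_grid_rejected(self):
        suit = make_suitability([[0.7]])
        occ = OccupancySet.from_cells("spX", [(5, 0)])
        with pytest.raises(ValueError, match="outside"):
            compute_threshold(suit, occ)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        scores=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=50,
        ),
        p=st.floats(min_value=0.0, max_value=100.0),
    )
    def test_matches_independent_percentile_oracle(self, scores, p):
        suit = make_suitability([scores])
        occ = OccupancySet.from_cells("spX", [(c, 0) for c in range(len(scores))])
        t = compute_threshold(suit, occ, percentile=p)
        assert t.tau == pytest.approx(brute_force_percentile(scores, p), abs=1e-12)


class TestPaMaxSuitability:
    def test_spanning_pa_takes_maximum(self):
        suit = make_suitability([[0.2, 0.9]])
        pa = box(100, 100, 19_000, 9_000)
        assert pa_max_suitability(suit, pa) == 0.9

    def test_subcell_pa_inherits_cell_score(self):
        suit = make_suitability([[0.33, 0.9]])
        pa = box(100, 100, 900, 900)
        assert pa_max_suitability(suit, pa) == 0.33

    def test_all_zero_grid(self):
        suit = make_suitability([[0.0, 0.0]])
        assert pa_max_suitability(suit, box(100, 100, 900, 900)) == 0.0

    def test_outside_domain_raises(self):
        suit = make_suitability([[0.5]])
        with pytest.raises(PAOutsideDomainError, match="outside modelled domain"):
            pa_max_suitability(suit, box(-2e4, -2e4, -1e4, -1e4))

    def test_zero_area_polygon_rejected(self):
        suit = make_suitability([[0.5]])
        with pytest.raises(ValueError, match="positive area"):
            pa_max_suitability(suit, box(10, 10, 10, 10))

    def test_missing_cells_excluded(self):
        suit = make_suitability([[np.nan, 0.4]])
        pa = box(100, 100, 19_000, 9_000)
        assert pa_max_suitability(suit, pa) == 0.4
        only_missing = box(100, 100, 900, 900)
        assert np.isnan(pa_max_suitability(suit, only_missing))

    def test_exceeds_every_intersecting_cell(self):
        rng = np.random.default_rng(11)
        suit = make_suitability(rng.uniform(0, 1, (6, 6)))
        grid = suit.grid
        for _ in range(20):
            x0, y0 = rng.uniform(0, grid.width, 2)
            pa = box(x0, y0, x0 + rng.uniform(100, 3e4), y0 + rng.uniform(100, 3e4))
            pa = pa.intersection(box(*grid.extent))
            if pa.area == 0:
                continue
            m = pa_max_suitability(suit, pa)
            cols, rows = grid.cells_intersecting(pa)
            assert all(m >= suit.values[r, c] for c, r in zip(cols, rows))


class TestBuildTable:
    def make_world(self):
        rng = np.random.default_rng(5)
        grid = GridSpec(n_cols=4, n_rows=3, fine_factor=1)
        grids = {}
        for sid in ("spA", "spB"):
            cur = make_suitability(rng.uniform(0, 1, (3, 4)), species_id=sid)
            fut = make_suitability(
                rng.uniform(0, 1, (3, 4)), species_id=sid, period="future"
            )
            grids[sid] = (cur, fut)
        pas = [
            ProtectedArea("PA0", box(100, 100, 5_000, 5_000)),
            ProtectedArea("PA1", box(12_000, 3_000, 33_000, 8_000)),
            ProtectedArea("PA2", box(1_000, 21_000, 39_000, 29_000)),
        ]
        return grids, pas

    def test_record_count_and_ordering(self):
        grids, pas = self.make_world()
        records = build_pa_suitability_table(grids, pas)
        assert len(records) == 6
        assert [(r.species_id, r.pa_id) for r in records] == sorted(
            (r.species_id, r.pa_id) for r in records
        )

    def test_identical_periods_give_equal_maxima(self):
        grids, pas = self.make_world()
        records = build_pa_suitability_table(
            {
                sid: (cur, make_suitability(cur.values, species_id=sid, period="future"))
                for sid, (cur, _) in grids.items()
            },
            pas,
        )
        for r in records:
            assert r.max_current == r.max_future

    def test_matches_individual_zonal_calls(self):
        grids, pas = self.make_world()
        records = build_pa_suitability_table(grids, pas)
        for r in records:
            cur, fut = grids[r.species_id]
            pa = next(p for p in pas if p.pa_id == r.pa_id)
            assert r.max_current == pa_max_suitability(cur, pa.geometry)
            assert r.max_future == pa_max_suitability(fut, pa.geometry)
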