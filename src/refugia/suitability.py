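"""Habitat refinement, suitability thresholds and zonal PA extraction.

The screening converts a continuous suitability surface into a per-PA
binary judgement in three steps: (1) zero out cells lacking any of the
species' preferred land-cover classes; (2) derive the species' suitability
threshold tau as a low percentile (default 10th) of refined suitability at
its occupied hectads; (3) take the zonal maximum of suitability over every
protected area, for both periods, and compare against tau downstream.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .domain import (
    HabitatPreference,
    OccupancySet,
    PASuitability,
    ProtectedArea,
    SpeciesThreshold,
    SuitabilityGrid,
)
from .grids import GridSpec, Raster

__all__ = [
    "PAOutsideDomainError",
    "refine_by_habitat",
    "compute_threshold",
    "pa_max_suitability",
    "build_pa_suitability_table",
]

log = logging.getLogger(__name__)


class PAOutsideDomainError(ValueError):
    """Raised when a PA polygon intersects no grid-cell footprint."""


def _classes_present(
    landcover: Raster, grid: GridSpec, classes: Iterable[int]
) -> np.ndarray:
    """Boolean coarse-cell mask: does any fine cell carry a listed class?"""
    f = grid.fine_factor
    lc = landcover.values
    if lc.shape != (grid.n_rows * f, grid.n_cols * f):
        raise ValueError("land-cover raster does not match the fine lattice")
    blocks = lc.reshape(grid.n_rows, f, grid.n_cols, f)
    mask = np.zeros(grid.shape, dtype=bool)
    for cls in classes:
        mask |= (blocks == cls).any(axis=(1, 3))
    return mask


def refine_by_habitat(
    suit: SuitabilityGrid, landcover: Raster, pref: HabitatPreference
) -> SuitabilityGrid:
    """Restrict suitability to cells containing preferred habitat.

    A coarse cell keeps its score iff at least one fine land-cover cell
    inside it carries one of the species' preferred classes; otherwise the
    score is set to 0.  Scores are never increased.
    """
    available = set(int(c) for c in np.unique(landcover.values))
    unknown = sorted(set(pref.preferred_classes) - available)
    if unknown:
        raise ValueError(
            f"unknown land-cover class code(s) {unknown} for species "
            f"{pref.species_id!r}"
        )
    mask = _classes_present(landcover, suit.grid, pref.preferred_classes)
    refined = np.where(mask, suit.values, 0.0)
    return suit.copy_with(refined)


def compute_threshold(
    refined_current: SuitabilityGrid,
    occ: OccupancySet,
    percentile: float = 10.0,
) -> SpeciesThreshold:
    """Suitability threshold tau from occupied-cell scores.

    tau is the given percentile (default 10th) of the refined current
    suitability at the species' occupied cells, using linear interpolation
    between closest order statistics (zero-based position ``(n-1)*p/100``).
    Missing-valued occupied cells are excluded.
    """
    if len(occ) == 0:
        raise ValueError(f"no occupied cells for species {occ.species_id!r}")
    grid = refined_current.grid
    cells = np.array(sorted(occ.cells))
    cols, rows = cells[:, 0], cells[:, 1]
    if (cols < 0).any() or (cols >= grid.n_cols).any() or (rows < 0).any() or (
        rows >= grid.n_rows
    ).any():
        raise ValueError("occupied cells lie outside the grid")
    scores = refined_current.values[rows, cols]
    scores = scores[~np.isnan(scores)]
    if scores.size == 0:
        raise ValueError(f"no occupied cells for species {occ.species_id!r}")
    tau = float(np.percentile(scores, percentile, method="linear"))
    return SpeciesThreshold(
        species_id=refined_current.species_id,
        tau=tau,
        n_occupied_cells=int(scores.size),
    )


def pa_max_suitability(suit: SuitabilityGrid, pa_geometry) -> float:
    """Zonal maximum suitability over one PA polygon.

    The maximum is taken over all cells whose half-open footprint has a
    positive-area intersection with the polygon — so a PA far smaller than
    one cell inherits its cell's score.  Returns ``NaN`` when every
    intersecting cell is missing-valued.
    """
    if pa_geometry.area <= 0:
        raise ValueError("PA polygon must have positive area")
    cols, rows = suit.grid.cells_intersecting(pa_geometry)
    if cols.size == 0:
        raise PAOutsideDomainError("PA outside modelled domain")
    vals = suit.values[rows, cols]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.max())


def build_pa_suitability_table(
    grids: Mapping[str, tuple[SuitabilityGrid, SuitabilityGrid]],
    pas: Sequence[ProtectedArea],
) -> list[PASuitability]:
    """Zonal maxima for every (species, PA) pair, both periods.

    ``grids`` maps species_id -> (current, future) refined grids, all on one
    shared :class:`GridSpec`.  Records are ordered by (species_id, pa_id);
    cell intersections are computed once per PA and reused across species.
    """
    if not grids:
        return []
    ref_grid = next(iter(grids.values()))[0].grid
    for pair in grids.values():
        for g in pair:
            if g.grid != ref_grid:
                raise ValueError("all suitability grids must share one GridSpec")

    pa_cells: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pa in pas:
        if pa.geometry.area <= 0:
            raise ValueError(f"PA {pa.pa_id!r}: polygon must have positive area")
        cols, rows = ref_grid.cells_intersecting(pa.geometry)
        if cols.size == 0:
            raise PAOutsideDomainError(f"PA {pa.pa_id!r}: PA outside modelled domain")
        pa_cells[pa.pa_id] = (cols, rows)

    def zonal_max(g: SuitabilityGrid, pa_id: str) -> float:
        cols, rows = pa_cells[pa_id]
        vals = g.values[rows, cols]
        vals = vals[~np.isnan(vals)]
        return float(vals.max()) if vals.size else float("nan")

    records = []
    for sid in sorted(grids):
        current, future = grids[sid]
        for pa in sorted(pas, key=lambda p: p.pa_id):
            records.append(
                PASuitability(
                    pa_id=pa.pa_id,
                    species_id=sid,
                    max_current=zonal_max(current, pa.pa_id),
                    max_future=zonal_max(future, pa.pa_id),
                )
            )
    return records
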