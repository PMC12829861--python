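"""PA-level predictors and the standardized design matrix.

Six predictors per protected area: centroid northing (latitude role),
centroid easting (longitude role), area, mean elevation, elevational range
and the number of distinct land-cover classes.  Mean elevation, elevational
range and area are log-transformed (with +1 offsets so flat, sea-level or
single-cell PAs stay in the analysis) and every column — habitat count
included — is z-scored over the analysed set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domain import ProtectedArea
from .grids import Raster

__all__ = ["PACovariates", "DesignMatrix", "compute_covariates", "build_design_matrix"]

#: Design-matrix column order (matches the count-model report tables).
COLUMNS = (
    "log_mean_elevation",
    "log_elev_range",
    "log_area",
    "northing",
    "easting",
    "habitat_count",
)

#: Additive offsets inside the log transforms (m, m, m^2).
LOG_OFFSETS = {"log_mean_elevation": 1.0, "log_elev_range": 1.0, "log_area": 1.0}


@dataclass(frozen=True)
class PACovariates:
    pa_id: str
    centroid_northing: float
    centroid_easting: float
    area: float
    mean_elevation: float
    elevation_range: float
    habitat_count: int

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"PA {self.pa_id!r}: area must be positive")
        if self.elevation_range < 0:
            raise ValueError(f"PA {self.pa_id!r}: negative elevation range")


@dataclass
class DesignMatrix:
    """Standardized predictors with the scaling retained for back-transform."""

    pa_ids: tuple[str, ...]
    X: np.ndarray  # shape (n_pas, 6), z-scored columns
    columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    offsets: Mapping[str, float]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=list(self.pa_ids), columns=list(self.columns))


def compute_covariates(
    pa: ProtectedArea, elevation: Raster, landcover: Raster
) -> PACovariates:
    """Covariates for one PA from its geometry and the fine grids.

    Elevation statistics and the habitat count are taken over all fine cells
    whose footprint overlaps the polygon with positive area — the same zonal
    rule used for suitability, so sub-cell PAs inherit their cell.
    """
    cols, rows = elevation.grid.cells_intersecting(pa.geometry)
    if cols.size == 0:
        raise ValueError(f"PA {pa.pa_id!r}: no intersecting elevation cells")
    elev = elevation.at_cells(cols, rows)
    elev = elev[~np.isnan(elev)]
    if elev.size == 0:
        raise ValueError(f"PA {pa.pa_id!r}: no intersecting elevation cells")

    if landcover.grid != elevation.grid:
        lc_cols, lc_rows = landcover.grid.cells_intersecting(pa.geometry)
    else:
        lc_cols, lc_rows = cols, rows
    lc = landcover.at_cells(lc_cols, lc_rows)
    lc = lc[~np.isnan(lc)] if np.issubdtype(lc.dtype, np.floating) else lc

    cx, cy = pa.centroid
    return PACovariates(
        pa_id=pa.pa_id,
        centroid_northing=float(cy),
        centroid_easting=float(cx),
        area=float(pa.geometry.area),
        mean_elevation=float(elev.mean()),
        elevation_range=float(elev.max() - elev.min()),
        habitat_count=int(np.unique(lc).size),
    )


def covariates_frame(covs: Sequence[PACovariates]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in covs]).set_index("pa_id")


def build_design_matrix(covs: Sequence[PACovariates]) -> DesignMatrix:
    """Log-transform and z-score the six predictors.

    Raises on fewer than two PAs or on any zero-variance column (named in
    the error), since a degenerate column cannot be standardized.
    """
    if len(covs) < 2:
        raise ValueError("design matrix needs at least two PAs")
    raw = np.column_stack(
        [
            np.log(np.array([c.mean_elevation for c in covs]) + LOG_OFFSETS["log_mean_elevation"]),
            np.log(np.array([c.elevation_range for c in covs]) + LOG_OFFSETS["log_elev_range"]),
            np.log(np.array([c.area for c in covs]) + LOG_OFFSETS["log_area"]),
            np.array([c.centroid_northing for c in covs], dtype=float),
            np.array([c.centroid_easting for c in covs], dtype=float),
            np.array([c.habitat_count for c in covs], dtype=float),
        ]
    )
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    for name, sd in zip(COLUMNS, sds):
        if sd == 0.0:
            raise ValueError(f"zero-variance column: {name}")
    X = (raw - means) / sds
    return DesignMatrix(
        pa_ids=tuple(c.pa_id for c in covs),
        X=X,
        columns=COLUMNS,
        means=means,
        sds=sds,
        offsets=dict(LOG_OFFSETS),
    )
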