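"""Core domain types shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable

import numpy as np
from shapely.geometry.base import BaseGeometry

from .grids import GridSpec

__all__ = [
    "SuitabilityGrid",
    "OccupancySet",
    "ProtectedArea",
    "HabitatPreference",
    "SpeciesThreshold",
    "PASuitability",
]

PERIODS = ("current", "future")


@dataclass
class SuitabilityGrid:
    """One species x one period surface of habitat-suitability scores.

    Scores range from 0 (unsuitable) to 1 (highly suitable); ``NaN`` marks
    cells with no modelled value.
    """

    species_id: str
    period: str
    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValueError(f"period must be one of {PERIODS}, got {self.period!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("suitability values do not match grid shape")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("suitability scores must lie in [0, 1]")

    def copy_with(self, values: np.ndarray) -> "SuitabilityGrid":
        return SuitabilityGrid(self.species_id, self.period, self.grid, values)


@dataclass(frozen=True)
class OccupancySet:
    """Grid cells (hectads) where a species was recorded in the baseline
    period, stored as ``(col, row)`` pairs."""

    species_id: str
    cells: FrozenSet[tuple[int, int]]

    @classmethod
    def from_cells(cls, species_id: str, cells: Iterable[tuple[int, int]]) -> "OccupancySet":
        return cls(species_id, frozenset((int(c), int(r)) for c, r in cells))

    def __len__(self) -> int:
        return len(self.cells)

    def to_mask(self, grid: GridSpec) -> np.ndarray:
        mask = np.zeros(grid.shape, dtype=bool)
        for col, row in self.cells:
            if 0 <= col < grid.n_cols and 0 <= row < grid.n_rows:
                mask[row, col] = True
        return mask


@dataclass(frozen=True)
class ProtectedArea:
    """An identified protected-area polygon (NNR / SSSI analogue)."""

    pa_id: str
    geometry: BaseGeometry

    @property
    def area(self) -> float:
        return self.geometry.area

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.geometry.centroid
        return (c.x, c.y)


@dataclass(frozen=True)
class HabitatPreference:
    """Land-cover classes a species can occupy (broad habitat types)."""

    species_id: str
    preferred_classes: FrozenSet[int]

    def __post_init__(self) -> None:
        if not self.preferred_classes:
            raise ValueError("preferred_classes must be non-empty")


@dataclass(frozen=True)
class SpeciesThreshold:
    """Suitability threshold tau: an occupied-site percentile of scores."""

    species_id: str
    tau: float
    n_occupied_cells: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError("tau must lie in [0, 1]")
        if self.n_occupied_cells < 1:
            raise ValueError("threshold requires at least one occupied cell")


@dataclass(frozen=True)
class PASuitability:
    """Zonal maximum suitability of one PA for one species, both periods."""

    pa_id: str
    species_id: str
    max_current: float
    max_future: float
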