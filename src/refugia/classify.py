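"""Refugia classification and summary tables.

Each (species, PA) pair falls into one of four categories:

* ``at_risk``   — the species is currently found in the PA but the PA's
  future suitability drops below the species' threshold tau;
* ``in_situ``   — currently found and projected to remain suitable;
* ``ex_situ``   — not currently found, but suitable in both periods: a
  candidate receptor site for assisted colonisation;
* ``none``      — everything else.

Occupancy overrides modelled current suitability for occupied PAs: presence
is itself evidence the site is currently suitable, so occupied PAs split
purely on future suitability and ``occupied = at_risk + in_situ`` holds
exactly per species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .domain import OccupancySet, PASuitability, ProtectedArea, SpeciesThreshold
from .grids import GridSpec

__all__ = [
    "RefugiaStatus",
    "SpeciesSummaryRow",
    "SummaryTable",
    "mark_occupied",
    "classify_pa",
    "classify_all",
    "summarize_species",
    "summarize_table",
    "count_species_per_pa",
]

log = logging.getLogger(__name__)

STATUSES = ("at_risk", "in_situ", "ex_situ", "none")


@dataclass(frozen=True)
class RefugiaStatus:
    pa_id: str
    species_id: str
    occupied: bool
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status in ("at_risk", "in_situ") and not self.occupied:
            raise ValueError(f"{self.status} implies an occupied PA")
        if self.status == "ex_situ" and self.occupied:
            raise ValueError("ex_situ implies an unoccupied PA")


@dataclass(frozen=True)
class SpeciesSummaryRow:
    """One species' PA counts, mirroring the columns of a per-species
    occupied / at-risk / in situ / ex situ summary table."""

    species_id: str
    n_occupied: int
    n_at_risk: int
    n_in_situ: int
    n_ex_situ: int
    pct_at_risk: float | None  # 1 dp; None when no PA is occupied


@dataclass(frozen=True)
class SummaryTable:
    rows: tuple[SpeciesSummaryRow, ...]
    averages: Mapping[str, float]  # per-column means, 1 dp
    pct_ex_situ_of_refugia: int  # share of refugia that are ex situ, %
    pooled_retention_pct: int  # 100 * total in situ / total occupied, %
    mean_retention_pct: float  # mean of per-species retention %, 1 dp

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([r.__dict__ for r in self.rows])
        avg = {"species_id": "Average", **self.averages}
        return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def mark_occupied(pa_geometry, occ: OccupancySet, grid: GridSpec) -> bool:
    """True iff the PA polygon overlaps (positive area) an occupied cell."""
    cols, rows = grid.cells_intersecting(pa_geometry)
    return any((int(c), int(r)) in occ.cells for c, r in zip(cols, rows))


def classify_pa(
    rec: PASuitability, occupied: bool, threshold: SpeciesThreshold
) -> RefugiaStatus:
    """Classify one (species, PA) pair against the species' threshold."""
    if rec.species_id != threshold.species_id:
        raise ValueError(
            f"species mismatch: record {rec.species_id!r} vs threshold "
            f"{threshold.species_id!r}"
        )
    tau = threshold.tau
    if occupied:
        if math.isnan(rec.max_future):
            raise ValueError(f"PA {rec.pa_id!r}: missing future suitability")
        status = "in_situ" if rec.max_future >= tau else "at_risk"
    else:
        if math.isnan(rec.max_current) or math.isnan(rec.max_future):
            raise ValueError(f"PA {rec.pa_id!r}: missing suitability")
        if rec.max_current >= tau and rec.max_future >= tau:
            status = "ex_situ"
        else:
            status = "none"
    return RefugiaStatus(rec.pa_id, rec.species_id, occupied, status)


def classify_all(
    records: Sequence[PASuitability],
    occupancy: Mapping[str, OccupancySet],
    thresholds: Mapping[str, SpeciesThreshold],
    pas: Sequence[ProtectedArea],
    grid: GridSpec,
) -> list[RefugiaStatus]:
    """Classify every (species, PA) record; PA-occupancy overlays are
    computed once per species.  Records whose suitability is entirely
    missing are excluded (logged), per the zonal missing-value policy."""
    pa_cells = {
        pa.pa_id: set(
            zip(*(arr.tolist() for arr in grid.cells_intersecting(pa.geometry)))
        )
        for pa in pas
    }
    occupied_pa: dict[tuple[str, str], bool] = {}
    for sid, occ in occupancy.items():
        for pa in pas:
            occupied_pa[(sid, pa.pa_id)] = bool(pa_cells[pa.pa_id] & occ.cells)

    statuses = []
    for rec in records:
        occ_flag = occupied_pa.get((rec.species_id, rec.pa_id), False)
        needs = (rec.max_future,) if occ_flag else (rec.max_current, rec.max_future)
        if any(math.isnan(v) for v in needs):
            log.info(
                "excluding PA %s / species %s: missing suitability",
                rec.pa_id,
                rec.species_id,
            )
            continue
        statuses.append(classify_pa(rec, occ_flag, thresholds[rec.species_id]))
    return statuses


def _round1(x: float) -> float:
    return float(round(x, 1))


def summarize_species(statuses: Iterable[RefugiaStatus]) -> SpeciesSummaryRow:
    """Counts by status for one species, with % at risk to 1 dp."""
    statuses = list(statuses)
    species = {s.species_id for s in statuses}
    if len(species) > 1:
        raise ValueError(f"statuses span multiple species: {sorted(species)}")
    species_id = species.pop() if species else ""
    n_at_risk = sum(s.status == "at_risk" for s in statuses)
    n_in_situ = sum(s.status == "in_situ" for s in statuses)
    n_ex_situ = sum(s.status == "ex_situ" for s in statuses)
    n_occupied = n_at_risk + n_in_situ
    pct = _round1(100.0 * n_at_risk / n_occupied) if n_occupied > 0 else None
    return SpeciesSummaryRow(
        species_id=species_id,
        n_occupied=n_occupied,
        n_at_risk=n_at_risk,
        n_in_situ=n_in_situ,
        n_ex_situ=n_ex_situ,
        pct_at_risk=pct,
    )


def summarize_table(rows: Sequence[SpeciesSummaryRow]) -> SummaryTable:
    """Aggregate per-species rows into the summary table.

    Column averages (1 dp) use *unrounded* per-species percentages.  The ex
    situ share of refugia and the pooled retention (100 * total in situ /
    total occupied) are reported to the nearest integer, the mean per-species
    retention to 1 dp.
    """
    if not rows:
        raise ValueError("summarize_table needs at least one row")
    occ = np.array([r.n_occupied for r in rows], dtype=float)
    risk = np.array([r.n_at_risk for r in rows], dtype=float)
    insitu = np.array([r.n_in_situ for r in rows], dtype=float)
    exsitu = np.array([r.n_ex_situ for r in rows], dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        pct_risk = np.where(occ > 0, 100.0 * risk / occ, np.nan)
        pct_keep = np.where(occ > 0, 100.0 * insitu / occ, np.nan)

    averages = {
        "n_occupied": _round1(occ.mean()),
        "n_at_risk": _round1(risk.mean()),
        "pct_at_risk": _round1(float(np.nanmean(pct_risk))),
        "n_in_situ": _round1(insitu.mean()),
        "n_ex_situ": _round1(exsitu.mean()),
    }
    refugia_total = insitu.sum() + exsitu.sum()
    pct_ex = (
        int(round(100.0 * exsitu.sum() / refugia_total)) if refugia_total > 0 else 0
    )
    pooled = int(round(100.0 * insitu.sum() / occ.sum())) if occ.sum() > 0 else 0
    mean_keep = _round1(float(np.nanmean(pct_keep)))
    return SummaryTable(
        rows=tuple(rows),
        averages=averages,
        pct_ex_situ_of_refugia=pct_ex,
        pooled_retention_pct=pooled,
        mean_retention_pct=mean_keep,
    )


def count_species_per_pa(
    statuses: Iterable[RefugiaStatus],
    mode: str,
    pa_ids: Sequence[str],
) -> pd.Series:
    """Number of distinct species with the given status per PA.

    ``mode`` is ``"in_situ"`` or ``"ex_situ"``.  Every PA in ``pa_ids``
    appears in the result — zeros matter for the count regression.
    """
    if mode not in ("in_situ", "ex_situ"):
        raise ValueError("mode must be 'in_situ' or 'ex_situ'")
    counts = pd.Series(0, index=pd.Index(pa_ids, name="pa_id"), dtype=int)
    seen: set[tuple[str, str]] = set()
    for s in statuses:
        if s.status == mode and (s.pa_id, s.species_id) not in seen:
            seen.add((s.pa_id, s.species_id))
            if s.pa_id in counts.index:
                counts[s.pa_id] += 1
    counts.name = f"n_species_{mode}"
    return counts
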