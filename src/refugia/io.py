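"""File formats for pipeline inputs and intermediates.

Grids travel as ESRI ASCII (.asc), polygons as GeoJSON, tables as CSV with
self-describing headers, configuration as YAML.  All formats are plain text
so a full run can be archived and diffed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .domain import HabitatPreference, OccupancySet, PASuitability, ProtectedArea
from .grids import read_ascii_grid, write_ascii_grid  # re-exported for convenience
from .synthetic import ScenarioConfig

__all__ = [
    "read_ascii_grid",
    "write_ascii_grid",
    "write_pas_geojson",
    "read_pas_geojson",
    "write_occupancy_csv",
    "read_occupancy_csv",
    "write_habitat_prefs_csv",
    "read_habitat_prefs_csv",
    "write_pa_suitability_csv",
    "read_pa_suitability_csv",
    "write_scenario_yaml",
    "read_scenario_yaml",
]


def write_pas_geojson(pas: Sequence[ProtectedArea], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"pa_id": pa.pa_id},
            "geometry": mapping(pa.geometry),
        }
        for pa in pas
    ]
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload))


def read_pas_geojson(path: str | Path) -> list[ProtectedArea]:
    payload = json.loads(Path(path).read_text())
    return [
        ProtectedArea(
            pa_id=str(f["properties"]["pa_id"]), geometry=shape(f["geometry"])
        )
        for f in payload["features"]
    ]


def write_occupancy_csv(occs: Sequence[OccupancySet], path: str | Path) -> None:
    rows = [
        {"species_id": occ.species_id, "cell_col": col, "cell_row": row}
        for occ in occs
        for col, row in sorted(occ.cells)
    ]
    pd.DataFrame(rows, columns=["species_id", "cell_col", "cell_row"]).to_csv(
        path, index=False
    )


def read_occupancy_csv(path: str | Path) -> dict[str, OccupancySet]:
    df = pd.read_csv(path)
    out = {}
    for sid, grp in df.groupby("species_id"):
        out[str(sid)] = OccupancySet.from_cells(
            str(sid), zip(grp["cell_col"], grp["cell_row"])
        )
    return out


def write_habitat_prefs_csv(prefs: Sequence[HabitatPreference], path: str | Path) -> None:
    rows = [
        {"species_id": p.species_id, "class_code": code}
        for p in prefs
        for code in sorted(p.preferred_classes)
    ]
    pd.DataFrame(rows, columns=["species_id", "class_code"]).to_csv(path, index=False)


def read_habitat_prefs_csv(path: str | Path) -> dict[str, HabitatPreference]:
    df = pd.read_csv(path)
    return {
        str(sid): HabitatPreference(
            str(sid), frozenset(int(c) for c in grp["class_code"])
        )
        for sid, grp in df.groupby("species_id")
    }


def write_pa_suitability_csv(
    records: Sequence[PASuitability],
    taus: dict[str, float],
    path: str | Path,
) -> None:
    df = pd.DataFrame(
        [
            {
                "pa_id": r.pa_id,
                "species_id": r.species_id,
                "max_current": r.max_current,
                "max_future": r.max_future,
                "tau": taus[r.species_id],
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)


def read_pa_suitability_csv(path: str | Path) -> tuple[list[PASuitability], dict[str, float]]:
    df = pd.read_csv(path)
    records = [
        PASuitability(
            pa_id=str(r.pa_id),
            species_id=str(r.species_id),
            max_current=float(r.max_current),
            max_future=float(r.max_future),
        )
        for r in df.itertuples()
    ]
    taus = {str(s): float(t) for s, t in df.groupby("species_id")["tau"].first().items()}
    return records, taus


def write_scenario_yaml(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))


def read_scenario_yaml(path: str | Path) -> ScenarioConfig:
    data = yaml.safe_load(Path(path).read_text())
    for key in ("species_northing_band", "preferred_elevation_range", "true_beta"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return ScenarioConfig(**data)
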