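"""End-to-end orchestration: simulate/load -> refine -> threshold -> zonal
extraction -> classify -> summarize -> covariates -> two count-model fits ->
report.

Every intermediate is written in a plain-text format, and the run manifest
records the configuration hash, derived seeds, per-stage row counts and
timings, so a run is a pure, reproducible function of (inputs, config).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .classify import classify_all, count_species_per_pa, summarize_species, summarize_table
from .covariates import build_design_matrix, compute_covariates, covariates_frame
from .glmm import SpatialGLMMConfig, SpatialPoissonGLMM
from .grids import GridSpec, Raster
from .report import render_report
from .suitability import build_pa_suitability_table, compute_threshold, refine_by_habitat
from .synthetic import (
    ScenarioConfig,
    generate_environment,
    generate_habitat_preferences,
    generate_occupancy,
    generate_pas,
    generate_species_surfaces,
    species_label,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: a synthetic scenario XOR real-data paths.

    ``data_paths`` must provide: ``elevation``, ``landcover`` (.asc),
    ``suitability_dir`` (files ``<species>_current.asc`` /
    ``<species>_future.asc``), ``occupancy`` (CSV), ``pas`` (GeoJSON),
    ``habitat_prefs`` (CSV) and ``fine_factor``.
    """

    outdir: str | Path
    scenario: ScenarioConfig | None = None
    grid: GridSpec | None = None
    data_paths: dict | None = None
    percentile: float = 10.0
    glmm: SpatialGLMMConfig = field(default_factory=SpatialGLMMConfig)
    make_plots: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.data_paths is None):
            raise ValueError(
                "provide exactly one of a synthetic scenario or real-data paths"
            )
        if self.scenario is not None and self.grid is None:
            self.grid = GridSpec()

    def config_hash(self) -> str:
        blob = {
            "scenario": dataclasses.asdict(self.scenario) if self.scenario else None,
            "grid": dataclasses.asdict(self.grid) if self.grid else None,
            "data_paths": {k: str(v) for k, v in (self.data_paths or {}).items()} or None,
            "percentile": self.percentile,
            "glmm": dataclasses.asdict(self.glmm),
        }
        return hashlib.sha256(
            yaml.safe_dump(blob, sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    """Stage 1: simulate the synthetic study system or load real data."""
    if config.scenario is not None:
        sc, grid = config.scenario, config.grid
        elevation, landcover = generate_environment(grid, sc)
        surfaces = {}
        for i in range(sc.n_species):
            cur, fut = generate_species_surfaces(grid, sc, i, elevation=elevation)
            surfaces[species_label(i)] = (cur, fut)
        pas = generate_pas(grid, sc)
        prefs = {p.species_id: p for p in generate_habitat_preferences(sc)}
        return grid, elevation, landcover, surfaces, None, pas, prefs

    paths = config.data_paths
    fine_factor = int(paths.get("fine_factor", 10))
    elevation = rio.read_ascii_grid(paths["elevation"])
    landcover = rio.read_ascii_grid(paths["landcover"])
    suit_dir = Path(paths["suitability_dir"])
    surfaces = {}
    species = sorted(p.name[: -len("_current.asc")] for p in suit_dir.glob("*_current.asc"))
    if not species:
        raise FileNotFoundError(f"no *_current.asc grids in {suit_dir}")
    from .domain import SuitabilityGrid

    for sid in species:
        fut_path = suit_dir / f"{sid}_future.asc"
        if not fut_path.exists():
            raise FileNotFoundError(f"missing future grid for species {sid!r}")
        cur = rio.read_ascii_grid(suit_dir / f"{sid}_current.asc", fine_factor)
        fut = rio.read_ascii_grid(fut_path, fine_factor)
        surfaces[sid] = (
            SuitabilityGrid(sid, "current", cur.grid, cur.values),
            SuitabilityGrid(sid, "future", fut.grid, fut.values),
        )
    grid = surfaces[species[0]][0].grid
    occupancy = rio.read_occupancy_csv(paths["occupancy"])
    pas = rio.read_pas_geojson(paths["pas"])
    prefs = rio.read_habitat_prefs_csv(paths["habitat_prefs"])
    return grid, elevation, landcover, surfaces, occupancy, pas, prefs


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full screening and regression; returns the run manifest."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "stages": {},
        "row_counts": {},
    }
    timings = manifest["stages"]

    def stage(name):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    log.error("stage %s failed: %s", name, exc)
                return False

        return _T()

    with stage("inputs"):
        grid, elevation, landcover, surfaces, occupancy, pas, prefs = _load_inputs(config)
        if config.scenario is not None:
            rio.write_ascii_grid(elevation, outdir / "elevation.asc")
            rio.write_ascii_grid(landcover, outdir / "landcover.asc", fmt="%d")
            rio.write_pas_geojson(pas, outdir / "pas.geojson")
            rio.write_habitat_prefs_csv(list(prefs.values()), outdir / "habitat_prefs.csv")
            rio.write_scenario_yaml(config.scenario, outdir / "scenario.yaml")

    with stage("refine"):
        refined = {}
        for sid, (cur, fut) in sorted(surfaces.items()):
            if sid not in prefs:
                raise KeyError(f"no habitat preference for species {sid!r}")
            refined[sid] = (
                refine_by_habitat(cur, landcover, prefs[sid]),
                refine_by_habitat(fut, landcover, prefs[sid]),
            )
            rio.write_ascii_grid(
                Raster(refined[sid][0].values, grid), outdir / f"{sid}_current.asc"
            )
            rio.write_ascii_grid(
                Raster(refined[sid][1].values, grid), outdir / f"{sid}_future.asc"
            )

    with stage("occupancy"):
        if occupancy is None:  # synthetic mode: record where suitable
            occupancy = {
                sid: generate_occupancy(refined[sid][0], config.scenario)
                for sid in sorted(refined)
            }
        rio.write_occupancy_csv(
            [occupancy[s] for s in sorted(occupancy)], outdir / "occupancy.csv"
        )

    with stage("threshold"):
        thresholds = {}
        for sid in sorted(refined):
            if sid not in occupancy or len(occupancy[sid]) == 0:
                raise ValueError(f"no occupied cells for species {sid!r}")
            thresholds[sid] = compute_threshold(
                refined[sid][0], occupancy[sid], percentile=config.percentile
            )

    with stage("zonal"):
        records = build_pa_suitability_table(refined, pas)
        rio.write_pa_suitability_csv(
            records,
            {s: t.tau for s, t in thresholds.items()},
            outdir / "pa_suitability.csv",
        )
        manifest["row_counts"]["pa_suitability"] = len(records)

    with stage("classify"):
        statuses = classify_all(records, occupancy, thresholds, pas, grid)
        pd.DataFrame([s.__dict__ for s in statuses]).to_csv(
            outdir / "statuses.csv", index=False
        )
        manifest["row_counts"]["statuses"] = len(statuses)
        by_species = {}
        for s in statuses:
            by_species.setdefault(s.species_id, []).append(s)
        rows = [summarize_species(by_species.get(sid, [])) for sid in sorted(refined)]
        rows = [dataclasses.replace(r, species_id=sid) for r, sid in zip(rows, sorted(refined))]
        table = summarize_table(rows)
        table.to_dataframe().to_csv(outdir / "summary.csv", index=False)

    with stage("counts"):
        pa_ids = [pa.pa_id for pa in pas]
        counts = {
            mode: count_species_per_pa(statuses, mode, pa_ids)
            for mode in ("in_situ", "ex_situ")
        }
        pd.DataFrame(counts).to_csv(outdir / "species_per_pa.csv")

    with stage("covariates"):
        covs = [compute_covariates(pa, elevation, landcover) for pa in pas]
        covariates_frame(covs).to_csv(outdir / "covariates.csv")
        design = build_design_matrix(covs)
        design.to_dataframe().to_csv(outdir / "design_matrix.csv", index_label="pa_id")
        scaling = {
            "columns": list(design.columns),
            "means": [float(m) for m in design.means],
            "sds": [float(s) for s in design.sds],
            "offsets": dict(design.offsets),
        }
        (outdir / "design_scaling.yaml").write_text(yaml.safe_dump(scaling))
        coords = np.array([[c.centroid_easting, c.centroid_northing] for c in covs])

    results = {}
    for mode in ("in_situ", "ex_situ"):
        with stage(f"fit_{mode}"):
            y = counts[mode].loc[list(design.pa_ids)].to_numpy()
            if y.sum() == 0:
                log.warning("no %s refugia: model not fitted", mode)
                results[mode] = None
                continue
            mode_key = {"in_situ": 11, "ex_situ": 12}[mode]
            seed = int(
                np.random.SeedSequence(
                    entropy=config.glmm.seed, spawn_key=(mode_key,)
                ).generate_state(1)[0]
                % 2**31
            )
            cfg = dataclasses.replace(config.glmm, seed=seed)
            model = SpatialPoissonGLMM(y, design, coords, config=cfg)
            res = model.fit()
            results[mode] = res
            res.summary().to_csv(outdir / f"glmm_{mode}.csv")
            manifest["row_counts"][f"fit_{mode}"] = int(y.sum())

    with stage("report"):
        text = render_report(table, results, make_plots=config.make_plots, outdir=outdir)
        (outdir / "report.txt").write_text(text)

    manifest["n_species"] = len(refined)
    manifest["n_pas"] = len(pas)
    manifest["outputs"] = sorted(p.name for p in outdir.iterdir())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
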