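"""Synthetic study-system generator.

Builds a self-contained planar landscape with the statistical structure the
refugia screening assumes: smooth species-suitability fields that shift
poleward and upslope between the baseline and future periods, hectad
occupancy concentrated where current suitability is high, strongly
right-skewed protected-area sizes (most PAs far smaller than one 10 km cell),
a smooth elevation surface rising northward, and a patchy categorical
land-cover map.  Every generator is a pure function of (grid, config, seed).

The defaults emulate the British setting the analysis was designed for: a
600 km x 600 km domain of 10 km recording cells, a DEM on a 10-fold finer
lattice, a dozen narrowly distributed focal species, and a poleward/upward
displacement of each species' climatic optimum by 2080.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from scipy.special import expit
from shapely.geometry import box

from .domain import HabitatPreference, OccupancySet, ProtectedArea, SuitabilityGrid
from .grids import GridSpec, Raster

__all__ = [
    "ScenarioConfig",
    "generate_environment",
    "generate_species_surfaces",
    "generate_occupancy",
    "generate_pas",
    "generate_habitat_preferences",
    "species_label",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic scenario.

    Parameters
    ----------
    warming_shift : float
        Poleward displacement (m) of each species' climatic optimum between
        the baseline and future periods.  Default 100 km, the order of the
        range shifts projected for British plants by 2080.
    elevation_shift : float
        Upslope displacement (m) of the preferred elevation over the same
        horizon; default 350 m over ~9 decades, the upper range of observed
        upslope movement of European plants (roughly 25-35 m per decade).
    elevation_lapse : float
        Suitability-elevation coupling: the logit of suitability falls by
        ``elevation_lapse * d^2`` where ``d`` (m) is the distance from the
        species' preferred elevation to the cell's elevation span.  The
        default corresponds to a ~100 m elevational tolerance.
    occupancy_rate : float
        Probability that a climatically suitable cell was actually recorded
        occupied; hectad recording of rare plants is incomplete.
    pa_area_log_mean, pa_area_log_sd : float
        Log-normal PA-size parameters (m^2).  Defaults give a median of
        1 km^2 with a heavy right tail: most PAs are well below one hectad,
        a few span several, mirroring the skew of the British estate.
    pa_quality_coupling : float
        Correlation between a reserve's log-area z-score and the site's
        multi-species climatic quality — designation bias: reserves exist
        *because* of their biological interest, and the largest ones sit on
        the best sites.  Zero decouples size from quality.
    true_beta : tuple
        Ground-truth coefficients (intercept + 6 predictors) used by the
        forward count-model simulator in parameter-recovery scenarios.
    """

    seed: int = 0
    n_species: int = 12
    warming_shift: float = 100_000.0
    elevation_shift: float = 350.0
    elevation_lapse: float = 5.0e-5
    range_scale: float = 150_000.0
    peak_logit: float = 2.5
    occupancy_rate: float = 0.35
    occupancy_cut: float = 0.5
    n_pas: int = 4000
    pa_area_log_mean: float = math.log(1e6)
    pa_area_log_sd: float = 1.8
    pa_quality_coupling: float = 0.5
    n_landcover_classes: int = 20
    landcover_nuclei_per_class: int = 720
    min_preferred_classes: int = 1
    max_preferred_classes: int = 1
    grf_amplitude: float = 350.0
    grf_bandwidth: float = 18_000.0
    grf_amplitude_fine: float = 350.0
    grf_bandwidth_fine: float = 4_000.0
    elevation_ramp: float = 1.0e-3
    species_northing_band: tuple[float, float] = (0.10, 0.65)
    preferred_elevation_range: tuple[float, float] = (100.0, 700.0)
    true_beta: tuple[float, ...] = (0.5, 0.3, 0.4, 0.25, 0.15, 0.1, -0.1)

    def __post_init__(self) -> None:
        if not (0.0 < self.occupancy_rate <= 1.0):
            raise ValueError("occupancy_rate must lie in (0, 1]")
        if self.n_pas < 1:
            raise ValueError("n_pas must be >= 1")
        if self.warming_shift < 0:
            raise ValueError("warming_shift must be >= 0")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_landcover_classes < 1:
            raise ValueError("need at least one land-cover class")
        if not (-1.0 <= self.pa_quality_coupling <= 1.0):
            raise ValueError("pa_quality_coupling must lie in [-1, 1]")


# Stage keys keep every generator on an independent, reproducible stream.
_STAGES = {"environment": 1, "species": 2, "occupancy": 3, "pas": 4, "habitat": 5}


def _rng(seed: int, stage: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES[stage], *extra))
    )


def species_label(index: int) -> str:
    return f"sp{index:02d}"


def _elevation_field(grid: GridSpec, config: ScenarioConfig) -> np.ndarray:
    """The elevation surface on the fine lattice (own seeded stream)."""
    rng = _rng(config.seed, "environment", 0)
    fine = grid.fine()
    _, ys = fine.cell_centers()
    yy = np.repeat(ys[:, None], fine.n_cols, axis=1)
    ramp = config.elevation_ramp * (yy - fine.origin_y)

    def grf(amplitude: float, bandwidth_m: float) -> np.ndarray:
        # smoothed seeded white noise; bandwidth is in metres so the field
        # is invariant to the fine subdivision. The stream advances even at
        # zero amplitude so toggling one component never reseeds the other.
        noise = rng.standard_normal(fine.shape)
        if amplitude <= 0:
            return np.zeros(fine.shape)
        smooth = gaussian_filter(
            noise, sigma=bandwidth_m / fine.cell_size, mode="reflect"
        )
        sd = smooth.std()
        return smooth / sd * amplitude if sd > 0 else smooth

    # broad component: hill massifs spanning a few coarse cells; fine
    # component: local relief whose amplitude is modulated by an
    # independent broad "ruggedness" field, so some districts are rugged
    # and others flat at any base elevation
    base = ramp + grf(config.grf_amplitude, config.grf_bandwidth)
    rough = grf(1.0, config.grf_bandwidth)
    span = rough.max() - rough.min()
    r01 = (rough - rough.min()) / span if span > 0 else np.zeros_like(rough)
    relief = (0.1 + 1.8 * r01) * grf(
        config.grf_amplitude_fine, config.grf_bandwidth_fine
    )
    return np.clip(base + relief, 0.0, None)


def generate_environment(
    grid: GridSpec, config: ScenarioConfig
) -> tuple[Raster, Raster]:
    """Elevation (m) and land-cover class rasters on the fine lattice.

    Elevation is a northward ramp plus a low-frequency Gaussian random field
    (seeded white noise smoothed with a Gaussian kernel), clipped at sea
    level.  Land cover assigns each fine cell the class of its nearest
    randomly seeded class nucleus, giving contiguous patches.
    """
    rng = _rng(config.seed, "environment", 1)
    fine = grid.fine()
    xs, ys = fine.cell_centers()
    yy = np.repeat(ys[:, None], fine.n_cols, axis=1)
    elevation = _elevation_field(grid, config)

    k = config.n_landcover_classes
    n_nuclei = max(k, k * config.landcover_nuclei_per_class)
    nuclei = np.column_stack(
        [
            rng.uniform(fine.origin_x, fine.origin_x + fine.width, n_nuclei),
            rng.uniform(fine.origin_y, fine.origin_y + fine.height, n_nuclei),
        ]
    )
    labels = 1 + (np.arange(n_nuclei) % k)
    xx = np.tile(xs, fine.n_rows)
    pts = np.column_stack([xx, yy.ravel()])
    _, nearest = cKDTree(nuclei).query(pts)
    landcover = labels[nearest].reshape(fine.shape).astype(np.int16)

    return Raster(elevation, fine), Raster(landcover, fine)


def _coarse_elevation_span(elevation: Raster, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-coarse-cell (min, max) of the fine elevation values inside it."""
    f = grid.fine_factor
    vals = elevation.values
    if vals.shape != (grid.n_rows * f, grid.n_cols * f):
        raise ValueError("elevation raster does not match the fine lattice")
    blocks = vals.reshape(grid.n_rows, f, grid.n_cols, f)
    return blocks.min(axis=(1, 3)), blocks.max(axis=(1, 3))


def _species_optimum(
    grid: GridSpec, config: ScenarioConfig, species_index: int
) -> tuple[float, float, float]:
    """Baseline climatic optimum (easting, northing, preferred elevation)."""
    rng = _rng(config.seed, "species", species_index)
    minx, miny, maxx, maxy = grid.extent
    lo, hi = config.species_northing_band
    opt_x = float(rng.uniform(minx, maxx))
    opt_y = float(rng.uniform(miny + lo * grid.height, miny + hi * grid.height))
    e_lo, e_hi = config.preferred_elevation_range
    opt_e = float(rng.uniform(e_lo, e_hi))
    return opt_x, opt_y, opt_e


def generate_species_surfaces(
    grid: GridSpec,
    config: ScenarioConfig,
    species_index: int,
    elevation: Raster | None = None,
) -> tuple[SuitabilityGrid, SuitabilityGrid]:
    """Current and future suitability surfaces for one species.

    Suitability is the inverse logit of a quadratic penalty on the distance
    to a species-specific climatic optimum — a location in planar space plus
    a preferred elevation.  The elevational penalty uses the distance from
    the preferred elevation to the cell's [min, max] span of fine-lattice
    elevations, so topographically diverse cells buffer a wider band of
    species (microclimate buffering).  The future surface is identical except
    the optimum is displaced poleward by ``warming_shift`` and upward by
    ``elevation_shift``.
    """
    if species_index >= config.n_species:
        raise ValueError("species_index out of range")
    if elevation is None:
        elevation, _ = generate_environment(grid, config)
    emin, emax = _coarse_elevation_span(elevation, grid)

    opt_x, opt_y, opt_e = _species_optimum(grid, config, species_index)
    xs, ys = grid.cell_centers()
    xx, yy = np.meshgrid(xs, ys)

    def surface(oy: float, oe: float) -> np.ndarray:
        d2_xy = (xx - opt_x) ** 2 + (yy - oy) ** 2
        d_e = np.maximum(emin - oe, 0.0) + np.maximum(oe - emax, 0.0)
        logit = (
            config.peak_logit
            - d2_xy / config.range_scale**2
            - config.elevation_lapse * d_e**2
        )
        return expit(logit)

    sid = species_label(species_index)
    current = SuitabilityGrid(sid, "current", grid, surface(opt_y, opt_e))
    future = SuitabilityGrid(
        sid,
        "future",
        grid,
        surface(opt_y + config.warming_shift, opt_e + config.elevation_shift),
    )
    return current, future


def _species_stream(species_id: str) -> int:
    digest = hashlib.sha256(species_id.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def generate_occupancy(current: SuitabilityGrid, config: ScenarioConfig) -> OccupancySet:
    """Baseline occupancy: suitable cells recorded with ``occupancy_rate``.

    Each cell whose current suitability exceeds ``occupancy_cut`` is included
    independently with probability ``occupancy_rate``.  The result may be
    empty; the thresholding stage rejects empty sets.
    """
    rng = _rng(config.seed, "occupancy", _species_stream(current.species_id))
    vals = current.values
    candidate = ~np.isnan(vals) & (vals > config.occupancy_cut)
    draw = rng.uniform(size=vals.shape) < config.occupancy_rate
    rows, cols = np.nonzero(candidate & draw)
    return OccupancySet.from_cells(current.species_id, zip(cols, rows))


def _site_quality(
    grid: GridSpec, config: ScenarioConfig, cx: np.ndarray, cy: np.ndarray
) -> np.ndarray:
    """Standardised multi-species climatic quality of candidate PA sites.

    Each coarse cell is scored by the habitat-refined current-plus-future
    suitability summed over species, and the score is then *locally centred*
    (its ~50 km Gaussian smooth is subtracted) so that it measures how much
    better a cell is than its district, not which district it is in.  The
    z-scored cell value at each site is returned.  Coupling reserve size to
    this local quality encodes designation bias: within any district, the
    larger reserves were drawn over the locally best ground.
    """
    elevation, landcover = generate_environment(grid, config)
    emin, emax = _coarse_elevation_span(elevation, grid)
    prefs = generate_habitat_preferences(config)

    f = grid.fine_factor
    lc = landcover.values.reshape(grid.n_rows, f, grid.n_cols, f)
    xs, ys = grid.cell_centers()
    xx, yy = np.meshgrid(xs, ys)

    quality = np.zeros(grid.shape)
    for i in range(config.n_species):
        opt_x, opt_y, opt_e = _species_optimum(grid, config, i)
        present = np.zeros(grid.shape, dtype=bool)
        for cls in prefs[i].preferred_classes:
            present |= (lc == cls).any(axis=(1, 3))
        for oy, oe in (
            (opt_y, opt_e),
            (opt_y + config.warming_shift, opt_e + config.elevation_shift),
        ):
            d2_xy = (xx - opt_x) ** 2 + (yy - oy) ** 2
            d_e = np.maximum(emin - oe, 0.0) + np.maximum(oe - emax, 0.0)
            suit = expit(
                config.peak_logit
                - d2_xy / config.range_scale**2
                - config.elevation_lapse * d_e**2
            )
            quality += np.where(present, suit, 0.0)

    local = quality - gaussian_filter(quality, sigma=50_000.0 / grid.cell_size)
    sd = local.std()
    local = (local - local.mean()) / sd if sd > 0 else np.zeros_like(local)
    cols = np.clip(((cx - grid.origin_x) // grid.cell_size).astype(int), 0, grid.n_cols - 1)
    rows = np.clip(((cy - grid.origin_y) // grid.cell_size).astype(int), 0, grid.n_rows - 1)
    return local[rows, cols]


def generate_pas(grid: GridSpec, config: ScenarioConfig) -> list[ProtectedArea]:
    """Protected-area rectangles with log-normal areas, clipped to the grid.

    Aspect ratios are uniform on [0.5, 2]; centres are uniform over the
    extent, so edge PAs are clipped and may lose area.  Log-areas are
    marginally Normal(pa_area_log_mean, pa_area_log_sd), but their z-score
    is correlated (``pa_quality_coupling``) with the site's multi-species
    climatic quality: reserves are designated *for* their biological
    interest, so larger reserves sit on better sites.
    """
    rng = _rng(config.seed, "pas")
    minx, miny, maxx, maxy = grid.extent
    extent_box = box(minx, miny, maxx, maxy)
    cx = rng.uniform(minx, maxx, config.n_pas)
    cy = rng.uniform(miny, maxy, config.n_pas)
    eps = rng.standard_normal(config.n_pas)
    aspects = rng.uniform(0.5, 2.0, config.n_pas)
    c = config.pa_quality_coupling
    if c != 0.0 and config.n_species > 0:
        z = math.sqrt(1.0 - c * c) * eps + c * _site_quality(grid, config, cx, cy)
    else:
        z = eps
    areas = np.exp(config.pa_area_log_mean + config.pa_area_log_sd * z)
    pas = []
    for i in range(config.n_pas):
        w = math.sqrt(areas[i] * aspects[i])
        h = math.sqrt(areas[i] / aspects[i])
        geom = box(cx[i] - w / 2, cy[i] - h / 2, cx[i] + w / 2, cy[i] + h / 2)
        geom = geom.intersection(extent_box)
        pas.append(ProtectedArea(pa_id=f"PA{i:04d}", geometry=geom))
    return pas


def generate_habitat_preferences(config: ScenarioConfig) -> list[HabitatPreference]:
    """Preferred land-cover classes per species (1-based class codes)."""
    rng = _rng(config.seed, "habitat")
    k = config.n_landcover_classes
    prefs = []
    for i in range(config.n_species):
        n_pref = int(
            rng.integers(
                min(config.min_preferred_classes, k),
                min(config.max_preferred_classes, k) + 1,
            )
        )
        classes = rng.choice(np.arange(1, k + 1), size=n_pref, replace=False)
        prefs.append(
            HabitatPreference(species_label(i), frozenset(int(c) for c in classes))
        )
    return prefs
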