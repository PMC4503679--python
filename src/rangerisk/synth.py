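"""Synthetic study system: terrain, climate, scenarios, species, reserves.

The generator emulates the inputs of a montane-forest extinction-risk
study in the tropical Andes: a ridge-shaped digital elevation model on a
decimal-degree lattice, four bioclimatic predictor layers (mean annual
temperature, mean diurnal range, precipitation of the wettest and driest
months), SRES-style uniform-warming scenarios (+3.0 degC "A2-like",
+2.2 degC "B2-like"), a binary forest mask, presence-only occurrence
records sampled from known Gaussian climatic niches, and rectangular
protected-area polygons. Because the niches are planted, every
downstream estimate (range, decline, category) can be checked against
ground truth.

All operations draw from a single numpy Generator seeded explicitly, so
fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import box
from shapely.ops import unary_union

from .grids import CLIMATE_VARIABLES, ClimateStack, Grid
from .occurrences import OccurrenceSet, make_set

#: Default synthetic window: a 1/9-scale cut of the tropical-Andes study
#: window (-81.3..-55.3 E, -29.3..12.3 N), placed on the equatorial
#: Andes. Cells are 0.045 deg (~5 km), matching the ~25 km^2 analysis
#: resolution.
DEFAULT_ORIGIN = (-79.0, 2.0)
DEFAULT_CELL_DEG = 0.045

#: Study-region countries, assigned by fixed longitudinal bands (west to
#: east) so the multi-country endemic filter is deterministic.
COUNTRIES = ("Ecuador", "Colombia", "Peru", "Venezuela", "Bolivia", "Argentina")

ALTITUDE_THRESHOLD_M = 1500.0


@dataclass(frozen=True)
class ScenarioSpec:
    """A uniform climate-change scenario: warming plus optional
    multiplicative precipitation change."""

    name: str
    delta_T: float
    precip_scale_wet: float = 1.0
    precip_scale_dry: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_T < 0:
            raise ValueError("delta_T must be >= 0")
        if self.precip_scale_wet <= 0 or self.precip_scale_dry <= 0:
            raise ValueError("precipitation scale factors must be positive")


#: SRES-style defaults: A2 projects ~3.0 degC surface warming by 2100,
#: B2 ~2.2 degC; neither carries a quantitative precipitation change here.
A2_LIKE = ScenarioSpec("A2", 3.0)
B2_LIKE = ScenarioSpec("B2", 2.2)


@dataclass
class NicheSpec:
    """Ground-truth Gaussian climatic niche for one synthetic species."""

    species_id: str
    optimum: np.ndarray  # optima on the 4 climate variables
    breadth: np.ndarray  # niche standard deviations, same order
    prevalence: int  # expected number of presence records
    countries: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.optimum = np.asarray(self.optimum, dtype=float)
        self.breadth = np.asarray(self.breadth, dtype=float)
        if self.optimum.shape != self.breadth.shape:
            raise ValueError("optimum and breadth must have equal length")
        if not np.all(self.breadth > 0):
            raise ValueError("niche breadth must be positive elementwise")
        if self.prevalence < 0:
            raise ValueError("prevalence must be >= 0")


def _smooth_noise(shape, rng, sigma=4.0):
    """Unit-variance spatially smooth field."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def make_terrain(
    n_rows: int,
    n_cols: int,
    ridge_height_m: float,
    seed: int,
    origin: tuple[float, float] = DEFAULT_ORIGIN,
    cell_size_deg: float = DEFAULT_CELL_DEG,
) -> Grid:
    """An elongated north-south montane massif with a single summit.

    Elevation falls off exponentially with anisotropic distance from
    the summit (cone-like flanks, closed contours, longer north-south
    than east-west), so the land area available per elevation band
    strictly *decreases* towards the summit — the hypsometry that makes
    an up-slope range shift under warming a net loss, as on real
    mountains. The raw field (profile plus smooth noise) is affinely
    rescaled so the maximum is 1.05 * ridge_height_m and the minimum
    -100 m, guaranteeing montane cells above any threshold up to
    ridge_height_m as well as lowland cells.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("terrain must be at least 8 x 8 cells")
    if ridge_height_m <= 1500:
        raise ValueError("ridge_height_m must exceed 1500 m")
    rng = np.random.default_rng(seed)
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    dx = (cols - n_cols / 2) / (0.20 * n_cols)
    dy = (rows - n_rows / 2) / (0.35 * n_rows)
    profile = np.exp(-np.sqrt(dx**2 + dy**2))
    raw = profile + 0.05 * _smooth_noise((n_rows, n_cols), rng)
    lo, hi = raw.min(), raw.max()
    elev = -100.0 + (raw - lo) / (hi - lo) * (1.05 * ridge_height_m + 100.0)
    return Grid(elev, origin, cell_size_deg)


DEFAULT_PRECIP_PARAMS = {
    "wettest_base_mm": 280.0,
    "wettest_grad_mm": 120.0,  # west-to-east gradient amplitude
    "driest_base_mm": 45.0,
    "driest_grad_mm": 25.0,
    "noise_mm": 15.0,
}


def make_climate(
    terrain: Grid,
    lapse_rate_C_per_m: float = 0.0055,
    sea_level_T: float = 26.0,
    precip_params: dict | None = None,
    noise_sd_C: float = 0.3,
    seed: int = 0,
) -> ClimateStack:
    """Four co-registered climate layers driven by the terrain.

    Mean annual temperature follows a linear lapse from sea level plus a
    smooth noise field (strictly monotone in elevation when
    ``noise_sd_C`` is 0). Diurnal range is a smooth field independent of
    elevation; the two precipitation layers combine a west-east gradient
    with smooth noise and are floored at 1 mm.
    """
    if lapse_rate_C_per_m <= 0:
        raise ValueError("lapse_rate_C_per_m must be positive")
    pp = {**DEFAULT_PRECIP_PARAMS, **(precip_params or {})}
    rng = np.random.default_rng(seed)
    shape = terrain.data.shape
    temp = sea_level_T - lapse_rate_C_per_m * terrain.data
    if noise_sd_C > 0:
        temp = temp + noise_sd_C * _smooth_noise(shape, rng)
    diurnal = 11.0 + 1.5 * _smooth_noise(shape, rng)
    xnorm = np.linspace(-1.0, 1.0, shape[1])[None, :]
    wet = pp["wettest_base_mm"] + pp["wettest_grad_mm"] * xnorm + pp["noise_mm"] * _smooth_noise(shape, rng)
    dry = pp["driest_base_mm"] + pp["driest_grad_mm"] * xnorm + 0.4 * pp["noise_mm"] * _smooth_noise(shape, rng)
    layers = {
        "mean_annual_temp_C": temp,
        "diurnal_range_C": diurnal,
        "precip_wettest_mm": np.maximum(wet, 1.0),
        "precip_driest_mm": np.maximum(dry, 1.0),
    }
    return ClimateStack(layers, terrain.origin, terrain.cell_size_deg, epoch="current")


def apply_scenario(climate: ClimateStack, scenario: ScenarioSpec) -> ClimateStack:
    """Shift the temperature layer by +delta_T and scale the two
    precipitation layers; the diurnal range, being a temperature
    difference, is unchanged by uniform warming."""
    out = climate.copy()
    out.layers["mean_annual_temp_C"] = out.layers["mean_annual_temp_C"] + scenario.delta_T
    out.layers["precip_wettest_mm"] = out.layers["precip_wettest_mm"] * scenario.precip_scale_wet
    out.layers["precip_driest_mm"] = out.layers["precip_driest_mm"] * scenario.precip_scale_dry
    out.epoch = scenario.name
    return out


def make_forest(terrain: Grid, cover: float = 0.85, seed: int = 0) -> Grid:
    """Binary forest mask: a smooth random field thresholded so about
    ``cover`` of cells are forest (value 1)."""
    if not 0 <= cover <= 1:
        raise ValueError("cover must be in [0, 1]")
    rng = np.random.default_rng(seed)
    f = _smooth_noise(terrain.data.shape, rng, sigma=3.0)
    if cover == 1.0:
        mask = np.ones_like(f)
    elif cover == 0.0:
        mask = np.zeros_like(f)
    else:
        mask = (f <= np.quantile(f, cover)).astype(float)
    return Grid(mask, terrain.origin, terrain.cell_size_deg)


def country_of_lon(lon, west: float, east: float) -> np.ndarray:
    """Country labels from fixed equal-width longitudinal bands."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    n = len(COUNTRIES)
    idx = np.clip(((lon - west) / (east - west) * n).astype(int), 0, n - 1)
    return np.array(COUNTRIES)[idx]


def true_suitability(niche: NicheSpec, climate: ClimateStack) -> np.ndarray:
    """Noise-free Gaussian niche suitability per cell:
    exp(-sum_k (x_k - mu_k)^2 / (2 sigma_k^2))."""
    z2 = np.zeros(climate.shape)
    for k, var in enumerate(CLIMATE_VARIABLES):
        z2 += ((climate.layers[var] - niche.optimum[k]) / niche.breadth[k]) ** 2
    return np.exp(-0.5 * z2)


def sample_occurrences(
    niche: NicheSpec,
    climate: ClimateStack,
    terrain: Grid,
    forest_mask: Grid | None = None,
    seed: int = 0,
) -> OccurrenceSet:
    """Presence-only records drawn with probability proportional to niche
    suitability, optionally restricted to forested cells, jittered
    uniformly within their source cell. Elevation comes from the terrain
    cell; country labels from the longitudinal bands."""
    if niche.prevalence < 1:
        raise ValueError("prevalence must be >= 1 to sample records")
    climate.require_georef(terrain)
    suit = true_suitability(niche, climate)
    if forest_mask is not None:
        terrain.require_georef(forest_mask)
        suit = suit * (forest_mask.data > 0)
    total = suit.sum()
    if total <= 0 or not np.isfinite(total):
        warnings.warn(f"{niche.species_id}: no suitable area; empty occurrence set")
        return make_set(niche.species_id, [], [], provenance="synthetic")
    rng = np.random.default_rng(seed)
    p = (suit / total).ravel()
    flat = rng.choice(suit.size, size=int(niche.prevalence), p=p)
    row, col = np.unravel_index(flat, suit.shape)
    cell = terrain.cell_size_deg
    lon = terrain.west + (col + rng.random(len(col))) * cell
    lat = terrain.north - (row + rng.random(len(row))) * cell
    return make_set(
        niche.species_id,
        lon,
        lat,
        elevation_m=terrain.data[row, col],
        country=country_of_lon(lon, terrain.west, terrain.east),
        provenance="synthetic",
    )


def make_model_suite(
    climate: ClimateStack,
    terrain: Grid,
    n_species: int = 13,
    prevalence: int = 40,
    elev_range_m: tuple[float, float] = (2400.0, 3900.0),
    breadth_scale_temp: float = 0.25,
    breadth_scale_other: float = 1.0,
    seed: int = 0,
) -> list[NicheSpec]:
    """Plant ``n_species`` Gaussian niches centred on the climates of
    randomly chosen montane cells.

    The species are thermally specialised upper-montane trees: the
    temperature breadth is ``breadth_scale_temp`` times the regional
    standard deviation (a narrow elevational band), while tolerance of
    the remaining variables is broad (``breadth_scale_other`` regional
    standard deviations), so suitable area tracks the thermal band.
    """
    rng = np.random.default_rng(seed)
    elev = terrain.data
    candidates = np.flatnonzero((elev >= elev_range_m[0]) & (elev <= elev_range_m[1]))
    if len(candidates) < n_species:
        raise ValueError("not enough montane cells to plant niches")
    chosen = rng.choice(candidates, size=n_species, replace=False)
    rows, cols = np.unravel_index(chosen, elev.shape)
    sds = np.array([climate.layers[v].std() for v in CLIMATE_VARIABLES])
    scales = np.full(len(CLIMATE_VARIABLES), breadth_scale_other)
    scales[0] = breadth_scale_temp  # mean annual temperature leads
    suite = []
    for i, (r, c) in enumerate(zip(rows, cols)):
        optimum = np.array([climate.layers[v][r, c] for v in CLIMATE_VARIABLES])
        suite.append(
            NicheSpec(
                species_id=f"SP{i + 1:03d}",
                optimum=optimum,
                breadth=scales * sds,
                prevalence=prevalence,
            )
        )
    return suite


def make_filter_fixture(
    seed: int = 0,
    n_no_georef: int = 917,
    n_single_country: int = 1287,
    n_below_altitude: int = 1400,
    n_synonyms: int = 17,
    n_survivors: int = 129,
    n_data_deficient: int = 9,
    n_mcp_only: int = 16,
    window: tuple[float, float, float, float] = (-79.0, -76.12, -0.88, 2.0),
) -> tuple[dict[str, OccurrenceSet], list[str]]:
    """A species collection engineered for the candidate-selection rules.

    Defaults mirror a full-scale regional screen: 3750 candidates of which
    917 have no georeferenced records, 1287 are single-country, 1400 have
    at least one record below 1500 m, 17 are taxonomic synonyms, leaving
    129 survivors. Of the survivors, ``n_data_deficient`` have < 3 unique
    records and ``n_mcp_only`` have 3-4, so 25 are excluded from
    modelling by default; the first survivor carries 65 records, the
    regional maximum. Returns (species collection, synonym list).

    ``window`` is (west, east, south, north) for coordinate placement.
    """
    if n_data_deficient + n_mcp_only > n_survivors:
        raise ValueError("survivor sub-counts exceed n_survivors")
    rng = np.random.default_rng(seed)
    west, east, south, north = window
    sets: dict[str, OccurrenceSet] = {}
    synonyms: list[str] = []
    counter = 0

    def _coords(n):
        return (
            rng.uniform(west, east, n),
            rng.uniform(south, north, n),
        )

    def _add(tag, n_records, elevations, countries):
        nonlocal counter
        counter += 1
        sid = f"{tag}{counter:04d}"
        lon, lat = _coords(n_records)
        sets[sid] = make_set(sid, lon, lat, elevations, countries, provenance="fixture")
        return sid

    for _ in range(n_no_georef):
        _add("NG", 0, [], [])
    for _ in range(n_single_country):
        n = int(rng.integers(2, 5))
        _add("SC", n, rng.uniform(1500, 3500, n), ["Peru"] * n)
    for _ in range(n_below_altitude):
        n = int(rng.integers(2, 5))
        elev = rng.uniform(1500, 3500, n)
        elev[0] = rng.uniform(200, 1499)
        _add("BA", n, elev, [COUNTRIES[i % 2] for i in range(n)])
    for _ in range(n_synonyms):
        n = int(rng.integers(2, 5))
        sid = _add("SY", n, rng.uniform(1500, 3500, n), [COUNTRIES[i % 3] for i in range(n)])
        synonyms.append(sid)
    record_counts = (
        [2] * n_data_deficient
        + [int(rng.integers(3, 5)) for _ in range(n_mcp_only)]
        + [65]
        + [int(rng.integers(5, 40)) for _ in range(n_survivors - n_data_deficient - n_mcp_only - 1)]
    )
    for n in record_counts:
        _add("SV", n, rng.uniform(1500, 3500, n), [COUNTRIES[i % 3] for i in range(n)])
    return sets, synonyms


def make_protected_areas(terrain: Grid, coverage_fraction: float, seed: int = 0) -> list:
    """Protected-area polygons over the montane (>= 1500 m) zone.

    Randomly chosen montane cells are promoted to cell-sized rectangles
    and dissolved into polygons; the fraction of montane cell centres
    covered equals ``coverage_fraction`` to within one cell.
    """
    if not 0 <= coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in [0, 1]")
    if coverage_fraction == 0:
        return []
    rng = np.random.default_rng(seed)
    high = np.flatnonzero(terrain.data >= ALTITUDE_THRESHOLD_M)
    k = int(round(coverage_fraction * len(high)))
    if coverage_fraction == 1:
        chosen = high
    else:
        chosen = rng.choice(high, size=k, replace=False)
    rows, cols = np.unravel_index(chosen, terrain.data.shape)
    cell = terrain.cell_size_deg
    boxes = [
        box(
            terrain.west + c * cell,
            terrain.north - (r + 1) * cell,
            terrain.west + (c + 1) * cell,
            terrain.north - r * cell,
        )
        for r, c in zip(rows, cols)
    ]
    merged = unary_union(boxes)
    return list(getattr(merged, "geoms", [merged]))
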