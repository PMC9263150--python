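"""Seeded synthetic coastal sites for end-to-end testing of the pipeline.

The generator emulates the structure the analysis depends on, not the
physics that produced it: a DEM with a gentle seaward gradient and tidal
creeks dipping below mean sea level, a mangrove fringe occupying the
elevation band between mean sea level (MSL) and mean high water spring
(MHWS), a 4-band integer surface-reflectance image in which open water,
land, and isolated ponds are spectrally separable by the green+red−NIR−SWIR1
index, and ²¹⁰Pb/²²⁶Ra core profiles with exponential excess decay.

Convention: row 0 is the northern, seaward edge; elevation rises inland
(southward). All rasters produced for one site share shape, transform, and
CRS, so downstream alignment checks pass by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidConfigError
from .pb210 import Pb210Core, write_core_csv
from .raster import GridTransform, Raster, write_ascii_grid
from .scenarios import builtin_scenario_table  # noqa: F401  (fixture surface)

__all__ = [
    "SiteConfig", "SiteFixture", "make_dem", "make_mangrove_mask",
    "make_multiband_image", "make_core", "make_site_fixture",
    "builtin_scenario_table", "write_fixture_bundle",
]

# Band-mean reflectances (on the 0..scale integer scale) for the two
# spectral classes. Chosen so the water index g+r−nir−swir1 sits far on
# either side of the segmentation threshold 500: +4600 for water, −3700
# for land at zero noise.
_WATER_REFLECTANCE = {"green": 2800, "red": 2400, "nir": 400, "swir1": 200}
_LAND_REFLECTANCE = {"green": 900, "red": 800, "nir": 2600, "swir1": 2300}

BAND_ORDER = ("green", "red", "nir", "swir1")


@dataclass(frozen=True)
class SiteConfig:
    """Parameters of one synthetic coastal site.

    ``noise_sd`` is the additive Gaussian reflectance noise (integer counts
    on the 0..reflectance_scale scale); setting it to 0 makes the whole
    site deterministic, including the DEM microtopography, whose amplitude
    is otherwise ``dem_roughness_m``.
    """

    grid_rows: int = 120
    grid_cols: int = 120
    cell_size: float = 30.0                  # metres per pixel
    elevation_range: tuple[float, float] = (-1.0, 3.0)  # m (offshore, inland)
    creek_count: int = 3
    msl_height: float = 0.40                 # m, plays the role of H0
    mhws_height: float = 1.20                # m, upper mangrove bound
    pond_count: int = 3
    reflectance_scale: int = 10000
    noise_sd: float = 150.0
    dem_roughness_m: float = 0.05
    seed: int = 0

    def __post_init__(self):
        emin, emax = self.elevation_range
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise InvalidConfigError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise InvalidConfigError("cell_size must be positive")
        if not (emin < self.msl_height < self.mhws_height < emax):
            raise InvalidConfigError(
                "need elevation min < msl_height < mhws_height < elevation max")
        if self.creek_count < 0 or self.pond_count < 0:
            raise InvalidConfigError("creek_count and pond_count must be >= 0")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if self.reflectance_scale <= 0:
            raise InvalidConfigError("reflectance_scale must be positive")

    @property
    def transform(self) -> GridTransform:
        return GridTransform(0.0, self.grid_rows * self.cell_size,
                             self.cell_size)


@dataclass
class MultibandImage:
    """Integer surface-reflectance rasters for green, red, NIR, SWIR1."""

    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    swir1: np.ndarray
    transform: GridTransform
    crs: str = "local-metric"
    nodata: int | None = None
    scale: int = 10000

    def __post_init__(self):
        shapes = {b.shape for b in (self.green, self.red, self.nir, self.swir1)}
        if len(shapes) != 1:
            raise InvalidConfigError(f"band shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape

    def bands(self) -> dict[str, np.ndarray]:
        return {"green": self.green, "red": self.red,
                "nir": self.nir, "swir1": self.swir1}


@dataclass
class SiteFixture:
    """One generated site: rasters, ground truth, and dating cores."""

    config: SiteConfig
    dem: Raster
    mangrove_mask: Raster            # boolean data
    image: MultibandImage
    true_water_mask: Raster          # boolean; elevation < msl
    pond_mask: Raster                # boolean; isolated inland water in image
    cores: list[Pb210Core] = field(default_factory=list)
    core_sites: list[tuple[str, int, int]] = field(default_factory=list)
    core_rates: dict[str, float] = field(default_factory=dict)


def make_dem(config: SiteConfig) -> Raster:
    """Synthesize the site DEM: inclined plane + smoothed random field +
    sinusoidal creek channels carved below MSL."""
    rows, cols = config.grid_rows, config.grid_cols
    emin, emax = config.elevation_range
    rng = np.random.default_rng(config.seed)

    inland = np.linspace(0.0, 1.0, rows)[:, None]       # 0 at sea edge (north)
    dem = emin + (emax - emin) * inland * np.ones((1, cols))

    if config.noise_sd > 0 and config.dem_roughness_m > 0:
        rough = ndimage.gaussian_filter(rng.standard_normal((rows, cols)),
                                        sigma=2.0)
        sd = rough.std()
        if sd > 0:
            dem = dem + config.dem_roughness_m * rough / sd

    # Tidal creeks: sinuous channels entering from the seaward edge and
    # tapering out ~70% of the way inland, carved strictly below MSL.
    creek_len = int(round(0.7 * rows))
    col_idx = np.arange(cols)
    for _ in range(config.creek_count):
        base = rng.uniform(0.1, 0.9) * cols
        amp = rng.uniform(2.0, 6.0)
        period = rng.uniform(0.5, 1.5) * rows
        phase = rng.uniform(0, 2 * np.pi)
        width = rng.uniform(1.0, 2.0)
        for r in range(creek_len):
            center = base + amp * np.sin(2 * np.pi * r / period + phase)
            in_channel = np.abs(col_idx - center) <= width
            taper = max(1.0 - r / creek_len, 0.15)
            carved = config.msl_height - (config.msl_height - emin) * taper
            dem[r, in_channel] = np.minimum(dem[r, in_channel], carved)

    return Raster(dem, config.transform, crs="local-metric")


def make_mangrove_mask(dem: Raster, msl: float, mhws: float) -> Raster:
    """Habitat band: cells with MSL ≤ elevation ≤ MHWS (and valid data)."""
    if not msl < mhws:
        raise InvalidConfigError(f"msl {msl} must be below mhws {mhws}")
    mask = (dem.data >= msl) & (dem.data <= mhws) & dem.valid_mask()
    return dem.like(mask)


def _true_water(dem: Raster, msl: float) -> Raster:
    return dem.like((dem.data < msl) & dem.valid_mask())


def _place_ponds(true_water: np.ndarray, mangrove: np.ndarray,
                 config: SiteConfig, rng: np.random.Generator) -> np.ndarray:
    """Isolated 2×2 ponds on dry land, kept ≥2 cells from any open water
    (and from each other) so 8-connectivity can never bridge them to sea."""
    rows, cols = true_water.shape
    pond = np.zeros_like(true_water)
    forbidden = ndimage.binary_dilation(true_water, iterations=2) | mangrove
    eligible = ~forbidden
    eligible[:2, :] = eligible[-3:, :] = False
    eligible[:, :2] = eligible[:, -3:] = False
    candidates = np.flatnonzero(eligible)
    rng.shuffle(candidates)
    placed = 0
    for flat in candidates:
        if placed >= config.pond_count:
            break
        r, c = divmod(int(flat), cols)
        block = np.s_[r:r + 2, c:c + 2]
        if eligible[block].all():
            pond[block] = True
            # keep later ponds clear of this one so each stays one component
            guard = np.s_[max(r - 3, 0):r + 5, max(c - 3, 0):c + 5]
            eligible[guard] = False
            placed += 1
    return pond


def make_multiband_image(true_water_mask: Raster,
                         pond_mask: Raster | np.ndarray | None,
                         config: SiteConfig,
                         rng: np.random.Generator | None = None) -> MultibandImage:
    """Render the spectral image: water signature over open water and
    ponds, land signature elsewhere, plus additive Gaussian noise."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    water = true_water_mask.data.astype(bool)
    if pond_mask is not None:
        pond = pond_mask.data if isinstance(pond_mask, Raster) else pond_mask
        water = water | pond.astype(bool)

    bands = {}
    for name in BAND_ORDER:
        mean = np.where(water, _WATER_REFLECTANCE[name],
                        _LAND_REFLECTANCE[name]).astype(float)
        if config.noise_sd > 0:
            mean = mean + rng.normal(0.0, config.noise_sd, size=mean.shape)
        bands[name] = np.clip(np.rint(mean), 0,
                              config.reflectance_scale).astype(np.int32)
    return MultibandImage(transform=true_water_mask.transform,
                          crs=true_water_mask.crs,
                          scale=config.reflectance_scale, **bands)


def make_core(station: str, d: float, surface_excess: float = 80.0,
              ra_background: float = 20.0, depth_step: float = 2.0,
              max_depth: float = 60.0, noise_cv: float = 0.0,
              seed: int = 0) -> Pb210Core:
    """Synthesize a ²¹⁰Pb core whose excess decays as exp(−d·l).

    Multiplicative lognormal noise with unit median and coefficient of
    variation ``noise_cv`` perturbs the excess; the ²²⁶Ra background is
    noise-free and the reported total ²¹⁰Pb is excess + background, so
    activities stay non-negative.
    """
    if d <= 0:
        raise InvalidConfigError("decay slope d must be positive")
    if max_depth <= 0 or depth_step <= 0:
        raise InvalidConfigError("depths must be positive")
    rng = np.random.default_rng(seed)
    tops = np.arange(0.0, max_depth, depth_step)
    bottoms = np.minimum(tops + depth_step, max_depth)
    mid = (tops + bottoms) / 2.0
    excess = surface_excess * np.exp(-d * mid)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        excess = excess * np.exp(sigma * rng.standard_normal(len(mid)))
    intervals = pd.DataFrame({
        "depth_top_cm": tops,
        "depth_bottom_cm": bottoms,
        "pb210_total": excess + ra_background,
        "ra226": np.full(len(mid), float(ra_background)),
    })
    return Pb210Core(station=station, intervals=intervals)


#: Default stations: decay slopes chosen so V = 0.03/d reproduces the
#: Dongzhaigang rates (HG 0.53, SJ 0.40 cm yr⁻¹).
DEFAULT_CORE_SLOPES = {"HG": 0.03 / 0.53, "SJ": 0.03 / 0.40}


def make_site_fixture(config: SiteConfig | None = None,
                      core_slopes: dict[str, float] | None = None,
                      core_noise_cv: float = 0.0) -> SiteFixture:
    """Generate a complete, internally consistent site."""
    if config is None:
        config = SiteConfig()
    if core_slopes is None:
        core_slopes = dict(DEFAULT_CORE_SLOPES)
    rng = np.random.default_rng(config.seed + 2)

    dem = make_dem(config)
    true_water = _true_water(dem, config.msl_height)
    mangrove = make_mangrove_mask(dem, config.msl_height, config.mhws_height)
    pond = _place_ponds(true_water.data, mangrove.data, config, rng)
    image = make_multiband_image(true_water, pond, config,
                                 rng=np.random.default_rng(config.seed + 1))

    # Station placement: spread cores across the mangrove band at fixed
    # quantiles of the flattened mask-cell index (deterministic).
    mask_cells = np.argwhere(mangrove.data)
    cores, core_sites, core_rates = [], [], {}
    stations = sorted(core_slopes)
    for i, station in enumerate(stations):
        frac = (i + 1) / (len(stations) + 1)
        r, c = mask_cells[int(frac * (len(mask_cells) - 1))]
        core = make_core(station, core_slopes[station],
                         noise_cv=core_noise_cv, seed=config.seed + 10 + i)
        cores.append(core)
        core_sites.append((station, int(r), int(c)))
        core_rates[station] = 0.03 / core_slopes[station]

    return SiteFixture(config=config, dem=dem, mangrove_mask=mangrove,
                       image=image, true_water_mask=true_water,
                       pond_mask=dem.like(pond), cores=cores,
                       core_sites=core_sites, core_rates=core_rates)


def write_fixture_bundle(fixture: SiteFixture, outdir) -> dict:
    """Write a site to disk as plain-text rasters/CSVs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    write_ascii_grid(outdir / "dem.asc", fixture.dem)
    files["dem"] = "dem.asc"
    write_ascii_grid(outdir / "mangrove_mask.asc", fixture.mangrove_mask)
    files["mangrove_mask"] = "mangrove_mask.asc"
    write_ascii_grid(outdir / "true_water_mask.asc", fixture.true_water_mask)
    files["true_water_mask"] = "true_water_mask.asc"
    for name, band in fixture.image.bands().items():
        fname = f"band_{name}.asc"
        write_ascii_grid(outdir / fname,
                         Raster(band, fixture.image.transform,
                                fixture.image.crs))
        files[f"band_{name}"] = fname

    core_rows = []
    for core in fixture.cores:
        write_core_csv(outdir / f"core_{core.station}.csv", core)
        files[f"core_{core.station}"] = f"core_{core.station}.csv"
    for station, r, c in fixture.core_sites:
        core_rows.append({"station": station, "row": r, "col": c})
    pd.DataFrame(core_rows).to_csv(outdir / "core_sites.csv", index=False)
    files["core_sites"] = "core_sites.csv"

    builtin_scenario_table().to_csv(outdir / "scenario_table.csv")
    files["scenario_table"] = "scenario_table.csv"

    manifest = {"config": asdict(fixture.config), "files": files,
                "band_order": list(BAND_ORDER)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
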