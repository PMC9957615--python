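"""Seeded synthetic-landscape generator.

Produces every input the simulator needs — DEM and slope, vegetation map
with optional overstory, daily climate series, livestock distributions and
parameter tables — emulating a temperate oceanic mountain rangeland:
elevations spanning roughly 100–1200 m, a 14 °C mean annual temperature
with regular rain, nine pastureland types and mixed cattle/mare herds.

Generation is fully reproducible: every artifact draws from its own named
substream of a single seed, so reordering generation calls never changes
any individual output.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .context import GridSpec, RasterField
from .units import unit

__all__ = [
    "LandscapeConfig",
    "generate_dem",
    "generate_vegetation_map",
    "generate_climate",
    "generate_livestock",
    "generate_whc",
    "default_vegetation_params",
    "default_livestock_params",
    "generate_exposure",
]

_STREAMS = {
    "dem": 1, "vegetation": 2, "overstory": 3, "climate": 4,
    "livestock": 5, "whc": 6, "exposure": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration of one synthetic landscape."""

    seed: int = 0
    ncols: int = 40
    nrows: int = 40
    cell_size: float = 50.0
    n_vegetation_types: int = 9
    overstory_probability: float = 0.15
    elevation_min: float = 100.0
    elevation_max: float = 1200.0
    tmean_annual: float = 14.0          # °C
    tmean_amplitude: float = 6.0        # °C seasonal half-range
    tmean_noise_sd: float = 1.0         # °C daily noise
    precip_mean: float = 3.5            # mm/day annual mean
    rg_mean: float = 13.0               # MJ/m²/day annual mean
    rg_amplitude: float = 8.0
    n_livestock_groups: int = 14
    animals_per_group: int = 20
    patch_smoothing: float = 3.0        # cells; larger => fewer, bigger patches
    start_year: int = 2018

    def __post_init__(self) -> None:
        if self.n_vegetation_types < 1:
            raise ValueError("need at least one vegetation type")
        if not 0 <= self.overstory_probability <= 1:
            raise ValueError("overstory_probability must lie in [0, 1]")
        if self.elevation_min > self.elevation_max:
            raise ValueError("elevation_min must not exceed elevation_max")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(ncols=self.ncols, nrows=self.nrows,
                        cell_size=self.cell_size)


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    z = rng.standard_normal(shape)
    z = ndimage.gaussian_filter(z, sigma=sigma, mode="reflect")
    lo, hi = z.min(), z.max()
    if hi - lo < 1e-12:
        return np.zeros(shape)
    return (z - lo) / (hi - lo)


def generate_dem(config: LandscapeConfig):
    """A smooth correlated elevation surface and its slope (degrees).

    Slope is computed from central differences of the elevation field.
    Returns ``(elevation_field, slope_field)``.
    """
    rng = _rng(config.seed, "dem")
    grid = config.grid
    z01 = _smooth_noise(rng, grid.shape, sigma=max(2.0, config.patch_smoothing))
    elev = config.elevation_min + z01 * (config.elevation_max - config.elevation_min)
    if min(grid.shape) >= 2:
        dzdy, dzdx = np.gradient(elev, grid.cell_size)
        slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    else:  # degenerate one-cell grids have no gradient
        slope = np.zeros(grid.shape)
    return (
        RasterField("terrain.elevation", grid, elev, unit("m")),
        RasterField("terrain.slope", grid, slope, unit("deg")),
    )


def generate_vegetation_map(config: LandscapeConfig, dem: RasterField):
    """Main and overstory vegetation-code rasters (codes 1..n).

    Types form contiguous patches (quantile slices of a smoothed random
    field blended with elevation); the overstory code differs from the main
    code in a seeded fraction of cells and equals it elsewhere.
    """
    rng = _rng(config.seed, "vegetation")
    grid = config.grid
    n = config.n_vegetation_types
    z = _smooth_noise(rng, grid.shape, sigma=config.patch_smoothing)
    elev01 = (dem.values - dem.values.min())
    rng_e = dem.values.max() - dem.values.min()
    if rng_e > 0:
        elev01 = elev01 / rng_e
    blend = 0.7 * z + 0.3 * elev01
    qs = np.quantile(blend, np.linspace(0, 1, n + 1)[1:-1]) if n > 1 else []
    codes = (np.digitize(blend, qs) + 1).astype(np.int32)

    over_rng = _rng(config.seed, "overstory")
    over = codes.copy()
    mask = over_rng.random(grid.shape) < config.overstory_probability
    if n > 1:
        shift = over_rng.integers(1, n, size=grid.shape)
        over[mask] = ((codes[mask] - 1 + shift[mask]) % n + 1).astype(np.int32)
    main = RasterField("vegetation.code", grid, codes, kind="categorical")
    overstory = RasterField("vegetation.overstory_code", grid, over,
                            kind="categorical")
    return main, overstory


def generate_climate(config: LandscapeConfig, n_days: int,
                     start: _dt.date | None = None) -> pd.DataFrame:
    """Daily climate series: sinusoidal seasonal cycles plus seeded noise.

    Columns: date, tmean_c, precip_mm, rg_mj_m2, pet_mm.  The annual mean
    temperature tracks the configured mean; precipitation is an
    intermittent gamma process; potential evapotranspiration is an
    energy-limited proxy (0.2 mm per MJ/m²).
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    rng = _rng(config.seed, "climate")
    start = start or _dt.date(config.start_year, 1, 1)
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    phase = 2 * np.pi * (doy - 196) / 365.25  # peak near mid-July
    tmean = (config.tmean_annual + config.tmean_amplitude * np.cos(phase)
             + config.tmean_noise_sd * rng.standard_normal(n_days))
    seasonal_wet = 1.0 - 0.4 * np.cos(phase)  # wetter winters
    wet = rng.random(n_days) < 0.45
    precip = np.where(
        wet,
        rng.gamma(shape=0.9, scale=config.precip_mean * seasonal_wet / (0.45 * 0.9),
                  size=n_days),
        0.0,
    )
    rg = np.clip(
        config.rg_mean + config.rg_amplitude * np.cos(phase)
        + 1.5 * rng.standard_normal(n_days),
        0.05, None)
    pet = 0.2 * rg
    return pd.DataFrame({
        "date": dates.date, "tmean_c": tmean, "precip_mm": precip,
        "rg_mj_m2": rg, "pet_mm": pet,
    })


def generate_livestock(config: LandscapeConfig, slope: RasterField):
    """Per-species density rasters plus the per-group parameter table.

    Groups alternate cattle/mare; each group's animals are spread over a
    random low-slope patch, with no animals where the slope exceeds the
    species' accessibility cut-off, so densities concentrate on gentle
    terrain.  Total animals per group equals ``animals_per_group`` (up to
    rounding of the per-cell shares).
    """
    from .livestock import DEFAULT_SLOPE_THRESHOLDS

    rng = _rng(config.seed, "livestock")
    grid = config.grid
    density = {sp: np.zeros(grid.shape) for sp in ("cattle", "mare")}
    rows = []
    for g in range(config.n_livestock_groups):
        sp = "cattle" if g % 2 == 0 else "mare"
        s0, s1 = DEFAULT_SLOPE_THRESHOLDS[sp]
        eligible = slope.values < s1
        if not eligible.any():
            continue
        # seeded preference surface biased to gentle slopes
        pref = np.clip((s1 - slope.values) / s1, 0.0, None) ** 2
        pref *= _smooth_noise(rng, grid.shape, sigma=2.0) + 0.2
        pref[~eligible] = 0.0
        total = pref.sum()
        if total <= 0:
            continue
        density[sp] += config.animals_per_group * pref / total
        rows.append({
            "group_id": f"group_{g + 1:02d}", "species": sp,
            "weight_kg": 550.0 if sp == "cattle" else 450.0,
            "intake_max": 13000.0 if sp == "cattle" else 10000.0,
            "maintenance_coeff": 15.0 if sp == "cattle" else 13.0,
            "conversion_eff": 2e-4,
            "n_retention": 0.15,
            "solid_fraction": 0.6,
        })
    params = pd.DataFrame(rows, columns=[
        "group_id", "species", "weight_kg", "intake_max", "maintenance_coeff",
        "conversion_eff", "n_retention", "solid_fraction"])
    fields = {
        sp: RasterField(f"livestock.{sp}.density", grid, density[sp],
                        unit("animals/cell"))
        for sp in ("cattle", "mare")
    }
    return fields, params


def generate_whc(config: LandscapeConfig) -> RasterField:
    """Soil water-holding capacity raster, 80–150 mm."""
    rng = _rng(config.seed, "whc")
    z = _smooth_noise(rng, config.grid.shape, sigma=config.patch_smoothing)
    return RasterField("soil.whc", config.grid, 80.0 + 70.0 * z, unit("mm"))


def generate_exposure(config: LandscapeConfig) -> RasterField:
    """Topographic radiation exposure raster in [0.6, 1]."""
    rng = _rng(config.seed, "exposure")
    z = _smooth_noise(rng, config.grid.shape, sigma=2.0)
    return RasterField("terrain.exposure", config.grid, 0.6 + 0.4 * z,
                       unit("fraction"))


def default_vegetation_params(n_types: int = 9) -> pd.DataFrame:
    """Per-vegetation-type parameter table for codes 1..n.

    Values vary smoothly across codes within field-plausible ranges for
    temperate pasture and scrub: maximum daily growth 3–6 g/m²/day, tissue
    N targets 2–3.5%, moderate palatability and turnover rates, and a
    spring–autumn phenology window.
    """
    codes = np.arange(1, n_types + 1)
    f = (codes - 1) / max(1, n_types - 1)  # 0..1 across types
    return pd.DataFrame({
        "code": codes,
        "t_base": 2.0 + 2.0 * f,
        "t_opt_lo": 12.0 + 2.0 * f,
        "t_opt_hi": 20.0 + 2.0 * f,
        "t_max": 33.0 + 2.0 * f,
        "rg_half": 4.0 + 3.0 * f,
        "w_crit": 0.5 + 0.2 * f,
        "xf": 3.0 + 3.0 * f,
        "senescence_rate": 0.008 + 0.008 * f,
        "litterfall_rate": 0.015 + 0.01 * f,
        "n_conc_target": 0.02 + 0.015 * f,
        "digestibility": 0.55 + 0.15 * f,
        "palatability": 0.4 + 0.2 * f,
        "k_min": 0.006 + 0.008 * f,
        "reabs_fraction": 0.35 + 0.2 * f,
        "phen_start": np.full(n_types, 60),
        "phen_full_lo": np.full(n_types, 110),
        "phen_full_hi": np.full(n_types, 250),
        "phen_end": np.full(n_types, 330),
    })


def default_livestock_params(config: LandscapeConfig | None = None) -> pd.DataFrame:
    """The per-group livestock parameter table for the default landscape."""
    config = config or LandscapeConfig()
    dem, slope = generate_dem(config)
    _, params = generate_livestock(config, slope)
    return params
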