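"""File formats: single-band GeoTIFF rasters, climate and parameter CSVs,
event tables, and complete fixture directories.

GeoTIFFs are written with ``tifffile``, carrying the standard georeferencing
tags (ModelPixelScale, ModelTiepoint) and the GDAL nodata tag, with
continuous fields as float32 and categorical fields as int32.  A fixture
directory holds every input the simulator needs and round-trips through
:func:`write_fixtures` / :func:`load_fixtures`.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .context import GridSpec, RasterField
from .landscape import (
    LandscapeConfig, generate_dem, generate_vegetation_map, generate_climate,
    generate_livestock, generate_whc, generate_exposure,
    default_vegetation_params,
)
from .units import unit, DIMENSIONLESS

__all__ = [
    "write_geotiff",
    "read_geotiff",
    "write_climate_csv",
    "read_climate_csv",
    "read_events_csv",
    "write_fixtures",
    "load_fixtures",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_geotiff(path, field: RasterField) -> None:
    """Write a RasterField as a single-band GeoTIFF.

    Continuous fields are float32, categorical int32; nodata is recorded in
    the GDAL nodata tag and the grid origin/cell size in the standard
    georeferencing tags.
    """
    grid = field.grid
    if field.kind == "categorical":
        data = field.values.astype(np.int32)
        nodata = str(int(grid.nodata))
    else:
        data = field.values.astype(np.float32)
        nodata = repr(float(grid.nodata))
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", len(nodata) + 1, nodata),
    ]
    tifffile.imwrite(str(path), data, extratags=extratags,
                     metadata={"concept_id": field.concept_id,
                               "units": field.units.name,
                               "kind": field.kind})


def read_geotiff(path, concept_id: str | None = None) -> RasterField:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = page.asarray()
        tags = page.tags
        sx, sy = 1.0, 1.0
        ox, oy = 0.0, 0.0
        nodata = -9999.0
        if _TAG_PIXEL_SCALE in tags:
            scale = tags[_TAG_PIXEL_SCALE].value
            sx, sy = float(scale[0]), float(scale[1])
        if _TAG_TIEPOINT in tags:
            tp = tags[_TAG_TIEPOINT].value
            ox, oy = float(tp[3]), float(tp[4])
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).rstrip("\x00"))
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    kind = meta.get("kind", "categorical"
                    if np.issubdtype(data.dtype, np.integer) else "continuous")
    units = unit(meta["units"]) if meta.get("units") else DIMENSIONLESS
    cid = concept_id or meta.get("concept_id", Path(str(path)).stem)
    grid = GridSpec(ncols=data.shape[1], nrows=data.shape[0], cell_size=sx,
                    origin_x=ox, origin_y=oy, nodata=nodata)
    return RasterField(cid, grid, data, units, kind)


_CLIMATE_COLUMNS = ["date", "tmean_c", "precip_mm", "rg_mj_m2", "pet_mm"]


def write_climate_csv(path, climate: pd.DataFrame) -> None:
    climate.to_csv(path, index=False, columns=_CLIMATE_COLUMNS)


def read_climate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    missing = set(_CLIMATE_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"climate CSV missing columns: {sorted(missing)}")
    if "pet_mm" not in df.columns:
        df["pet_mm"] = 0.2 * df["rg_mj_m2"]
    return df


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    missing = {"date", "zone_id", "kind", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"event CSV missing columns: {sorted(missing)}")
    return df


_RASTER_FILES = {
    "terrain.elevation": "elevation.tif",
    "terrain.slope": "slope.tif",
    "terrain.exposure": "exposure.tif",
    "soil.whc": "whc.tif",
    "vegetation.code": "vegetation_code.tif",
    "vegetation.overstory_code": "overstory_code.tif",
    "livestock.cattle.density": "cattle_density.tif",
    "livestock.mare.density": "mare_density.tif",
}


def write_fixtures(config: LandscapeConfig, outdir, n_days: int = 365,
                   start: _dt.date | None = None) -> Path:
    """Generate and write a complete runnable input set.

    Writes the eight input rasters, the daily climate CSV, the vegetation
    and livestock parameter CSVs, an (empty) event CSV and the landscape
    config as YAML.  Deterministic per (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dem, slope = generate_dem(config)
    veg, over = generate_vegetation_map(config, dem)
    densities, livestock_params = generate_livestock(config, slope)
    whc = generate_whc(config)
    exposure = generate_exposure(config)
    climate = generate_climate(config, n_days, start)
    veg_params = default_vegetation_params(config.n_vegetation_types)

    fields = {
        "terrain.elevation": dem, "terrain.slope": slope,
        "terrain.exposure": exposure, "soil.whc": whc,
        "vegetation.code": veg, "vegetation.overstory_code": over,
        "livestock.cattle.density": densities["cattle"],
        "livestock.mare.density": densities["mare"],
    }
    for cid, fname in _RASTER_FILES.items():
        write_geotiff(outdir / fname, fields[cid])
    write_climate_csv(outdir / "climate.csv", climate)
    veg_params.to_csv(outdir / "vegetation_params.csv", index=False)
    livestock_params.to_csv(outdir / "livestock_params.csv", index=False)
    pd.DataFrame(columns=["date", "zone_id", "kind", "value"]).to_csv(
        outdir / "events.csv", index=False)
    with open(outdir / "landscape.yaml", "w") as fh:
        yaml.safe_dump({k: getattr(config, k)
                        for k in LandscapeConfig.__dataclass_fields__},
                       fh, sort_keys=False)
    return outdir


def load_fixtures(fixture_dir) -> dict:
    """Load a fixture directory into the in-memory input structures.

    Returns a dict with keys ``rasters`` (concept id -> RasterField),
    ``climate`` (DataFrame), ``vegetation_params``, ``livestock_params``
    and ``events`` (None when the event table is empty).
    """
    d = Path(fixture_dir)
    missing = [f for f in list(_RASTER_FILES.values())
               + ["climate.csv", "vegetation_params.csv",
                  "livestock_params.csv"] if not (d / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"fixture directory {d} is missing: {', '.join(missing)}")
    rasters = {cid: read_geotiff(d / fname, cid)
               for cid, fname in _RASTER_FILES.items()}
    events = None
    if (d / "events.csv").exists():
        ev = read_events_csv(d / "events.csv")
        events = ev if len(ev) else None
    return {
        "rasters": rasters,
        "climate": read_climate_csv(d / "climate.csv"),
        "vegetation_params": pd.read_csv(d / "vegetation_params.csv"),
        "livestock_params": pd.read_csv(d / "livestock_params.csv"),
        "events": events,
    }
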