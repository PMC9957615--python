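"""High-level simulation driver: wire a landscape to the dataflow engine.

Ties together the synthetic (or loaded) landscape, the default component
registry and the engine: build the external-input mapping, resolve a
queried concept over a context, execute it and return the state store plus
the resolved dataflow for provenance export.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

from . import engine as eng
from .components import build_default_registry, default_initial_state
from .context import Context, GridSpec, Timeline
from .landscape import (
    LandscapeConfig, default_vegetation_params, generate_climate, generate_dem,
    generate_exposure, generate_livestock, generate_vegetation_map,
    generate_whc,
)

__all__ = ["SimulationSetup", "build_setup", "setup_from_fixtures", "run_query"]


class SimulationSetup:
    """A registry plus the external inputs needed to execute queries."""

    def __init__(self, registry: eng.ModelRegistry, inputs: dict,
                 grid: GridSpec, climate: pd.DataFrame,
                 vegetation_params: pd.DataFrame,
                 livestock_params: pd.DataFrame) -> None:
        self.registry = registry
        self.inputs = inputs
        self.grid = grid
        self.climate = climate
        self.vegetation_params = vegetation_params
        self.livestock_params = livestock_params

    def context(self, start: _dt.date | None = None,
                end: _dt.date | None = None) -> Context:
        dates = pd.to_datetime(self.climate["date"]).dt.date
        start = start or dates.iloc[0]
        end = end or dates.iloc[-1]
        return Context(grid=self.grid, timeline=Timeline(start, end))


def _climate_series(climate: pd.DataFrame) -> dict:
    idx = pd.DatetimeIndex(pd.to_datetime(climate["date"]))
    return {
        "climate.tmean": pd.Series(climate["tmean_c"].to_numpy(), index=idx),
        "climate.precip": pd.Series(climate["precip_mm"].to_numpy(), index=idx),
        "climate.rg": pd.Series(climate["rg_mj_m2"].to_numpy(), index=idx),
        "climate.pet": pd.Series(climate["pet_mm"].to_numpy(), index=idx),
    }


def build_setup(config: LandscapeConfig | None = None, n_days: int = 365,
                with_livestock: bool = True,
                events: pd.DataFrame | None = None) -> SimulationSetup:
    """Generate a synthetic landscape and wire it to the default registry."""
    config = config or LandscapeConfig()
    dem, slope = generate_dem(config)
    veg, over = generate_vegetation_map(config, dem)
    densities, livestock_params = generate_livestock(config, slope)
    whc = generate_whc(config)
    exposure = generate_exposure(config)
    climate = generate_climate(config, n_days)
    veg_params = default_vegetation_params(config.n_vegetation_types)
    if not with_livestock:
        for sp in densities:
            densities[sp].values[:] = 0.0

    registry = build_default_registry(veg_params, livestock_params, events)
    inputs = {
        "terrain.slope": slope,
        "terrain.exposure": exposure,
        "soil.whc": whc,
        "vegetation.code": veg,
        "vegetation.overstory_code": over,
        "livestock.cattle.density": densities["cattle"],
        "livestock.mare.density": densities["mare"],
        **_climate_series(climate),
        **default_initial_state(whc.values, veg.values, veg_params,
                                livestock_params),
    }
    return SimulationSetup(registry, inputs, config.grid, climate,
                           veg_params, livestock_params)


def setup_from_fixtures(fixtures: dict) -> SimulationSetup:
    """Wire a loaded fixture dict (see :func:`pastoral.io.load_fixtures`)."""
    rasters = fixtures["rasters"]
    veg_params = fixtures["vegetation_params"]
    livestock_params = fixtures["livestock_params"]
    registry = build_default_registry(veg_params, livestock_params,
                                      fixtures.get("events"))
    grid = rasters["vegetation.code"].grid
    inputs = {cid: f for cid, f in rasters.items()
              if cid not in ("terrain.elevation",)}
    inputs.update(_climate_series(fixtures["climate"]))
    inputs.update(default_initial_state(
        rasters["soil.whc"].values, rasters["vegetation.code"].values,
        veg_params, livestock_params))
    return SimulationSetup(registry, inputs, grid, fixtures["climate"],
                           veg_params, livestock_params)


def run_query(setup: SimulationSetup, concept_id: str,
              context: Context | None = None, keep: str = "all",
              snapshot_steps=None):
    """Resolve and execute one concept query.

    Returns ``(store, dataflow)``.
    """
    context = context or setup.context()
    dataflow = eng.resolve(concept_id, setup.registry, context)
    store = eng.execute(dataflow, context, setup.inputs, keep=keep,
                        snapshot_steps=snapshot_steps)
    return store, dataflow
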