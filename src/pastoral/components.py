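"""The default component registry: the full pasture–livestock–nitrogen model
wired into the dataflow engine.

Component models are grouped into ten thematic namespaces — moisture,
radiation, temperature, vegetation growth, senescence, litterfall,
ingestion, livestock mass, excretion and nitrogen.  Each component produces
exactly one concept from other concepts; per-vegetation-type parameters are
mapped onto the grid through the vegetation-code raster, and per-species
livestock parameters are aggregated over the groups of each species.

State concepts (soil water, the three biomass pools, the four nitrogen
pools, the plant's reabsorption credit, per-species liveweight, cumulative
animal-retained N) each have a ``change_in_*`` component, so any query
touching them becomes dynamic on multi-step timelines.

Within a day the dependency graph orders the work as: climate limiting
factors → phenology → potential growth → nitrogen uptake and FN → actual
growth → livestock ingestion → digestion and weight change → excretion →
senescence → litterfall → pool updates.  The daily state update is explicit
Euler with Δt = 1 day.  Default parameters keep every outflow sum below its
pool (palatability + senescence rate + harvest fraction ≤ 1), so pools stay
non-negative without rescaling and all balances close exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import climate as cl
from . import livestock as lv
from .engine import Concept, ComponentModel, ModelRegistry, change_concept
from .units import unit

__all__ = ["NAMESPACES", "SPECIES", "build_default_registry", "default_initial_state"]

#: The ten thematic namespaces.
NAMESPACES = (
    "moisture", "radiation", "temperature", "vegetation growth", "senescence",
    "litterfall", "ingestion", "livestock mass", "excretion", "nitrogen",
)

SPECIES = ("cattle", "mare")

#: State concepts advanced by the Euler update, with their external-init ids.
STATE_CONCEPTS = (
    "moisture.soil_water",
    "vegetation.agb_living",
    "vegetation.agb_dead",
    "vegetation.litter",
    "nitrogen.soil_mineral_n",
    "nitrogen.litter_organic_n",
    "nitrogen.n_living",
    "nitrogen.n_dead",
    "nitrogen.reabsorption_credit",
    "livestock.cattle.weight",
    "livestock.mare.weight",
    "livestock.retained_n",
)

#: Multi-sink query pulling the entire coupled system into one dataflow
#: (all pools, both liveweights, and the boundary fluxes needed for budgets).
FULL_SYSTEM_QUERY = STATE_CONCEPTS + (
    "nitrogen.leaching",
    "nitrogen.fertilization",
    "vegetation.harvest_flux",
    "vegetation.litter_decomposition",
    "vegetation.actual_growth",
    "ingestion.total_intake",
    "excretion.n_living_biomass_from_cattle_solid_manure",
)

_EPS = 1e-12


class _CodeParams:
    """Maps per-vegetation-code parameter columns onto a code raster."""

    def __init__(self, table: pd.DataFrame) -> None:
        if "code" not in table.columns:
            raise ValueError("vegetation parameter table needs a 'code' column")
        self.table = table.set_index("code")

    def __call__(self, column: str, codes: np.ndarray) -> np.ndarray:
        series = self.table[column]
        flat = series.reindex(codes.astype(int).ravel())
        if flat.isna().any():
            missing = sorted(set(codes.astype(int).ravel()) - set(series.index))
            raise KeyError(f"vegetation codes without parameters: {missing}")
        return flat.to_numpy(dtype=float).reshape(codes.shape)

    def calendar(self, codes: np.ndarray) -> np.ndarray:
        """Per-cell 366-day phenology calendars stacked by code."""
        cals = {
            int(code): cl.trapezoid_calendar(
                int(row["phen_start"]), int(row["phen_full_lo"]),
                int(row["phen_full_hi"]), int(row["phen_end"]))
            for code, row in self.table.iterrows()
        }
        return cals


def _species_params(livestock_table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Aggregate the per-group parameter table to per-species means."""
    required = {"species", "intake_max", "maintenance_coeff", "conversion_eff",
                "n_retention", "solid_fraction", "weight_kg"}
    missing = required - set(livestock_table.columns)
    if missing:
        raise ValueError(f"livestock table missing columns: {sorted(missing)}")
    out: dict[str, dict[str, float]] = {}
    for sp, grp in livestock_table.groupby("species"):
        out[sp] = {c: float(grp[c].mean()) for c in required - {"species"}}
    for sp in SPECIES:
        out.setdefault(sp, {
            "intake_max": 1.0, "maintenance_coeff": 0.0, "conversion_eff": 0.0,
            "n_retention": 0.0, "solid_fraction": 0.5, "weight_kg": 1.0,
        })
    return out


def _safe_div(num, den, fallback=0.0):
    den = np.asarray(den, dtype=float)
    ok = den > _EPS
    return np.where(ok, np.asarray(num, dtype=float) / np.where(ok, den, 1.0),
                    fallback)


def build_default_registry(
    vegetation_params: pd.DataFrame,
    livestock_params: pd.DataFrame,
    events: pd.DataFrame | None = None,
) -> ModelRegistry:
    """Assemble the full default model registry.

    ``vegetation_params`` has one row per vegetation code (columns: code,
    t_base, t_opt_lo, t_opt_hi, t_max, rg_half, w_crit, xf, senescence_rate,
    litterfall_rate, n_conc_target, digestibility, palatability, k_min,
    reabs_fraction, phen_start, phen_full_lo, phen_full_hi, phen_end);
    ``livestock_params`` one row per livestock group; ``events`` the
    optional harvest/fertilization event table (date, zone_id, kind, value).
    """
    P = _CodeParams(vegetation_params)
    S = _species_params(livestock_params)
    calendars = P.calendar(vegetation_params["code"].to_numpy())
    if events is not None and len(events):
        events = events.copy()
        events["date"] = pd.to_datetime(events["date"]).dt.date
    else:
        events = None

    reg = ModelRegistry()

    frac = unit("fraction")
    gm2 = unit("g/m^2")
    gm2d = unit("g/m^2/day")

    external = {
        "climate.tmean": ("daily mean air temperature", unit("degC")),
        "climate.precip": ("daily precipitation", unit("mm/day")),
        "climate.rg": ("incident solar radiation", unit("MJ/m^2/day")),
        "climate.pet": ("potential evapotranspiration", unit("mm/day")),
        "terrain.slope": ("terrain slope", unit("deg")),
        "terrain.exposure": ("topographic radiation exposure", frac),
        "soil.whc": ("soil water holding capacity", unit("mm")),
        "vegetation.code": ("main vegetation type code (com)", frac),
        "vegetation.overstory_code": ("overstory vegetation code (com2)", frac),
        "livestock.cattle.density": ("cattle per cell", unit("animals/cell")),
        "livestock.mare.density": ("mares per cell", unit("animals/cell")),
    }
    state_meta = {
        "moisture.soil_water": ("plant-available soil water", unit("mm")),
        "vegetation.agb_living": ("living above-ground biomass", gm2),
        "vegetation.agb_dead": ("standing dead biomass", gm2),
        "vegetation.litter": ("litter mass", gm2),
        "nitrogen.soil_mineral_n": ("soil mineral nitrogen", gm2),
        "nitrogen.litter_organic_n": ("litter organic nitrogen", gm2),
        "nitrogen.n_living": ("nitrogen in living biomass", gm2),
        "nitrogen.n_dead": ("nitrogen in standing dead biomass", gm2),
        "nitrogen.reabsorption_credit": ("plant internal reabsorbed-N budget", gm2),
        "livestock.cattle.weight": ("cattle liveweight", unit("kg")),
        "livestock.mare.weight": ("mare liveweight", unit("kg")),
        "livestock.retained_n": ("cumulative N retained by livestock", gm2),
    }
    for cid, (desc, u) in {**external, **state_meta}.items():
        reg.declare_external(cid, Concept(cid, desc, u, "amount"))

    def comp(cid, ns, output, inputs, fn, prov="expression", desc=""):
        reg.register(ComponentModel(id=cid, namespace=ns, output=output,
                                    inputs=tuple(inputs), compute=fn,
                                    provenance=prov, description=desc))
        if output not in reg.concepts:
            reg.declare_concept(Concept(output, desc or cid))

    # ------------------------------------------------------------------
    # temperature namespace
    def _ft(v, step):
        code = v["vegetation.code"]
        t = v["climate.tmean"]
        t_base = P("t_base", code)
        t_lo = P("t_opt_lo", code)
        t_hi = P("t_opt_hi", code)
        t_max = P("t_max", code)
        up = _safe_div(t - t_base, t_lo - t_base, 0.0)
        down = _safe_div(t_max - t, t_max - t_hi, 0.0)
        return np.clip(np.minimum(up, down), 0.0, 1.0)

    comp("temperature.growth_limiting_factor", "temperature",
         "temperature.growth_limiting_factor",
         ["climate.tmean", "vegetation.code"], _ft, "table",
         "Temperature limiting factor FT (trapezoid between vegetation-type "
         "thresholds)")

    # ------------------------------------------------------------------
    # radiation namespace
    comp("radiation.surface", "radiation", "radiation.surface",
         ["climate.rg", "terrain.exposure"],
         lambda v, s: v["climate.rg"] * v["terrain.exposure"],
         desc="Solar radiation at the surface after topographic exposure")

    comp("radiation.over_vegetation", "radiation", "radiation.over_vegetation",
         ["radiation.surface", "vegetation.code", "vegetation.overstory_code"],
         lambda v, s: cl.radiation_over_vegetation(
             v["radiation.surface"], v["vegetation.code"],
             v["vegetation.overstory_code"]),
         desc="Radiation reaching the (possibly understory) vegetation, rg2; "
              "0.2 x rg beneath a distinct overstory")

    comp("radiation.growth_limiting_factor", "radiation",
         "radiation.growth_limiting_factor",
         ["radiation.over_vegetation", "vegetation.code"],
         lambda v, s: v["radiation.over_vegetation"]
         / (v["radiation.over_vegetation"] + P("rg_half", v["vegetation.code"])),
         "table", "Radiation limiting factor FR (saturating)")

    # ------------------------------------------------------------------
    # moisture namespace
    comp("moisture.growth_limiting_factor", "moisture",
         "moisture.growth_limiting_factor",
         ["moisture.soil_water", "soil.whc", "vegetation.code"],
         lambda v, s: np.clip(
             _safe_div(v["moisture.soil_water"], v["soil.whc"])
             / P("w_crit", v["vegetation.code"]), 0.0, 1.0),
         "table", "Soil moisture limiting factor FH")

    comp("moisture.actual_et", "moisture", "moisture.actual_et",
         ["climate.pet", "moisture.growth_limiting_factor",
          "moisture.soil_water", "climate.precip"],
         lambda v, s: np.minimum(
             v["climate.pet"] * v["moisture.growth_limiting_factor"],
             v["moisture.soil_water"] + v["climate.precip"]),
         desc="Actual evapotranspiration (moisture-limited demand)")

    comp("moisture.drainage", "moisture", "moisture.drainage",
         ["moisture.soil_water", "climate.precip", "moisture.actual_et",
          "soil.whc"],
         lambda v, s: np.maximum(
             0.0, v["moisture.soil_water"] + v["climate.precip"]
             - v["moisture.actual_et"] - v["soil.whc"]),
         desc="Bucket overflow drainage")

    comp("moisture.soil_water.change", "moisture",
         change_concept("moisture.soil_water"),
         ["climate.precip", "moisture.actual_et", "moisture.drainage"],
         lambda v, s: v["climate.precip"] - v["moisture.actual_et"]
         - v["moisture.drainage"],
         desc="Daily soil-water balance")

    # ------------------------------------------------------------------
    # vegetation growth namespace
    def _ph(v, step):
        code = v["vegetation.code"].astype(int)
        doy = min(step.day_of_year, 366)
        out = np.zeros(code.shape)
        for c, cal in calendars.items():
            out[code == c] = cal[doy - 1]
        return out

    comp("vegetation.phenology", "vegetation growth", "vegetation.phenology",
         ["vegetation.code"], _ph, "table",
         "Phenological activity ph from the vegetation type's calendar")

    comp("vegetation.combined_climate_factor", "vegetation growth",
         "vegetation.combined_climate_factor",
         ["temperature.growth_limiting_factor",
          "radiation.growth_limiting_factor",
          "moisture.growth_limiting_factor"],
         lambda v, s: v["temperature.growth_limiting_factor"]
         * v["radiation.growth_limiting_factor"]
         * v["moisture.growth_limiting_factor"],
         desc="Combined abiotic factor FTRH = FT x FR x FH")

    comp("vegetation.potential_growth", "vegetation growth",
         "vegetation.potential_growth",
         ["vegetation.code", "vegetation.combined_climate_factor",
          "vegetation.phenology"],
         lambda v, s: P("xf", v["vegetation.code"])
         * v["vegetation.combined_climate_factor"] * v["vegetation.phenology"],
         "table", "Potential growth = xf x FTRH x ph")

    comp("vegetation.actual_growth", "vegetation growth",
         "vegetation.actual_growth",
         ["vegetation.potential_growth", "nitrogen.growth_limiting_factor"],
         lambda v, s: v["vegetation.potential_growth"]
         * v["nitrogen.growth_limiting_factor"],
         desc="Actual growth = potential x FN; grazing acts on the pool")

    comp("vegetation.agb_living.change", "vegetation growth",
         change_concept("vegetation.agb_living"),
         ["vegetation.actual_growth", "vegetation.senescence_flux",
          "vegetation.harvest_flux", "ingestion.cattle.intake_living",
          "ingestion.mare.intake_living"],
         lambda v, s: v["vegetation.actual_growth"]
         - v["vegetation.senescence_flux"] - v["vegetation.harvest_flux"]
         - v["ingestion.cattle.intake_living"]
         - v["ingestion.mare.intake_living"],
         desc="Daily living-biomass balance")

    # ------------------------------------------------------------------
    # senescence namespace
    comp("vegetation.senescence_flux", "senescence",
         "vegetation.senescence_flux",
         ["vegetation.agb_living", "vegetation.phenology", "vegetation.code"],
         lambda v, s: v["vegetation.agb_living"]
         * P("senescence_rate", v["vegetation.code"])
         * (1.0 - v["vegetation.phenology"]),
         "table", "Senescence flux, peaking at low phenological activity")

    # ------------------------------------------------------------------
    # litterfall namespace
    comp("vegetation.litterfall_flux", "litterfall",
         "vegetation.litterfall_flux",
         ["vegetation.agb_dead", "vegetation.code"],
         lambda v, s: v["vegetation.agb_dead"]
         * P("litterfall_rate", v["vegetation.code"]),
         "table", "Litterfall from the standing-dead pool")

    def _harvest(v, step):
        agb = v["vegetation.agb_living"]
        out = np.zeros(agb.shape)
        if events is None:
            return out
        todays = events[(events["date"] == step.date)
                        & (events["kind"] == "harvest")]
        for _, row in todays.iterrows():
            sel = v["vegetation.code"].astype(int) == int(row["zone_id"])
            out[sel] += agb[sel] * float(row["value"])
        return out

    comp("vegetation.harvest_flux", "litterfall", "vegetation.harvest_flux",
         ["vegetation.agb_living", "vegetation.code"], _harvest, "table",
         "Event-driven harvest removal of living biomass")

    comp("vegetation.litter_decomposition", "litterfall",
         "vegetation.litter_decomposition",
         ["vegetation.litter", "temperature.growth_limiting_factor",
          "moisture.growth_limiting_factor", "vegetation.code"],
         lambda v, s: v["vegetation.litter"] * P("k_min", v["vegetation.code"])
         * v["temperature.growth_limiting_factor"]
         * v["moisture.growth_limiting_factor"],
         "table", "Litter mass decomposition (same first-order rate as N "
         "mineralization, preserving the litter C:N ratio)")

    comp("vegetation.agb_dead.change", "litterfall",
         change_concept("vegetation.agb_dead"),
         ["vegetation.senescence_flux", "vegetation.litterfall_flux",
          "ingestion.cattle.intake_dead", "ingestion.mare.intake_dead"],
         lambda v, s: v["vegetation.senescence_flux"]
         - v["vegetation.litterfall_flux"]
         - v["ingestion.cattle.intake_dead"] - v["ingestion.mare.intake_dead"],
         desc="Daily standing-dead balance")

    comp("vegetation.litter.change", "litterfall",
         change_concept("vegetation.litter"),
         ["vegetation.litterfall_flux", "vegetation.litter_decomposition"],
         lambda v, s: v["vegetation.litterfall_flux"]
         - v["vegetation.litter_decomposition"],
         desc="Daily litter balance")

    # ------------------------------------------------------------------
    # ingestion namespace
    for sp in SPECIES:
        comp(f"ingestion.{sp}.accessibility", "ingestion",
             f"ingestion.{sp}.accessibility", ["terrain.slope"],
             (lambda sp: lambda v, s: lv.accessibility(v["terrain.slope"], sp))(sp),
             desc=f"Slope accessibility of {sp}")

        comp(f"ingestion.{sp}.demand", "ingestion", f"ingestion.{sp}.demand",
             [f"livestock.{sp}.density", f"ingestion.{sp}.accessibility"],
             (lambda sp: lambda v, s: v[f"livestock.{sp}.density"]
              * S[sp]["intake_max"] * v[f"ingestion.{sp}.accessibility"]
              / s.cell_area)(sp),
             "table", f"Grazing demand of {sp}, g/m^2/day")

    comp("ingestion.supply_living", "ingestion", "ingestion.supply_living",
         ["vegetation.agb_living", "vegetation.code"],
         lambda v, s: v["vegetation.agb_living"]
         * P("palatability", v["vegetation.code"]),
         "table", "Palatable living biomass")

    comp("ingestion.supply_dead", "ingestion", "ingestion.supply_dead",
         ["vegetation.agb_dead", "vegetation.code"],
         lambda v, s: v["vegetation.agb_dead"]
         * P("palatability", v["vegetation.code"]),
         "table", "Palatable standing-dead biomass")

    comp("ingestion.total_demand", "ingestion", "ingestion.total_demand",
         ["ingestion.cattle.demand", "ingestion.mare.demand"],
         lambda v, s: v["ingestion.cattle.demand"] + v["ingestion.mare.demand"])

    def _ration(v, s):
        supply = v["ingestion.supply_living"] + v["ingestion.supply_dead"]
        d = v["ingestion.total_demand"]
        return np.where(d > supply, _safe_div(supply, d, 1.0), 1.0)

    comp("ingestion.ration", "ingestion", "ingestion.ration",
         ["ingestion.total_demand", "ingestion.supply_living",
          "ingestion.supply_dead"], _ration,
         desc="Common satisfaction fraction under proportional competition")

    for sp in SPECIES:
        comp(f"ingestion.{sp}.intake", "ingestion", f"ingestion.{sp}.intake",
             [f"ingestion.{sp}.demand", "ingestion.ration"],
             (lambda sp: lambda v, s: v[f"ingestion.{sp}.demand"]
              * v["ingestion.ration"])(sp),
             desc=f"Realised total intake of {sp}")

    comp("ingestion.total_intake", "ingestion", "ingestion.total_intake",
         ["ingestion.cattle.intake", "ingestion.mare.intake"],
         lambda v, s: v["ingestion.cattle.intake"] + v["ingestion.mare.intake"])

    comp("ingestion.living_fraction", "ingestion", "ingestion.living_fraction",
         ["ingestion.total_intake", "ingestion.supply_living"],
         lambda v, s: np.where(
             v["ingestion.total_intake"] > _EPS,
             _safe_div(np.minimum(v["ingestion.total_intake"],
                                  v["ingestion.supply_living"]),
                       v["ingestion.total_intake"], 1.0),
             1.0),
         desc="Fraction of intake drawn from living biomass (living first)")

    for sp in SPECIES:
        comp(f"ingestion.{sp}.intake_living", "ingestion",
             f"ingestion.{sp}.intake_living",
             [f"ingestion.{sp}.intake", "ingestion.living_fraction"],
             (lambda sp: lambda v, s: v[f"ingestion.{sp}.intake"]
              * v["ingestion.living_fraction"])(sp))
        comp(f"ingestion.{sp}.intake_dead", "ingestion",
             f"ingestion.{sp}.intake_dead",
             [f"ingestion.{sp}.intake", "ingestion.living_fraction"],
             (lambda sp: lambda v, s: v[f"ingestion.{sp}.intake"]
              * (1.0 - v["ingestion.living_fraction"]))(sp))
        comp(f"ingestion.{sp}.intake_n", "ingestion",
             f"ingestion.{sp}.intake_n",
             [f"ingestion.{sp}.intake_living", f"ingestion.{sp}.intake_dead",
              "nitrogen.prop_n_living", "nitrogen.prop_n_dead"],
             (lambda sp: lambda v, s:
              v[f"ingestion.{sp}.intake_living"] * v["nitrogen.prop_n_living"]
              + v[f"ingestion.{sp}.intake_dead"] * v["nitrogen.prop_n_dead"])(sp),
             desc=f"Nitrogen ingested by {sp}")

    # ------------------------------------------------------------------
    # livestock mass namespace
    for sp in SPECIES:
        comp(f"livestock.{sp}.per_animal_intake", "livestock mass",
             f"livestock.{sp}.per_animal_intake",
             [f"ingestion.{sp}.intake", f"livestock.{sp}.density"],
             (lambda sp: lambda v, s: _safe_div(
                 v[f"ingestion.{sp}.intake"] * s.cell_area,
                 v[f"livestock.{sp}.density"]))(sp),
             desc=f"Intake per animal for {sp}, g/animal/day")

        comp(f"livestock.{sp}.digestible_intake", "livestock mass",
             f"livestock.{sp}.digestible_intake",
             [f"livestock.{sp}.per_animal_intake", "vegetation.code"],
             (lambda sp: lambda v, s: v[f"livestock.{sp}.per_animal_intake"]
              * P("digestibility", v["vegetation.code"]))(sp),
             "table", f"Digestible intake per animal for {sp}")

        comp(f"livestock.{sp}.weight.change", "livestock mass",
             change_concept(f"livestock.{sp}.weight"),
             [f"livestock.{sp}.digestible_intake", f"livestock.{sp}.weight",
              f"livestock.{sp}.density"],
             (lambda sp: lambda v, s: np.where(
                 v[f"livestock.{sp}.density"] > 0,
                 lv.mass_change(v[f"livestock.{sp}.digestible_intake"],
                                v[f"livestock.{sp}.weight"],
                                S[sp]["maintenance_coeff"],
                                S[sp]["conversion_eff"]),
                 0.0))(sp),
             "table", f"Daily weight change of {sp} (may be negative)")

    comp("livestock.cattle.prop_living_in_digestion", "livestock mass",
         "livestock.cattle.prop_living_in_digestion",
         ["ingestion.cattle.intake_living", "ingestion.cattle.intake"],
         lambda v, s: _safe_div(v["ingestion.cattle.intake_living"],
                                v["ingestion.cattle.intake"], 1.0),
         desc="Proportion of living biomass in cattle digestion")

    # ------------------------------------------------------------------
    # excretion namespace
    for sp in SPECIES:
        comp(f"excretion.{sp}.solid_n", "excretion", f"excretion.{sp}.solid_n",
             [f"ingestion.{sp}.intake_n"],
             (lambda sp: lambda v, s: v[f"ingestion.{sp}.intake_n"]
              * (1.0 - S[sp]["n_retention"]) * S[sp]["solid_fraction"])(sp),
             "table", f"Solid-manure N from {sp}")
        comp(f"excretion.{sp}.urine_n", "excretion", f"excretion.{sp}.urine_n",
             [f"ingestion.{sp}.intake_n"],
             (lambda sp: lambda v, s: v[f"ingestion.{sp}.intake_n"]
              * (1.0 - S[sp]["n_retention"])
              * (1.0 - S[sp]["solid_fraction"]))(sp),
             "table", f"Urine N from {sp}")

    comp("excretion.solid_n_total", "excretion", "excretion.solid_n_total",
         ["excretion.cattle.solid_n", "excretion.mare.solid_n"],
         lambda v, s: v["excretion.cattle.solid_n"] + v["excretion.mare.solid_n"])

    comp("excretion.urine_n_total", "excretion", "excretion.urine_n_total",
         ["excretion.cattle.urine_n", "excretion.mare.urine_n"],
         lambda v, s: v["excretion.cattle.urine_n"] + v["excretion.mare.urine_n"])

    comp("livestock.retained_n.change", "excretion",
         change_concept("livestock.retained_n"),
         ["ingestion.cattle.intake_n", "ingestion.mare.intake_n"],
         lambda v, s: v["ingestion.cattle.intake_n"] * S["cattle"]["n_retention"]
         + v["ingestion.mare.intake_n"] * S["mare"]["n_retention"],
         desc="N retained in animal tissue")

    comp("excretion.n_living_biomass_from_cattle_solid_manure", "excretion",
         "excretion.n_living_biomass_from_cattle_solid_manure",
         ["ingestion.cattle.intake_living",
          "livestock.cattle.prop_living_in_digestion",
          "nitrogen.prop_n_living"],
         lambda v, s: lv.n_in_biomass_from_solid_manure(
             v["ingestion.cattle.intake_living"],
             v["livestock.cattle.prop_living_in_digestion"],
             v["nitrogen.prop_n_living"]),
         desc="Cross-namespace showcase: N in living biomass routed through "
              "cattle solid manure")

    # ------------------------------------------------------------------
    # nitrogen namespace
    comp("nitrogen.prop_n_living", "nitrogen", "nitrogen.prop_n_living",
         ["nitrogen.n_living", "vegetation.agb_living"],
         lambda v, s: _safe_div(v["nitrogen.n_living"],
                                v["vegetation.agb_living"]),
         desc="Proportion of N in living above-ground biomass")

    comp("nitrogen.prop_n_dead", "nitrogen", "nitrogen.prop_n_dead",
         ["nitrogen.n_dead", "vegetation.agb_dead"],
         lambda v, s: _safe_div(v["nitrogen.n_dead"], v["vegetation.agb_dead"]),
         desc="Proportion of N in standing dead biomass")

    comp("nitrogen.mineralization", "nitrogen", "nitrogen.mineralization",
         ["nitrogen.litter_organic_n", "temperature.growth_limiting_factor",
          "moisture.growth_limiting_factor", "vegetation.code"],
         lambda v, s: v["nitrogen.litter_organic_n"]
         * P("k_min", v["vegetation.code"])
         * v["temperature.growth_limiting_factor"]
         * v["moisture.growth_limiting_factor"],
         "table", "First-order mineralization of litter organic N")

    comp("nitrogen.plant_demand", "nitrogen", "nitrogen.plant_demand",
         ["vegetation.potential_growth", "vegetation.code"],
         lambda v, s: v["vegetation.potential_growth"]
         * P("n_conc_target", v["vegetation.code"]),
         "table", "N demand implied by potential growth")

    comp("nitrogen.credit_used", "nitrogen", "nitrogen.credit_used",
         ["nitrogen.plant_demand", "nitrogen.reabsorption_credit"],
         lambda v, s: np.minimum(v["nitrogen.plant_demand"],
                                 v["nitrogen.reabsorption_credit"]),
         desc="Reabsorbed N spent against today's demand")

    comp("nitrogen.uptake", "nitrogen", "nitrogen.uptake",
         ["nitrogen.plant_demand", "nitrogen.credit_used",
          "nitrogen.soil_mineral_n"],
         lambda v, s: np.minimum(
             v["nitrogen.plant_demand"] - v["nitrogen.credit_used"],
             v["nitrogen.soil_mineral_n"]),
         desc="Mineral-N uptake limited by the soil pool")

    comp("nitrogen.growth_limiting_factor", "nitrogen",
         "nitrogen.growth_limiting_factor",
         ["nitrogen.plant_demand", "nitrogen.credit_used", "nitrogen.uptake"],
         lambda v, s: np.where(
             v["nitrogen.plant_demand"] > _EPS,
             _safe_div(v["nitrogen.credit_used"] + v["nitrogen.uptake"],
                       v["nitrogen.plant_demand"], 1.0),
             1.0),
         desc="Nitrogen limiting factor FN = met demand / demand")

    comp("nitrogen.senesced_n", "nitrogen", "nitrogen.senesced_n",
         ["vegetation.senescence_flux", "nitrogen.prop_n_living"],
         lambda v, s: v["vegetation.senescence_flux"]
         * v["nitrogen.prop_n_living"],
         desc="N leaving the living pool with senescing tissue")

    comp("nitrogen.reabsorbed", "nitrogen", "nitrogen.reabsorbed",
         ["nitrogen.senesced_n", "vegetation.code"],
         lambda v, s: v["nitrogen.senesced_n"]
         * P("reabs_fraction", v["vegetation.code"]),
         "table", "N reabsorbed from senescing tissue")

    comp("nitrogen.senesced_n_to_dead", "nitrogen",
         "nitrogen.senesced_n_to_dead",
         ["nitrogen.senesced_n", "nitrogen.reabsorbed"],
         lambda v, s: v["nitrogen.senesced_n"] - v["nitrogen.reabsorbed"])

    comp("nitrogen.reabsorption_credit.change", "nitrogen",
         change_concept("nitrogen.reabsorption_credit"),
         ["nitrogen.reabsorbed", "nitrogen.credit_used"],
         lambda v, s: v["nitrogen.reabsorbed"] - v["nitrogen.credit_used"],
         desc="Reabsorbed N buffers the next step's demand")

    comp("nitrogen.litterfall_n", "nitrogen", "nitrogen.litterfall_n",
         ["vegetation.litterfall_flux", "nitrogen.prop_n_dead"],
         lambda v, s: v["vegetation.litterfall_flux"]
         * v["nitrogen.prop_n_dead"])

    comp("nitrogen.ingested_living_n", "nitrogen", "nitrogen.ingested_living_n",
         ["ingestion.cattle.intake_living", "ingestion.mare.intake_living",
          "nitrogen.prop_n_living"],
         lambda v, s: (v["ingestion.cattle.intake_living"]
                       + v["ingestion.mare.intake_living"])
         * v["nitrogen.prop_n_living"])

    comp("nitrogen.ingested_dead_n", "nitrogen", "nitrogen.ingested_dead_n",
         ["ingestion.cattle.intake_dead", "ingestion.mare.intake_dead",
          "nitrogen.prop_n_dead"],
         lambda v, s: (v["ingestion.cattle.intake_dead"]
                       + v["ingestion.mare.intake_dead"])
         * v["nitrogen.prop_n_dead"])

    comp("nitrogen.leaching", "nitrogen", "nitrogen.leaching",
         ["nitrogen.soil_mineral_n", "nitrogen.uptake", "moisture.drainage",
          "soil.whc"],
         lambda v, s: (v["nitrogen.soil_mineral_n"] - v["nitrogen.uptake"])
         * np.minimum(1.0, _safe_div(v["moisture.drainage"], v["soil.whc"])),
         desc="Drainage-proportional leaching of the post-uptake mineral pool")

    def _fertilization(v, step):
        out = np.zeros(v["vegetation.code"].shape)
        if events is None:
            return out
        todays = events[(events["date"] == step.date)
                        & (events["kind"] == "fertilization")]
        for _, row in todays.iterrows():
            sel = v["vegetation.code"].astype(int) == int(row["zone_id"])
            out[sel] += float(row["value"])
        return out

    comp("nitrogen.fertilization", "nitrogen", "nitrogen.fertilization",
         ["vegetation.code"], _fertilization, "table",
         "Event-driven mineral-N fertilization, g N/m^2/day")

    comp("nitrogen.soil_mineral_n.change", "nitrogen",
         change_concept("nitrogen.soil_mineral_n"),
         ["nitrogen.mineralization", "excretion.urine_n_total",
          "nitrogen.fertilization", "nitrogen.uptake", "nitrogen.leaching"],
         lambda v, s: v["nitrogen.mineralization"]
         + v["excretion.urine_n_total"] + v["nitrogen.fertilization"]
         - v["nitrogen.uptake"] - v["nitrogen.leaching"],
         desc="Daily mineral-N balance")

    comp("nitrogen.litter_organic_n.change", "nitrogen",
         change_concept("nitrogen.litter_organic_n"),
         ["nitrogen.litterfall_n", "excretion.solid_n_total",
          "nitrogen.mineralization"],
         lambda v, s: v["nitrogen.litterfall_n"]
         + v["excretion.solid_n_total"] - v["nitrogen.mineralization"],
         desc="Daily litter organic-N balance")

    comp("nitrogen.n_living.change", "nitrogen",
         change_concept("nitrogen.n_living"),
         ["nitrogen.uptake", "nitrogen.credit_used", "nitrogen.senesced_n",
          "nitrogen.ingested_living_n"],
         lambda v, s: v["nitrogen.uptake"] + v["nitrogen.credit_used"]
         - v["nitrogen.senesced_n"] - v["nitrogen.ingested_living_n"],
         desc="Daily living-biomass N balance")

    comp("nitrogen.n_dead.change", "nitrogen",
         change_concept("nitrogen.n_dead"),
         ["nitrogen.senesced_n_to_dead", "nitrogen.litterfall_n",
          "nitrogen.ingested_dead_n"],
         lambda v, s: v["nitrogen.senesced_n_to_dead"]
         - v["nitrogen.litterfall_n"] - v["nitrogen.ingested_dead_n"],
         desc="Daily standing-dead N balance")

    return reg


def default_initial_state(whc: np.ndarray, codes: np.ndarray,
                          vegetation_params: pd.DataFrame,
                          livestock_params: pd.DataFrame) -> dict:
    """Reasonable initialization fields for the state concepts.

    Living biomass starts at 150 g/m², standing dead at 50, litter at 100;
    soil water at 60% of capacity; mineral N at 5 g/m²; tissue N at the
    vegetation type's target concentration.
    """
    P = _CodeParams(vegetation_params)
    S = _species_params(livestock_params)
    shape = np.asarray(whc).shape
    agb_living = np.full(shape, 150.0)
    agb_dead = np.full(shape, 50.0)
    litter = np.full(shape, 100.0)
    conc = P("n_conc_target", np.asarray(codes))
    return {
        "moisture.soil_water": 0.6 * np.asarray(whc, dtype=float),
        "vegetation.agb_living": agb_living,
        "vegetation.agb_dead": agb_dead,
        "vegetation.litter": litter,
        "nitrogen.soil_mineral_n": np.full(shape, 5.0),
        "nitrogen.litter_organic_n": litter * 0.015,
        "nitrogen.n_living": agb_living * conc,
        "nitrogen.n_dead": agb_dead * 0.5 * conc,
        "nitrogen.reabsorption_credit": np.zeros(shape),
        "livestock.cattle.weight": np.full(shape, S["cattle"]["weight_kg"]),
        "livestock.mare.weight": np.full(shape, S["mare"]["weight_kg"]),
        "livestock.retained_n": np.zeros(shape),
    }
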