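"""Soil and plant nitrogen cycle: mineralization, uptake, reabsorption,
leaching and the nitrogen limiting factor FN.

Nitrogen is tracked in four pools (g N/m²): soil mineral N, litter organic
N, N in living above-ground biomass and N in standing dead biomass.
Mineralization is first order in litter organic N, modulated by the
temperature and moisture factors.  Plant uptake meets the demand implied by
potential growth and the target tissue N concentration, limited by the
mineral pool; the shortfall defines FN.  A fraction of senesced N is
reabsorbed into an internal plant buffer that reduces the *next* step's
demand.  Leaching removes mineral N in proportion to the drained fraction
of the water bucket.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vegetation import rescale_outflows

__all__ = [
    "NitrogenPools",
    "NitrogenFluxes",
    "mineralization",
    "plant_uptake",
    "reabsorption",
    "leaching",
    "update_nitrogen",
]


@dataclass
class NitrogenPools:
    """Nitrogen pools, g N/m²."""

    soil_mineral_n: float
    litter_organic_n: float = 0.0
    n_living: float = 0.0
    n_dead: float = 0.0

    def __post_init__(self) -> None:
        for name in ("soil_mineral_n", "litter_organic_n", "n_living", "n_dead"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self):
        return (self.soil_mineral_n + self.litter_organic_n
                + self.n_living + self.n_dead)


@dataclass
class NitrogenFluxes:
    """Daily nitrogen fluxes, g N/m²/day."""

    mineralization: float = 0.0
    uptake: float = 0.0
    reabsorption: float = 0.0
    leaching: float = 0.0
    excreta_solid: float = 0.0
    excreta_urine: float = 0.0
    fertilization: float = 0.0
    litterfall_n: float = 0.0
    senesced_n_to_dead: float = 0.0
    ingested_living_n: float = 0.0
    ingested_dead_n: float = 0.0


def mineralization(litter_organic_n, k_min, ft, fh):
    """First-order mineralization of litter organic N, g N/m²/day.

    flux = litter N · k_min · FT · FH — frozen or dry soil mineralizes
    nothing.
    """
    out = (np.asarray(litter_organic_n, dtype=float) * np.asarray(k_min)
           * np.asarray(ft) * np.asarray(fh))
    return out if out.ndim else float(out)


def plant_uptake(growth_potential, n_conc_target, soil_mineral_n,
                 reabsorption_credit=0.0):
    """Uptake of mineral N to support growth, and the FN limiting factor.

    Demand = potential growth × target tissue N concentration.  An internal
    reabsorption credit (N recovered from senescing tissue on previous days)
    is spent first; the residual demand draws on the soil mineral pool.
    FN is the fraction of demand that could be met (1 when demand is zero).

    Returns ``(uptake, fn, credit_used)``.
    """
    demand = np.asarray(growth_potential, dtype=float) * np.asarray(n_conc_target)
    credit_used = np.minimum(np.asarray(reabsorption_credit, dtype=float), demand)
    residual = demand - credit_used
    uptake = np.minimum(residual, np.asarray(soil_mineral_n, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        fn = np.where(demand > 0, (credit_used + uptake) / np.where(demand > 0, demand, 1.0), 1.0)
    if demand.ndim:
        return uptake, fn, credit_used
    return float(uptake), float(fn), float(credit_used)


def reabsorption(senescence_flux, n_conc_living, reabs_fraction):
    """Partition the N in senescing tissue.

    Returns ``(n_to_dead, n_reabsorbed)``: the senesced N not recovered
    moves with the tissue to the standing-dead pool; the recovered part
    credits the plant's internal N budget for the next step's demand.
    """
    n_senesced = np.asarray(senescence_flux, dtype=float) * np.asarray(n_conc_living)
    reabsorbed = n_senesced * np.asarray(reabs_fraction)
    to_dead = n_senesced - reabsorbed
    if n_senesced.ndim:
        return to_dead, reabsorbed
    return float(to_dead), float(reabsorbed)


def leaching(soil_mineral_n, drainage, whc):
    """Drainage-proportional leaching: pool × min(1, drainage/whc)."""
    frac = np.minimum(1.0, np.asarray(drainage, dtype=float) / np.asarray(whc))
    out = np.asarray(soil_mineral_n, dtype=float) * frac
    return out if out.ndim else float(out)


def update_nitrogen(pools: NitrogenPools, fluxes: NitrogenFluxes):
    """Advance the nitrogen pools one day (explicit Euler, Δt = 1 day).

    Pool equations: mineral N gains mineralization, urine and fertilization
    and loses uptake and leaching; litter organic N gains litterfall N and
    solid manure N and loses mineralization; living-biomass N gains uptake
    and reabsorbed N and loses senesced and ingested N; standing-dead N
    gains the unreabsorbed senesced N and loses litterfall and ingested N.
    Outflows that would drive a pool negative are proportionally rescaled.
    Returns ``(new_pools, realised)`` with the realised flux dict.
    """
    up, lch = rescale_outflows(
        pools.soil_mineral_n,
        fluxes.mineralization + fluxes.excreta_urine + fluxes.fertilization,
        [fluxes.uptake, fluxes.leaching])
    (mnz,) = rescale_outflows(
        pools.litter_organic_n,
        fluxes.litterfall_n + fluxes.excreta_solid,
        [fluxes.mineralization])

    sen_raw = fluxes.senesced_n_to_dead + fluxes.reabsorption
    sen_tot, ing_l = rescale_outflows(pools.n_living, up,
                                      [sen_raw, fluxes.ingested_living_n])
    # keep the reabsorbed/to-dead split proportional under any rescaling
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(np.asarray(sen_raw) > 0,
                         np.asarray(fluxes.senesced_n_to_dead, dtype=float)
                         / np.where(np.asarray(sen_raw) > 0, sen_raw, 1.0),
                         0.0)
    to_dead = sen_tot * share
    reab = sen_tot - to_dead
    lfn, ing_d = rescale_outflows(pools.n_dead, to_dead,
                                  [fluxes.litterfall_n, fluxes.ingested_dead_n])

    new = NitrogenPools(
        soil_mineral_n=np.maximum(0.0, pools.soil_mineral_n + mnz
                                  + fluxes.excreta_urine + fluxes.fertilization
                                  - up - lch),
        litter_organic_n=np.maximum(0.0, pools.litter_organic_n + lfn
                                    + fluxes.excreta_solid - mnz),
        n_living=np.maximum(0.0, pools.n_living + up + reab - sen_tot - ing_l),
        n_dead=np.maximum(0.0, pools.n_dead + to_dead - lfn - ing_d),
    )
    realised = {
        "uptake": up, "leaching": lch, "mineralization": mnz,
        "senesced_n_to_dead": to_dead, "reabsorbed": reab,
        "ingested_living_n": ing_l, "litterfall_n": lfn,
        "ingested_dead_n": ing_d,
    }
    return new, realised
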