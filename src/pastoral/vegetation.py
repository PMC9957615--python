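"""Vegetation life cycle: growth, senescence, litterfall and harvest.

Above-ground biomass is tracked in three pools (g dry matter per m²):
living, standing dead, and litter.  Potential growth is the vegetation
type's maximum daily growth ``xf`` scaled by the combined abiotic factor
FTRH and the phenological activity ph; actual growth additionally applies
the nitrogen factor FN.  Livestock influence enters as the ingestion flux
removed from the pools, not as a growth-rate modifier.

All flux functions are vectorised over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VegetationType",
    "VegetationState",
    "GrowthFluxes",
    "potential_growth",
    "actual_growth",
    "senescence",
    "litterfall",
    "apply_harvest",
    "update_vegetation",
    "rescale_outflows",
]


@dataclass(frozen=True)
class VegetationType:
    """Life-cycle parameters of one vegetation type (by integer code)."""

    code: int
    xf: float                 # maximum daily growth, g/m²/day
    senescence_rate: float    # 1/day
    litterfall_rate: float    # 1/day
    n_conc_target: float      # g N per g biomass
    digestibility: float      # fraction of ingested matter digested
    palatability: float       # fraction of standing biomass available to graze

    def __post_init__(self) -> None:
        if self.xf <= 0:
            raise ValueError("xf must be positive")
        for name in ("senescence_rate", "litterfall_rate", "digestibility",
                     "palatability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_conc_target < 0:
            raise ValueError("n_conc_target must be non-negative")


@dataclass
class VegetationState:
    """Above-ground biomass pools, g/m²."""

    agb_living: float
    agb_dead: float = 0.0
    litter: float = 0.0

    def __post_init__(self) -> None:
        for name in ("agb_living", "agb_dead", "litter"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self):
        return self.agb_living + self.agb_dead + self.litter


@dataclass
class GrowthFluxes:
    """Daily biomass fluxes, g/m²/day."""

    potential_growth: float = 0.0
    actual_growth: float = 0.0
    senescence: float = 0.0
    litterfall: float = 0.0
    harvest: float = 0.0


def potential_growth(xf, ftrh, ph):
    """Potential daily growth = xf · FTRH · ph (g/m²/day)."""
    out = np.asarray(xf, dtype=float) * np.asarray(ftrh) * np.asarray(ph)
    return out if out.ndim else float(out)


def actual_growth(potential, fn):
    """Actual daily growth = potential · FN.

    Livestock influence is not applied here; it acts as the ingestion flux
    on the biomass pool.
    """
    out = np.asarray(potential, dtype=float) * np.asarray(fn)
    return out if out.ndim else float(out)


def senescence(agb_living, rate, ph):
    """Senescence flux = living biomass · rate · (1 − ph).

    Senescence peaks when phenological activity is low (dormancy) and
    vanishes for a fully active canopy.
    """
    out = np.asarray(agb_living, dtype=float) * np.asarray(rate) * (1.0 - np.asarray(ph))
    return out if out.ndim else float(out)


def litterfall(agb_dead, rate):
    """Litterfall flux = standing dead · rate."""
    out = np.asarray(agb_dead, dtype=float) * np.asarray(rate)
    return out if out.ndim else float(out)


def apply_harvest(state: VegetationState, fraction: float):
    """Remove a fraction of living biomass; returns (new_state, harvested flux)."""
    if not 0 <= fraction <= 1:
        raise ValueError("harvest fraction must lie in [0, 1]")
    removed = state.agb_living * fraction
    new = VegetationState(
        agb_living=state.agb_living - removed,
        agb_dead=state.agb_dead,
        litter=state.litter,
    )
    return new, removed


def rescale_outflows(pool, inflow, outflows):
    """Proportionally rescale outflows so ``pool + inflow − Σout ≥ 0``.

    Returns the list of realised outflows.  When the demanded outflows fit,
    they are returned unchanged; otherwise each is scaled by the same factor
    so the pool is drawn exactly to zero and mass balance still closes.
    Vectorised over arrays.
    """
    pool = np.asarray(pool, dtype=float)
    total = sum(np.asarray(o, dtype=float) for o in outflows)
    available = pool + np.asarray(inflow, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        scale = np.where(total > available, available / np.where(total > 0, total, 1.0), 1.0)
    scale = np.clip(scale, 0.0, 1.0)
    out = [np.asarray(o, dtype=float) * scale for o in outflows]
    if pool.ndim == 0:
        return [float(o) for o in out]
    return out


def update_vegetation(state: VegetationState, fluxes: GrowthFluxes,
                      ingestion_living=0.0, ingestion_dead=0.0,
                      litter_decomposition=0.0):
    """Advance the biomass pools one day (explicit Euler, Δt = 1 day).

    Outgoing fluxes that would drive a pool negative are proportionally
    rescaled (see :func:`rescale_outflows`).  Returns
    ``(new_state, realised)`` where ``realised`` is a dict of the realised
    fluxes after any rescaling.
    """
    sen, harv, ing_l = rescale_outflows(
        state.agb_living, fluxes.actual_growth,
        [fluxes.senescence, fluxes.harvest, ingestion_living])
    lf, ing_d = rescale_outflows(state.agb_dead, sen,
                                 [fluxes.litterfall, ingestion_dead])
    (dec,) = rescale_outflows(state.litter, lf, [litter_decomposition])

    new = VegetationState(
        agb_living=max(0.0, state.agb_living + fluxes.actual_growth - sen - harv - ing_l),
        agb_dead=max(0.0, state.agb_dead + sen - lf - ing_d),
        litter=max(0.0, state.litter + lf - dec),
    )
    realised = {
        "senescence": sen, "harvest": harv, "ingestion_living": ing_l,
        "litterfall": lf, "ingestion_dead": ing_d, "decomposition": dec,
    }
    return new, realised
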