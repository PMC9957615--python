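"""Climate limiting factors: temperature, radiation and soil moisture.

Potential pasture growth is throttled by dimensionless limiting factors in
[0, 1], one per abiotic constraint:

* FT — temperature: a trapezoid that is 0 at/below the base temperature,
  rises linearly to 1 over the optimal plateau and falls back to 0 at the
  maximum temperature.
* FR — solar radiation: Michaelis–Menten saturation of the radiation that
  actually reaches the (possibly overstoried) canopy.
* FH — soil moisture: linear in relative soil water content below a critical
  fraction of the water-holding capacity, 1 above it.

The combined abiotic factor FTRH = FT·FR·FH multiplies the vegetation
type's maximum growth rate; nitrogen limitation (FN) is applied separately
at actual growth.  Soil water itself follows a single-bucket balance with
drainage overflow.

All functions are vectorised: scalars or numpy arrays may be passed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClimateDay",
    "SoilWaterState",
    "VegetationClimateParams",
    "LimitingFactors",
    "temperature_factor",
    "soil_water_step",
    "moisture_factor",
    "radiation_over_vegetation",
    "radiation_factor",
    "phenology_activity",
    "combine_limiting",
    "trapezoid_calendar",
    "UNDERSTORY_RADIATION_FACTOR",
]

#: Fraction of incident radiation reaching an understory beneath a distinct
#: overstory canopy.
UNDERSTORY_RADIATION_FACTOR = 0.2


@dataclass(frozen=True)
class ClimateDay:
    """One day of climate forcing."""

    tmean: float      # °C
    precip: float     # mm/day
    rg: float         # incident solar radiation, MJ/m²/day
    pet: float = None  # type: ignore[assignment]  # mm/day; derived if absent

    def __post_init__(self) -> None:
        if self.precip < 0:
            raise ValueError("precip must be non-negative")
        if self.rg < 0:
            raise ValueError("rg must be non-negative")
        if self.pet is None:
            # energy-limited proxy: ~0.2 mm evaporative demand per MJ/m²
            object.__setattr__(self, "pet", 0.2 * self.rg)
        if self.pet < 0:
            raise ValueError("pet must be non-negative")


@dataclass
class SoilWaterState:
    """Plant-available soil water in a single bucket of capacity ``whc``."""

    water: float  # mm
    whc: float    # mm

    def __post_init__(self) -> None:
        if self.whc <= 0:
            raise ValueError("whc must be positive")
        if not 0 <= self.water <= self.whc:
            raise ValueError("water must lie in [0, whc]")


@dataclass(frozen=True)
class VegetationClimateParams:
    """Climate-response parameters of one vegetation type."""

    t_base: float
    t_opt_lo: float
    t_opt_hi: float
    t_max: float
    rg_half: float          # MJ/m²/day at which FR = 0.5
    w_crit: float           # fraction of whc below which moisture limits
    phenology_calendar: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (self.t_base < self.t_opt_lo <= self.t_opt_hi < self.t_max):
            raise ValueError("require t_base < t_opt_lo <= t_opt_hi < t_max")
        if self.rg_half <= 0:
            raise ValueError("rg_half must be positive")
        if not 0 < self.w_crit <= 1:
            raise ValueError("w_crit must lie in (0, 1]")
        cal = self.phenology_calendar
        if cal is None:
            cal = np.ones(366)
        cal = np.asarray(cal, dtype=float)
        if cal.shape != (366,):
            raise ValueError("phenology_calendar must have 366 entries")
        if cal.min() < 0 or cal.max() > 1:
            raise ValueError("phenology_calendar values must lie in [0, 1]")
        object.__setattr__(self, "phenology_calendar", cal)


@dataclass(frozen=True)
class LimitingFactors:
    """The per-cell limiting factors for one day."""

    FT: float
    FR: float
    FH: float
    FN: float
    FTRH: float


def temperature_factor(tmean, params: VegetationClimateParams):
    """Trapezoidal temperature limiting factor FT in [0, 1]."""
    t = np.asarray(tmean, dtype=float)
    up = (t - params.t_base) / (params.t_opt_lo - params.t_base)
    if params.t_max > params.t_opt_hi:
        down = (params.t_max - t) / (params.t_max - params.t_opt_hi)
    else:  # unreachable given validation; kept for clarity
        down = np.ones_like(t)
    ft = np.clip(np.minimum(up, down), 0.0, 1.0)
    return ft if ft.ndim else float(ft)


def soil_water_step(state: SoilWaterState, day: ClimateDay,
                    w_crit: float = 1.0):
    """Advance the soil-water bucket one day.

    Actual evapotranspiration is demand (pet) scaled by the moisture factor
    at the start-of-day water content, never exceeding the available water.
    Overflow beyond capacity leaves as drainage.  The balance closes exactly:
    ``precip == Δwater + actual_et + drainage``.

    Returns ``(new_state, drainage_mm, actual_et_mm)``.
    """
    fh = moisture_factor(state, w_crit)
    aet = min(day.pet * fh, state.water + day.precip)
    surplus = state.water + day.precip - aet
    drainage = max(0.0, surplus - state.whc)
    new_water = state.water + day.precip - aet - drainage
    return SoilWaterState(water=new_water, whc=state.whc), drainage, aet


def moisture_factor(state: SoilWaterState | float, w_crit: float,
                    whc: float | None = None):
    """Soil-moisture limiting factor FH = min(1, (water/whc)/w_crit)."""
    if isinstance(state, SoilWaterState):
        water, cap = state.water, state.whc
    else:
        if whc is None:
            raise TypeError("whc required when passing raw water content")
        water, cap = state, whc
    fh = np.clip((np.asarray(water, dtype=float) / cap) / w_crit, 0.0, 1.0)
    return fh if fh.ndim else float(fh)


def radiation_over_vegetation(rg, com, com2):
    """Radiation reaching the (possibly understory) vegetation, rg2.

    Where the main vegetation code equals the overstory code there is no
    overstory and the full radiation passes; otherwise only
    ``UNDERSTORY_RADIATION_FACTOR`` (0.2) of it reaches the understory.
    """
    rg = np.asarray(rg, dtype=float)
    rg2 = np.where(np.asarray(com) == np.asarray(com2),
                   rg, UNDERSTORY_RADIATION_FACTOR * rg)
    return rg2 if rg2.ndim else float(rg2)


def radiation_factor(rg2, rg_half: float):
    """Saturating radiation limiting factor FR = rg2 / (rg2 + rg_half)."""
    if rg_half <= 0:
        raise ValueError("rg_half must be positive")
    rg2 = np.asarray(rg2, dtype=float)
    fr = rg2 / (rg2 + rg_half)
    return fr if fr.ndim else float(fr)


def phenology_activity(day_of_year, calendar: np.ndarray):
    """Phenological activity ph in [0, 1] read from a per-day-of-year calendar."""
    doy = np.asarray(day_of_year)
    if np.any(doy < 1) or np.any(doy > 366):
        raise ValueError("day_of_year must lie in 1..366")
    cal = np.asarray(calendar, dtype=float)
    ph = cal[doy - 1]
    return ph if ph.ndim else float(ph)


def combine_limiting(ft, fr, fh):
    """Combined abiotic factor FTRH = FT·FR·FH (product composition)."""
    ftrh = np.asarray(ft, dtype=float) * np.asarray(fr) * np.asarray(fh)
    return ftrh if ftrh.ndim else float(ftrh)


def trapezoid_calendar(d_start: int, d_full_lo: int, d_full_hi: int,
                       d_end: int) -> np.ndarray:
    """A 366-entry phenology calendar: 0 outside the season, ramping linearly
    to a plateau of 1 between ``d_full_lo`` and ``d_full_hi``."""
    if not (1 <= d_start <= d_full_lo <= d_full_hi <= d_end <= 366):
        raise ValueError("require 1 <= d_start <= d_full_lo <= d_full_hi <= d_end <= 366")
    doy = np.arange(1, 367, dtype=float)
    up = np.ones_like(doy) if d_full_lo == d_start else (doy - d_start) / (d_full_lo - d_start)
    down = np.ones_like(doy) if d_end == d_full_hi else (d_end - doy) / (d_end - d_full_hi)
    return np.clip(np.minimum(up, down), 0.0, 1.0)
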