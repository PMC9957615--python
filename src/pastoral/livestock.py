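"""Livestock grazing: intake, digestion, weight change and excretion.

Cattle and mares graze the palatable fraction of standing biomass.  Demand
per cell is density × per-animal maximum intake × slope accessibility; when
the summed demand of all groups exceeds supply, the supply is shared in
proportion to demand (competition), living biomass being consumed before
standing dead.  Energy is proxied by digestible dry matter: daily weight
change is a linear balance of digestible intake against a
weight-proportional maintenance requirement, so weight loss is possible.
Ingested nitrogen not retained by the animal returns as solid manure and
urine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LivestockGroup",
    "IntakeResult",
    "DEFAULT_SLOPE_THRESHOLDS",
    "accessibility",
    "ingestion",
    "digestion",
    "mass_change",
    "excretion",
    "n_in_biomass_from_solid_manure",
]

#: (s0, s1) slope thresholds in degrees: accessibility is 1 at slope <= s0 and
#: declines linearly to 0 at slope >= s1.  Cattle thresholds lie strictly
#: inside the mares', so cattle accessibility <= mare accessibility everywhere.
DEFAULT_SLOPE_THRESHOLDS = {"cattle": (5.0, 25.0), "mare": (10.0, 35.0)}


@dataclass(frozen=True)
class LivestockGroup:
    """One herd of a single species with shared parameters."""

    id: str
    species: str                  # "cattle" | "mare"
    mean_weight: float            # kg
    intake_max: float             # g biomass per animal per day
    maintenance_coeff: float      # g biomass-equivalent per kg per day
    conversion_eff: float         # kg gain per g digestible intake
    n_retention: float            # fraction of ingested N retained
    solid_fraction: float         # fraction of excreted N in solid manure

    def __post_init__(self) -> None:
        if self.species not in ("cattle", "mare"):
            raise ValueError("species must be 'cattle' or 'mare'")
        if self.intake_max <= 0 or self.mean_weight <= 0:
            raise ValueError("intake_max and mean_weight must be positive")
        for name in ("n_retention", "solid_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class IntakeResult:
    """Realised grazing intake of one group on one cell."""

    intake_living: float   # g/m²/day
    intake_dead: float     # g/m²/day
    per_animal: float      # g/animal/day
    satisfaction: float    # fraction of demand met

    @property
    def total(self) -> float:
        return self.intake_living + self.intake_dead


def accessibility(slope, species: str,
                  thresholds: dict[str, tuple[float, float]] | None = None):
    """Slope accessibility in [0, 1] for a species.

    Linear decline from 1 at slope <= s0 to 0 at slope >= s1.  Cattle are
    more slope-restricted than mares (their thresholds are lower), so at any
    slope cattle accessibility <= mare accessibility.
    """
    thr = thresholds or DEFAULT_SLOPE_THRESHOLDS
    try:
        s0, s1 = thr[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}") from None
    s = np.asarray(slope, dtype=float)
    if np.any(s < 0):
        raise ValueError("slope must be non-negative")
    a = np.clip((s1 - s) / (s1 - s0), 0.0, 1.0)
    return a if a.ndim else float(a)


def ingestion(supply_living, supply_dead, demands):
    """Ration the palatable supply among competing demands.

    ``supply_living``/``supply_dead`` are palatable biomass (g/m²);
    ``demands`` is a sequence of per-group demands (g/m²/day).  When total
    demand exceeds supply, the supply is shared proportionally to demand so
    every group reaches the same satisfaction.  Living biomass is consumed
    preferentially; each group's intake is split in the common
    living/dead ratio.  Returns a list of ``(intake_living, intake_dead,
    satisfaction)`` triples, vectorised over cells.
    """
    sl = np.asarray(supply_living, dtype=float)
    sd = np.asarray(supply_dead, dtype=float)
    demands = [np.asarray(d, dtype=float) for d in demands]
    supply = sl + sd
    total_demand = sum(demands) if demands else np.zeros_like(supply)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ration = np.where(total_demand > supply,
                          supply / np.where(total_demand > 0, total_demand, 1.0),
                          1.0)
    total_intake = np.minimum(total_demand, supply)
    with np.errstate(divide="ignore", invalid="ignore"):
        living_frac = np.where(
            total_intake > 0,
            np.minimum(total_intake, sl) / np.where(total_intake > 0, total_intake, 1.0),
            1.0,
        )
    out = []
    for d in demands:
        intake = d * ration
        out.append((intake * living_frac, intake * (1.0 - living_frac), ration))
    return out


def digestion(intake, digestibility):
    """Split intake into digestible and indigestible parts."""
    intake = np.asarray(intake, dtype=float)
    dig = np.asarray(digestibility, dtype=float)
    if np.any(dig < 0) or np.any(dig > 1):
        raise ValueError("digestibility must lie in [0, 1]")
    digestible = intake * dig
    indigestible = intake - digestible
    if digestible.ndim:
        return digestible, indigestible
    return float(digestible), float(indigestible)


def mass_change(digestible, weight, maintenance_coeff, conversion_eff):
    """Daily weight change, kg/animal/day.

    Δw = conversion_eff · (digestible − maintenance_coeff · weight).
    Negative when digestible intake falls short of maintenance.
    """
    dw = np.asarray(conversion_eff, dtype=float) * (
        np.asarray(digestible, dtype=float)
        - np.asarray(maintenance_coeff) * np.asarray(weight)
    )
    return dw if dw.ndim else float(dw)


def excretion(intake_n, n_retention, solid_fraction):
    """Partition ingested N into retained, solid manure and urine.

    Returns ``(solid_n, urine_n, retained_n)``; the three sum exactly to the
    ingested N.
    """
    intake_n = np.asarray(intake_n, dtype=float)
    excreted = intake_n * (1.0 - n_retention)
    solid = excreted * solid_fraction
    urine = excreted - solid
    retained = intake_n - excreted
    if intake_n.ndim:
        return solid, urine, retained
    return float(solid), float(urine), float(retained)


def n_in_biomass_from_solid_manure(intake_living, prop_living_in_digestion,
                                   prop_n_living):
    """Nitrogen in living above-ground biomass routed through solid manure.

    The showcase cross-namespace composition: living-biomass intake × the
    proportion of living matter in digestion × the N proportion of living
    biomass.  Identical whether invoked standalone or inside a full
    dataflow.
    """
    out = (np.asarray(intake_living, dtype=float)
           * np.asarray(prop_living_in_digestion)
           * np.asarray(prop_n_living))
    return out if out.ndim else float(out)
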