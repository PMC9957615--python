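"""Minimal unit handling for raster quantities.

Every quantity moved between component models carries a :class:`UnitSpec`.
Each spec names a physical dimension and a scale factor to that dimension's
canonical unit, so conversion is a single multiply and dimension mismatches
are hard errors rather than silent unit bugs.

Canonical units per dimension: mass·area⁻¹ → g/m²; mass·area⁻¹·time⁻¹ →
g/m²/day; temperature → °C; length → mm (water depths); energy·area⁻¹·time⁻¹
→ MJ/m²/day; mass → g; dimensionless → 1.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["UnitSpec", "UnitError", "unit", "convert_units", "DIMENSIONLESS"]


class UnitError(ValueError):
    """Raised when converting between incompatible dimensions."""


@dataclass(frozen=True)
class UnitSpec:
    """A unit: its dimension and scale to the dimension's canonical unit."""

    name: str
    dimension: str
    scale_to_canonical: float

    def __post_init__(self) -> None:
        if self.scale_to_canonical <= 0:
            raise ValueError("scale_to_canonical must be positive")


_REGISTRY: dict[str, UnitSpec] = {}


def _register(name: str, dimension: str, scale: float) -> UnitSpec:
    spec = UnitSpec(name, dimension, scale)
    _REGISTRY[name] = spec
    return spec


DIMENSIONLESS = _register("1", "dimensionless", 1.0)
_register("fraction", "dimensionless", 1.0)

_register("g/m^2", "mass_per_area", 1.0)
_register("kg/ha", "mass_per_area", 0.1)       # 1000 g / 10000 m^2
_register("t/ha", "mass_per_area", 100.0)      # 1e6 g / 1e4 m^2

_register("g/m^2/day", "mass_per_area_per_time", 1.0)
_register("kg/ha/day", "mass_per_area_per_time", 0.1)

_register("degC", "temperature", 1.0)

_register("mm", "length", 1.0)
_register("mm/day", "length", 1.0)  # water-depth rate; shares the mm scale
_register("cm", "length", 10.0)
_register("m", "length", 1000.0)

_register("MJ/m^2/day", "energy_flux", 1.0)

_register("g", "mass", 1.0)
_register("kg", "mass", 1000.0)

_register("kg/day", "mass", 1000.0)
_register("g/animal/day", "mass", 1.0)

_register("deg", "angle", 1.0)
_register("animals/cell", "count_density", 1.0)
_register("1/day", "rate", 1.0)


def unit(name: str) -> UnitSpec:
    """Look up a unit by its string name (e.g. ``"kg/ha"``)."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnitError(f"unknown unit {name!r}") from None


def convert_units(value, from_unit: UnitSpec | str, to_unit: UnitSpec | str):
    """Convert ``value`` between two units of the same dimension.

    Accepts scalars or numpy arrays. Raises :class:`UnitError` when the
    dimensions differ, naming both.
    """
    f = unit(from_unit) if isinstance(from_unit, str) else from_unit
    t = unit(to_unit) if isinstance(to_unit, str) else to_unit
    if f.dimension != t.dimension:
        raise UnitError(
            f"cannot convert {f.name!r} ({f.dimension}) to {t.name!r} ({t.dimension})"
        )
    return value * (f.scale_to_canonical / t.scale_to_canonical)
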