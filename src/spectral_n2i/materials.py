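"""Material registry: formulas, densities, and mass-attenuation lookup.

Densities are nominal room-temperature values (g/cm^3) as tabulated in the
common public chemistry databases; olive oil is modelled as triolein, air as
the standard dry-air mixture.  Lookup accepts either a registered common
name ("water", "olive oil"), an element symbol ("Al", "I"), or a chemical
formula ("C3H6O").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attenuation import (
    ATOMIC_MASS,
    UnknownMaterialError,
    compound_mass_attenuation,
    element_mass_attenuation,
    mass_fractions,
)

__all__ = ["Material", "MATERIALS", "resolve_material", "get_mass_attenuation"]


@dataclass(frozen=True)
class Material:
    name: str
    density: float  # g/cm^3
    formula: str | None = None
    fractions: dict[str, float] | None = None  # explicit mass fractions

    def mass_attenuation(self, energy_kev):
        """mu/rho (cm^2/g) at the given energy (scalar or array)."""
        if self.fractions is not None:
            return compound_mass_attenuation(self.fractions, energy_kev)
        if self.formula in ATOMIC_MASS:
            return element_mass_attenuation(self.formula, energy_kev)
        return compound_mass_attenuation(mass_fractions(self.formula), energy_kev)

    def linear_attenuation(self, energy_kev, density: float | None = None):
        """mu (1/cm) = (mu/rho) * rho at the given energy."""
        rho = self.density if density is None else density
        return np.asarray(self.mass_attenuation(energy_kev)) * rho


_AIR_FRACTIONS = {"N": 0.755268, "O": 0.231781, "Ar": 0.012827, "C": 0.000124}

MATERIALS: dict[str, Material] = {
    m.name: m
    for m in [
        Material("water", 0.997, "H2O"),
        Material("olive oil", 0.911, "C57H104O6"),  # triolein surrogate
        Material("nitromethane", 1.1371, "CH3NO2"),
        Material("acetone", 0.7845, "C3H6O"),
        Material("methanol", 0.7918, "CH4O"),
        Material("ethylenediamine", 0.899, "C2H8N2"),
        Material("aluminium", 2.699, "Al"),
        Material("nitrobenzene", 1.2037, "C6H5NO2"),
        Material("iodine", 4.933, "I"),
        Material("beryllium", 1.848, "Be"),
        Material("tungsten", 19.30, "W"),
        Material("air", 1.2047e-3, fractions=_AIR_FRACTIONS),
    ]
}


def resolve_material(identifier: str | Material) -> Material:
    """Resolve a name, element symbol or formula into a Material.

    Formula/symbol lookups get a density of NaN unless registered; callers
    that need a LAC must then supply a density explicitly.
    """
    if isinstance(identifier, Material):
        return identifier
    key = identifier.strip()
    if key.lower() in MATERIALS:
        return MATERIALS[key.lower()]
    # fall through to symbol/formula; raises UnknownMaterialError if bad
    if key in ATOMIC_MASS:
        return Material(key, float("nan"), key)
    mass_fractions(key)  # validates
    return Material(key, float("nan"), key)


def get_mass_attenuation(material: str | Material, energy_kev):
    """mu/rho (cm^2/g) for a material identifier at energy_kev (keV)."""
    return resolve_material(material).mass_attenuation(energy_kev)
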