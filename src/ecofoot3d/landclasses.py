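"""The six biologically productive land classes used in footprint accounting.

Five classes (cropland, grassland, forest, water, construction) carry both an
ecological footprint and a biocapacity.  Fossil-energy land is the notional
area needed to absorb fossil-fuel carbon emissions; no real land is set aside
for it, so its biocapacity is identically zero.
"""

from __future__ import annotations

from enum import Enum


class LandClass(str, Enum):
    CROPLAND = "cropland"
    GRASSLAND = "grassland"
    FOREST = "forest"
    WATER = "water"
    CONSTRUCTION = "construction"
    FOSSIL_ENERGY = "fossil_energy"

    @property
    def has_biocapacity(self) -> bool:
        return self is not LandClass.FOSSIL_ENERGY

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: Canonical ordering used for all tabular output.
LAND_CLASSES: tuple[LandClass, ...] = tuple(LandClass)


def parse_land_class(value: str) -> LandClass:
    """Parse a land-class token, rejecting anything outside the six classes."""
    try:
        return LandClass(value)
    except ValueError:
        valid = ", ".join(c.value for c in LandClass)
        raise ValueError(f"unknown land_class {value!r}; expected one of: {valid}") from None
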