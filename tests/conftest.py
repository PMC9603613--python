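from __future__ import annotations

import pytest

from ecofoot3d import FootprintVector, LandClass
from ecofoot3d.landclasses import LAND_CLASSES

#: classes with real biocapacity, in canonical order
BIO_CLASSES = [lc for lc in LAND_CLASSES if lc.has_biocapacity]


def make_fv(ef, bc, region="R", year=2011) -> FootprintVector:
    """Build a FootprintVector from parallel EF/BC lists.

    Values are assigned to the biocapacity-bearing classes in canonical
    order, so fossil-energy land (BC must be 0) is only included when the
    caller passes six values.
    """
    classes = LAND_CLASSES if len(ef) == 6 else BIO_CLASSES[: len(ef)]
    return FootprintVector(
        region=region,
        year=year,
        ef=dict(zip(classes, map(float, ef))),
        bc=dict(zip(classes, map(float, bc))),
    )


@pytest.fixture
def deficit_fv() -> FootprintVector:
    """Two-class vector with every class in deficit (depth 2, size 2)."""
    return make_fv([2.0, 2.0], [1.0, 1.0])


@pytest.fixture
def mixed_fv() -> FootprintVector:
    """Six-class vector mixing surplus, deficit, and fossil-energy demand."""
    return FootprintVector(
        region="R",
        year=2015,
        ef={
            LandClass.CROPLAND: 0.30,
            LandClass.GRASSLAND: 0.40,
            LandClass.FOREST: 0.10,
            LandClass.WATER: 0.05,
            LandClass.CONSTRUCTION: 0.15,
            LandClass.FOSSIL_ENERGY: 0.60,
        },
        bc={
            LandClass.CROPLAND: 0.20,
            LandClass.GRASSLAND: 0.60,
            LandClass.FOREST: 0.20,
            LandClass.WATER: 0.10,
            LandClass.CONSTRUCTION: 0.10,
            LandClass.FOSSIL_ENERGY: 0.0,
        },
    )
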