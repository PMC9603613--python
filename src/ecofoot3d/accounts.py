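"""Natural-capital accounting: consumption and land area to per-capita EF/BC.

The classical ecological-footprint accounts convert item-level consumption
into demand for bioproductive area and regional land endowment into supply:

    EF_i = eqf_i * sum_j(quantity_j / world_yield_j) / population
    BC_i = area_i * yield_factor_i * eqf_i * (1 - deduction) / population

where ``eqf`` (equivalence factor) converts a land class to world-average
bioproductive hectares, the yield factor converts local to world-average
productivity, and the optional biodiversity deduction reserves a fraction of
biocapacity for wild species (conventionally 12%).  All areas are in hm²
(hectares) and per-capita results in hm²/person.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .landclasses import LAND_CLASSES, LandClass

#: Conventional fraction of biocapacity set aside for biodiversity.
DEFAULT_BIODIVERSITY_DEDUCTION = 0.12

# Equivalence factors (WWF Living Planet Report) and China NPP-based yield
# factors; the standard table for Chinese provincial accounts.
_DEFAULT_EQUIVALENCE = {
    LandClass.CROPLAND: 2.21,
    LandClass.GRASSLAND: 0.49,
    LandClass.FOREST: 1.34,
    LandClass.WATER: 0.36,
    LandClass.CONSTRUCTION: 2.21,
    LandClass.FOSSIL_ENERGY: 1.34,
}
_DEFAULT_YIELD = {
    LandClass.CROPLAND: 0.46,
    LandClass.GRASSLAND: 1.13,
    LandClass.FOREST: 0.50,
    LandClass.WATER: 1.13,
    LandClass.CONSTRUCTION: 0.19,
    LandClass.FOSSIL_ENERGY: 0.00,
}


@dataclass(frozen=True)
class ConsumptionRecord:
    """One consumed item for one region-year, with its world-average yield."""

    region: str
    year: int
    item: str
    land_class: LandClass
    quantity: float  # t or GJ per year
    global_avg_yield: float  # t/hm² or GJ/hm²

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError(f"quantity must be >= 0, got {self.quantity} for {self.item!r}")
        if self.global_avg_yield <= 0:
            raise ValueError(
                f"global_avg_yield must be > 0, got {self.global_avg_yield} for {self.item!r}"
            )


@dataclass(frozen=True)
class FactorTable:
    """Equivalence and yield factors per land class (dimensionless)."""

    equivalence: dict[LandClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_EQUIVALENCE)
    )
    yield_: dict[LandClass, float] = field(default_factory=lambda: dict(_DEFAULT_YIELD))

    def __post_init__(self) -> None:
        for lc in LAND_CLASSES:
            if lc not in self.equivalence or lc not in self.yield_:
                raise ValueError(f"factor table missing land class {lc.value!r}")
            if self.equivalence[lc] <= 0:
                raise ValueError(f"equivalence factor for {lc.value!r} must be > 0")
            if self.yield_[lc] < 0:
                raise ValueError(f"yield factor for {lc.value!r} must be >= 0")
        if self.yield_[LandClass.FOSSIL_ENERGY] != 0:
            raise ValueError("fossil_energy yield factor must be 0 (no real biocapacity)")


@dataclass(frozen=True)
class RegionYearContext:
    """Population and land endowment for one region-year."""

    region: str
    year: int
    population: float  # persons
    area_by_class: dict[LandClass, float]  # hm²

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError(
                f"population must be > 0 for {self.region} {self.year}, got {self.population}"
            )
        for lc, area in self.area_by_class.items():
            if area < 0:
                raise ValueError(f"area for {lc.value!r} must be >= 0 in {self.region} {self.year}")


@dataclass(frozen=True)
class FootprintVector:
    """Per-capita EF and BC by land class for one region-year (hm²/person)."""

    region: str
    year: int
    ef: dict[LandClass, float]
    bc: dict[LandClass, float]

    def __post_init__(self) -> None:
        for m in (self.ef, self.bc):
            for lc, v in m.items():
                if v < 0 or math.isnan(v):
                    raise ValueError(f"negative/NaN entry for {lc.value!r} in {self.region} {self.year}")
        if self.bc.get(LandClass.FOSSIL_ENERGY, 0.0) != 0.0:
            raise ValueError("fossil_energy biocapacity must be 0")

    def total_ef(self) -> float:
        return sum(self.ef.values())

    def total_bc(self) -> float:
        return sum(self.bc.values())


@dataclass(frozen=True)
class ConsumptionPanel:
    """Tidy input bundle: consumption records, contexts, and the factor table."""

    records: list[ConsumptionRecord]
    contexts: list[RegionYearContext]
    factors: FactorTable = field(default_factory=FactorTable)

    def context_for(self, region: str, year: int) -> RegionYearContext:
        for ctx in self.contexts:
            if ctx.region == region and ctx.year == year:
                return ctx
        raise KeyError(f"no population/area context for region-year ({region}, {year})")


def compute_ef_class(
    records: list[ConsumptionRecord], eqf: float, population: float
) -> float:
    """Per-capita EF of one land class from its consumption records.

    Returns ``eqf * Σ_j quantity_j / yield_j / population``; 0 for no records.
    """
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    if not records:
        return 0.0
    classes = {r.land_class for r in records}
    if len(classes) > 1:
        raise ValueError(f"records mix land classes: {sorted(c.value for c in classes)}")
    demand = sum(r.quantity / r.global_avg_yield for r in records)
    return eqf * demand / population


def compute_bc_class(
    area: float,
    yield_factor: float,
    eqf: float,
    population: float,
    biodiversity_deduction: float = DEFAULT_BIODIVERSITY_DEDUCTION,
) -> float:
    """Per-capita biocapacity of one land class.

    ``area * yield_factor * eqf * (1 - deduction) / population``; a land class
    with yield factor 0 (fossil-energy land) always yields 0.
    """
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    if area < 0:
        raise ValueError(f"area must be >= 0, got {area}")
    if not 0 <= biodiversity_deduction < 1:
        raise ValueError(f"biodiversity_deduction must be in [0, 1), got {biodiversity_deduction}")
    return area * yield_factor * eqf * (1.0 - biodiversity_deduction) / population


def build_footprint_panel(
    panel: ConsumptionPanel,
    biodiversity_deduction: float = DEFAULT_BIODIVERSITY_DEDUCTION,
) -> list[FootprintVector]:
    """Run the accounts for every region-year, ordered by (region, year).

    One FootprintVector is produced per context; region-years that appear in
    the consumption records but have no context raise a KeyError naming them.
    """
    keyed: dict[tuple[str, int], list[ConsumptionRecord]] = {}
    for rec in panel.records:
        keyed.setdefault((rec.region, rec.year), []).append(rec)

    have = {(c.region, c.year) for c in panel.contexts}
    missing = sorted(set(keyed) - have)
    if missing:
        raise KeyError(f"no population/area context for region-year(s): {missing}")

    out: list[FootprintVector] = []
    for ctx in sorted(panel.contexts, key=lambda c: (c.region, c.year)):
        recs = keyed.get((ctx.region, ctx.year), [])
        ef: dict[LandClass, float] = {}
        bc: dict[LandClass, float] = {}
        for lc in LAND_CLASSES:
            class_recs = [r for r in recs if r.land_class is lc]
            ef[lc] = compute_ef_class(class_recs, panel.factors.equivalence[lc], ctx.population)
            bc[lc] = compute_bc_class(
                ctx.area_by_class.get(lc, 0.0),
                panel.factors.yield_[lc],
                panel.factors.equivalence[lc],
                ctx.population,
                biodiversity_deduction,
            )
        out.append(FootprintVector(region=ctx.region, year=ctx.year, ef=ef, bc=bc))
    return out
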