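"""Statistically controlled synthetic input panels.

Real footprint accounts start from statistical-yearbook tables that are not
redistributable, so every pipeline stage here is exercised on generated
panels instead.  A scenario fixes, per region and land class, a per-capita
biocapacity trajectory and an EF/BC ratio trajectory (for fossil-energy
land, which has no biocapacity, a per-capita EF trajectory directly), plus a
population trajectory.  The generator *inverts* the accounting formulas:
quantities and areas are chosen so that, at zero noise, running the panel
through the accounts reproduces the configured per-class EF and BC exactly.

Noise, when enabled, is multiplicative log-normal with unit mean applied to
quantities only — per-capita EF stays mean-unbiased for its target, and all
series stay positive (a GM(1,1) requirement).  Areas and population are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accounts import (
    DEFAULT_BIODIVERSITY_DEDUCTION,
    ConsumptionPanel,
    ConsumptionRecord,
    FactorTable,
    FootprintVector,
    RegionYearContext,
)
from .landclasses import LAND_CLASSES, LandClass

#: World-average yields assigned to the synthetic items of a class (t/hm²).
_ITEM_YIELDS = (5.0, 10.0, 20.0)


@dataclass(frozen=True)
class ClassScenario:
    """Target trajectory for one land class in one region.

    ``bc0`` is the per-capita biocapacity in the first year (hm²/person) and
    ``ratio0`` the EF/BC ratio; both evolve multiplicatively per year.  For
    fossil-energy land set ``bc0 = 0`` and give ``ratio0`` as the per-capita
    EF itself (hm²/person).
    """

    bc0: float
    ratio0: float
    bc_growth: float = 1.0
    ratio_growth: float = 1.0

    def __post_init__(self) -> None:
        if self.bc0 < 0 or self.ratio0 <= 0:
            raise ValueError("bc0 must be >= 0 and ratio0 > 0")
        if self.bc_growth <= 0 or self.ratio_growth <= 0:
            raise ValueError("growth multipliers must be > 0")

    def targets(self, t: int) -> tuple[float, float]:
        """(EF, BC) per capita at year offset t."""
        bc = self.bc0 * self.bc_growth**t
        ratio = self.ratio0 * self.ratio_growth**t
        ef = ratio if self.bc0 == 0 else ratio * bc
        return ef, bc


@dataclass(frozen=True)
class RegionScenario:
    population0: float
    classes: dict[LandClass, ClassScenario]
    pop_growth: float = 1.0

    def __post_init__(self) -> None:
        if self.population0 <= 0 or self.pop_growth <= 0:
            raise ValueError("population0 and pop_growth must be > 0")
        missing = [lc.value for lc in LAND_CLASSES if lc not in self.classes]
        if missing:
            raise ValueError(f"scenario missing land classes: {missing}")
        fossil = self.classes[LandClass.FOSSIL_ENERGY]
        if fossil.bc0 != 0:
            raise ValueError("fossil_energy must be configured with bc0 = 0")


@dataclass(frozen=True)
class ScenarioConfig:
    regions: dict[str, RegionScenario]
    years: tuple[int, int]  # inclusive
    noise_sd: float = 0.0
    seed: int = 0
    items_per_class: int = 3
    biodiversity_deduction: float = DEFAULT_BIODIVERSITY_DEDUCTION
    factors: FactorTable = field(default_factory=FactorTable)

    def __post_init__(self) -> None:
        if self.years[1] < self.years[0]:
            raise ValueError("years must be an inclusive (start, end) range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.items_per_class < 1:
            raise ValueError("items_per_class must be >= 1")

    def year_range(self) -> range:
        return range(self.years[0], self.years[1] + 1)

    def expected_footprints(self) -> list[FootprintVector]:
        """The configured (noise-free) per-class EF/BC, ordered (region, year)."""
        out = []
        for region in sorted(self.regions):
            scen = self.regions[region]
            for t, year in enumerate(self.year_range()):
                ef = {}
                bc = {}
                for lc in LAND_CLASSES:
                    ef[lc], bc[lc] = scen.classes[lc].targets(t)
                out.append(FootprintVector(region=region, year=year, ef=ef, bc=bc))
        return out


def generate_panel(config: ScenarioConfig) -> ConsumptionPanel:
    """Generate a ConsumptionPanel realizing the configured trajectories.

    At ``noise_sd = 0`` the panel reproduces the target per-class EF and BC
    to rounding when run through the accounts.  Deterministic under a fixed
    seed.
    """
    rng = np.random.default_rng(config.seed)
    factors = config.factors
    records: list[ConsumptionRecord] = []
    contexts: list[RegionYearContext] = []
    for region in sorted(config.regions):
        scen = config.regions[region]
        for t, year in enumerate(config.year_range()):
            pop = scen.population0 * scen.pop_growth**t
            areas: dict[LandClass, float] = {}
            for lc in LAND_CLASSES:
                ef_target, bc_target = scen.classes[lc].targets(t)
                yf, eqf = factors.yield_[lc], factors.equivalence[lc]
                # invert BC = area*yf*eqf*(1-d)/pop
                if bc_target == 0 or yf == 0:
                    area = 0.0
                else:
                    area = bc_target * pop / (yf * eqf * (1.0 - config.biodiversity_deduction))
                if area < 0:
                    raise ValueError(
                        f"infeasible target: negative implied area for {region}/{lc.value}/{year}"
                    )
                areas[lc] = area
                # invert EF = eqf * Σ_j q_j/Y_j / pop, split equally across items
                demand_area = ef_target * pop / eqf
                m = config.items_per_class
                for j in range(m):
                    y = _ITEM_YIELDS[j % len(_ITEM_YIELDS)]
                    q = demand_area / m * y
                    if config.noise_sd > 0:
                        # unit-mean log-normal keeps EF unbiased and positive
                        q *= rng.lognormal(
                            mean=-0.5 * config.noise_sd**2, sigma=config.noise_sd
                        )
                    records.append(
                        ConsumptionRecord(
                            region=region,
                            year=year,
                            item=f"{lc.value}_item{j + 1}",
                            land_class=lc,
                            quantity=q,
                            global_avg_yield=y,
                        )
                    )
            contexts.append(
                RegionYearContext(region=region, year=year, population=pop, area_by_class=areas)
            )
    return ConsumptionPanel(records=records, contexts=contexts, factors=factors)


def scenario_upper_yellow_default(noise_sd: float = 0.0, seed: int = 0) -> ScenarioConfig:
    """Packaged four-region, 2011–2020 fixture.

    Emulates the qualitative structure of the upper-Yellow-River provinces:
    resource-rich/low-density regions (NMG, QH) with large biocapacity and
    low depth, dense resource-poor regions (NX, GS) where fossil-energy
    demand dominates.  At zero noise the pipeline reproduces the footprint
    depth ordering NX > GS > NMG > QH and size ordering NMG > QH > GS > NX
    in every year, with every region's comprehensive pressure index above 1.
    Magnitudes are synthetic, not calibrated to any published accounts.
    """

    def region(pop0, pg, fossil_ef, fossil_g, table):
        classes = {
            lc: ClassScenario(bc0=bc0, ratio0=r0, bc_growth=1.0, ratio_growth=rg)
            for lc, (bc0, r0, rg) in table.items()
        }
        classes[LandClass.FOSSIL_ENERGY] = ClassScenario(
            bc0=0.0, ratio0=fossil_ef, ratio_growth=fossil_g
        )
        return RegionScenario(population0=pop0, pop_growth=pg, classes=classes)

    regions = {
        # (bc0 hm²/person, EF/BC ratio, ratio growth per year)
        "QH": region(5.9e6, 1.005, 0.45, 1.030, {
            LandClass.GRASSLAND: (0.60, 0.85, 1.004),
            LandClass.FOREST: (0.25, 0.70, 1.004),
            LandClass.CROPLAND: (0.18, 1.30, 1.010),
            LandClass.WATER: (0.15, 0.50, 1.004),
            LandClass.CONSTRUCTION: (0.12, 1.20, 1.010),
        }),
        "GS": region(2.55e7, 1.002, 0.68, 1.030, {
            LandClass.GRASSLAND: (0.22, 0.90, 1.004),
            LandClass.FOREST: (0.10, 0.75, 1.004),
            LandClass.CROPLAND: (0.13, 1.80, 1.010),
            LandClass.WATER: (0.04, 0.80, 1.004),
            LandClass.CONSTRUCTION: (0.06, 1.40, 1.010),
        }),
        "NX": region(6.9e6, 1.010, 0.85, 1.030, {
            LandClass.GRASSLAND: (0.14, 0.95, 1.004),
            LandClass.FOREST: (0.06, 0.80, 1.004),
            LandClass.CROPLAND: (0.12, 2.00, 1.010),
            LandClass.WATER: (0.03, 1.20, 1.010),
            LandClass.CONSTRUCTION: (0.05, 1.50, 1.010),
        }),
        "NMG": region(2.5e7, 1.003, 1.10, 1.030, {
            LandClass.GRASSLAND: (0.85, 0.90, 1.004),
            LandClass.FOREST: (0.30, 0.80, 1.004),
            LandClass.CROPLAND: (0.35, 1.50, 1.010),
            LandClass.WATER: (0.12, 0.70, 1.004),
            LandClass.CONSTRUCTION: (0.18, 1.30, 1.010),
        }),
    }
    return ScenarioConfig(regions=regions, years=(2011, 2020), noise_sd=noise_sd, seed=seed)
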