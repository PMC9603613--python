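"""Improved three-dimensional ecological footprint: depth, size, EF3D.

The 3D model splits natural-capital use into flow occupation and stock
depletion.  Footprint depth measures how many multiples of the region's
annual flows are consumed:

    depth = 1 + Σ_i max(EF_i − BC_i, 0) / Σ_i BC_i        (depth ≥ 1)

and footprint size (breadth) is the flow capital actually occupied:

    size = Σ_i min(EF_i, BC_i)                            (0 ≤ size ≤ Σ BC_i)

EF3D = depth × size.  The improvement over the classic volumetric model is
that surpluses in one land class cannot mask deficits in another: the
per-class max/min is taken before summing.

Two companion indicators describe the flow/stock split.  The capital flow
occupancy rate γ_FLOW = size/BC × 100% applies where EF ≤ BC; the stock-flow
utilization ratio λ = (EF − BC)/BC applies where EF > BC (per class it equals
that class's depth − 1).  Regionally, γ = Σ min(EF_i, BC_i)/Σ BC_i × 100 and
λ = Σ_deficit (EF_i − BC_i) / Σ_deficit BC_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .accounts import FootprintVector
from .landclasses import LAND_CLASSES, LandClass

REGIONAL = "regional"


class UndefinedDepthError(ValueError):
    """Raised when footprint depth is undefined because total BC is zero."""


class NotApplicableError(ValueError):
    """Raised when γ_FLOW / λ is requested outside its side condition."""


@dataclass(frozen=True)
class EF3DResult:
    region: str
    year: int
    ef_depth: float
    ef_size: float
    ef_3d: float
    #: percent, only for classes with EF ≤ BC (NaN otherwise)
    gamma_flow_by_class: dict[LandClass, float]
    gamma_flow_regional: float
    #: dimensionless, only for classes with EF > BC (NaN otherwise)
    lambda_by_class: dict[LandClass, float]
    lambda_regional: float


def footprint_depth(fv: FootprintVector) -> float:
    """Regional footprint depth, ≥ 1; 1 iff no land class is in deficit."""
    total_bc = fv.total_bc()
    if total_bc <= 0:
        raise UndefinedDepthError(
            f"total biocapacity is zero for {fv.region} {fv.year}; depth undefined"
        )
    deficit = sum(max(fv.ef.get(lc, 0.0) - fv.bc.get(lc, 0.0), 0.0) for lc in fv.ef)
    return 1.0 + deficit / total_bc


def footprint_size(fv: FootprintVector) -> float:
    """Regional footprint size (breadth): flow capital actually occupied."""
    return sum(min(fv.ef.get(lc, 0.0), fv.bc.get(lc, 0.0)) for lc in fv.ef)


def footprint_3d(fv: FootprintVector) -> float:
    """Three-dimensional footprint, depth × size (hm²/person)."""
    return footprint_depth(fv) * footprint_size(fv)


def capital_flow_occupancy(fv: FootprintVector, scope: LandClass | str = REGIONAL) -> float:
    """γ_FLOW in percent.

    Class scope requires that class to be in surplus (EF ≤ BC); the regional
    value is Σ min(EF_i, BC_i) / Σ BC_i × 100 and is always defined when
    total BC > 0.
    """
    if scope == REGIONAL:
        total_bc = fv.total_bc()
        if total_bc <= 0:
            raise NotApplicableError(f"total biocapacity is zero for {fv.region} {fv.year}")
        return footprint_size(fv) / total_bc * 100.0
    lc = LandClass(scope)
    ef, bc = fv.ef.get(lc, 0.0), fv.bc.get(lc, 0.0)
    if bc <= 0 or ef > bc:
        raise NotApplicableError(
            f"{lc.value} is in deficit (EF={ef:g} > BC={bc:g}); γ_FLOW applies only where EF ≤ BC"
        )
    return ef / bc * 100.0


def stock_flow_ratio(fv: FootprintVector, scope: LandClass | str = REGIONAL) -> float:
    """λ (stock-flow utilization ratio), dimensionless.

    Class scope requires that class to be in deficit (EF > BC) and equals
    ED/BC = class depth − 1 (infinite for fossil-energy land, whose BC is 0).
    Regional scope is Σ_deficit (EF_i − BC_i) / Σ_deficit BC_i.
    """
    if scope == REGIONAL:
        num = 0.0
        den = 0.0
        for lc in fv.ef:
            ef, bc = fv.ef.get(lc, 0.0), fv.bc.get(lc, 0.0)
            if ef > bc:
                num += ef - bc
                den += bc
        if num == 0.0:
            raise NotApplicableError(
                f"no land class in deficit for {fv.region} {fv.year}; λ applies only where EF > BC"
            )
        return num / den if den > 0 else math.inf
    lc = LandClass(scope)
    ef, bc = fv.ef.get(lc, 0.0), fv.bc.get(lc, 0.0)
    if ef <= bc:
        raise NotApplicableError(
            f"{lc.value} is in surplus (EF={ef:g} ≤ BC={bc:g}); λ applies only where EF > BC"
        )
    return (ef - bc) / bc if bc > 0 else math.inf


def ef3d_result(fv: FootprintVector) -> EF3DResult:
    """All 3D-footprint indicators for one region-year; per-class values that
    fall outside their side condition are NaN."""
    depth = footprint_depth(fv)
    size = footprint_size(fv)
    gamma_c: dict[LandClass, float] = {}
    lam_c: dict[LandClass, float] = {}
    for lc in LAND_CLASSES:
        try:
            gamma_c[lc] = capital_flow_occupancy(fv, lc)
        except NotApplicableError:
            gamma_c[lc] = math.nan
        try:
            lam_c[lc] = stock_flow_ratio(fv, lc)
        except NotApplicableError:
            lam_c[lc] = math.nan
    try:
        lam_r = stock_flow_ratio(fv, REGIONAL)
    except NotApplicableError:
        lam_r = math.nan
    return EF3DResult(
        region=fv.region,
        year=fv.year,
        ef_depth=depth,
        ef_size=size,
        ef_3d=depth * size,
        gamma_flow_by_class=gamma_c,
        gamma_flow_regional=capital_flow_occupancy(fv, REGIONAL),
        lambda_by_class=lam_c,
        lambda_regional=lam_r,
    )
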