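"""Ecological-security index suite.

* EFDI — Shannon entropy of the footprint's land-class shares, −Σ p_i ln p_i
  (nats): diversity/equitability of resource demand.
* I_comprehensive — the comprehensive land pressure index; identical to
  footprint depth (EF/BC aggregated with per-class deficits only).
* ETI — ecological tension (pressure) index, ef′/ec: per-capita renewable-
  resource footprint over per-capita biocapacity, graded on the six-level
  WWF scale.
* ECC — ecological coordination coefficient, (EPI+1)/√(EPI²+1): √2 ≈ 1.414
  means supply and demand are balanced, values near 1 mean one side
  dominates.

Descriptive helpers: compound average annual growth and a Pearson
correlation matrix for index-vs-driver panels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accounts import FootprintVector
from .ef3d import footprint_depth
from .landclasses import LandClass

#: Land classes counted as "renewable" in ef′ (everything but fossil energy).
RENEWABLE_CLASSES: frozenset[LandClass] = frozenset(
    lc for lc in LandClass if lc is not LandClass.FOSSIL_ENERGY
)


@dataclass(frozen=True)
class GradeTable:
    """Six-level ecological-pressure grading.

    ``boundaries[i]`` is the lower edge of label ``labels[i+1]``; intervals
    are half-open ``[lower, upper)`` so the whole positive axis is covered.
    """

    boundaries: tuple[float, ...] = (0.5, 0.8, 1.0, 1.5, 2.0)
    labels: tuple[str, ...] = (
        "Very safe",
        "Relatively safe",
        "Slightly unsafe",
        "Moderately unsafe",
        "Highly unsafe",
        "Serious insecurity",
    )

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError("need exactly one more label than boundary")
        if list(self.boundaries) != sorted(self.boundaries):
            raise ValueError("boundaries must be increasing")


DEFAULT_GRADES = GradeTable()


@dataclass(frozen=True)
class SecurityIndices:
    region: str
    year: int
    efdi: float
    i_comprehensive: float
    eti: float
    eti_grade: str
    ecc: float


def efdi(shares) -> float:
    """Footprint diversity index: Shannon entropy of shares, in nats.

    Shares must be non-negative and sum to 1 (±1e-9); zero shares contribute
    nothing (0·ln 0 := 0).
    """
    p = np.asarray(shares, dtype=float)
    if (p < 0).any():
        raise ValueError("shares must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"shares must sum to 1 (±1e-9), got {total!r}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def efdi_from_footprint(fv: FootprintVector) -> float:
    """EFDI over the six land classes' EF shares."""
    total = fv.total_ef()
    if total <= 0:
        raise ValueError(f"total EF is zero for {fv.region} {fv.year}; shares undefined")
    return efdi([v / total for v in fv.ef.values()])


def comprehensive_pressure(fv: FootprintVector) -> float:
    """Comprehensive land pressure index; identical to footprint depth."""
    return footprint_depth(fv)


def eti(ef_renewable: float, ec: float) -> float:
    """Ecological tension index ef′/ec (ef′ excludes fossil-energy land)."""
    if ec <= 0:
        raise ValueError(f"per-capita biocapacity must be > 0, got {ec}")
    if ef_renewable < 0:
        raise ValueError("renewable footprint must be >= 0")
    return ef_renewable / ec


def eti_from_footprint(
    fv: FootprintVector, renewable_classes: frozenset[LandClass] = RENEWABLE_CLASSES
) -> float:
    ef_renew = sum(v for lc, v in fv.ef.items() if lc in renewable_classes)
    return eti(ef_renew, fv.total_bc())


def classify_eti(value: float, table: GradeTable = DEFAULT_GRADES) -> str:
    """Map a pressure-index value to its six-level grade (half-open bins)."""
    if value < 0 or math.isnan(value):
        raise ValueError(f"pressure index must be >= 0, got {value}")
    idx = int(np.searchsorted(table.boundaries, value, side="right"))
    return table.labels[idx]


def ecc(epi: float) -> float:
    """Ecological coordination coefficient (EPI+1)/√(EPI²+1).

    Strictly increasing on [0, 1], maximal (√2) at EPI = 1, strictly
    decreasing beyond; EPI = 0 gives the degenerate value exactly 1.
    """
    if epi < 0:
        raise ValueError(f"EPI must be >= 0, got {epi}")
    return (epi + 1.0) / math.sqrt(epi * epi + 1.0)


def avg_annual_growth(v_start: float, v_end: float, periods: int) -> float:
    """Compound average growth per period, (v_end/v_start)^(1/periods) − 1.

    For an annual series observed from year y0 to y1 the span is y1 − y0
    periods (a 2011→2020 series has 10 annual values but grows over 10
    compounding steps under this reporting convention).
    """
    if v_start <= 0:
        raise ValueError(f"starting value must be > 0, got {v_start}")
    if periods < 1:
        raise ValueError(f"periods must be >= 1, got {periods}")
    return (v_end / v_start) ** (1.0 / periods) - 1.0


def correlation_matrix(panel: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of a labeled panel of series.

    Requires at least 3 paired observations per pair.  Zero-variance columns
    produce NaN entries and a warning naming the column — never a silent 0.
    """
    df = panel.astype(float)
    if len(df) < 3:
        raise ValueError(f"need >= 3 observations, got {len(df)}")
    degenerate = [c for c in df.columns if df[c].nunique() <= 1]
    if degenerate:
        warnings.warn(
            f"zero-variance series {degenerate}: correlation undefined (NaN)",
            stacklevel=2,
        )
    return df.corr(method="pearson")


def security_indices(
    fv: FootprintVector,
    grade_table: GradeTable = DEFAULT_GRADES,
    renewable_classes: frozenset[LandClass] = RENEWABLE_CLASSES,
) -> SecurityIndices:
    """The full index suite for one region-year; ECC is evaluated at EPI = ETI."""
    pressure = eti_from_footprint(fv, renewable_classes)
    return SecurityIndices(
        region=fv.region,
        year=fv.year,
        efdi=efdi_from_footprint(fv),
        i_comprehensive=comprehensive_pressure(fv),
        eti=pressure,
        eti_grade=classify_eti(pressure, grade_table),
        ecc=ecc(pressure),
    )
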