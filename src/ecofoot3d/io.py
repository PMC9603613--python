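"""Validated CSV readers and writers for every pipeline schema.

All files are UTF-8, comma-separated, '.' decimal, header row required.
Floats are serialized with 6 significant digits except the index outputs,
which use 4 decimal places to match conventional reporting precision.
Schema violations raise ``SchemaError`` naming the file and column.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .accounts import (
    ConsumptionPanel,
    ConsumptionRecord,
    FactorTable,
    FootprintVector,
    RegionYearContext,
)
from .landclasses import LAND_CLASSES, LandClass, parse_land_class


class SchemaError(ValueError):
    """An input file violates its declared schema."""


_CONSUMPTION_COLS = ["region", "year", "item", "land_class", "quantity", "global_avg_yield"]
_CONTEXT_COLS = ["region", "year", "population"] + [f"{lc.value}_area" for lc in LAND_CLASSES]
_FACTOR_COLS = ["land_class", "equivalence_factor", "yield_factor"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, header row required") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_consumption_csv(path: str | Path) -> list[ConsumptionRecord]:
    df = _read_csv(path, _CONSUMPTION_COLS)
    dupes = df.duplicated(subset=["region", "year", "item"])
    if dupes.any():
        first = df.loc[dupes, ["region", "year", "item"]].iloc[0].tolist()
        raise SchemaError(f"{path}: duplicate (region, year, item) key {tuple(first)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ConsumptionRecord(
                    region=str(row["region"]),
                    year=int(row["year"]),
                    item=str(row["item"]),
                    land_class=parse_land_class(str(row["land_class"])),
                    quantity=float(row["quantity"]),
                    global_avg_yield=float(row["global_avg_yield"]),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: line {i + 2}: {exc}") from None
    return records


def read_context_csv(path: str | Path) -> list[RegionYearContext]:
    df = _read_csv(path, _CONTEXT_COLS)
    contexts = []
    for i, row in df.iterrows():
        try:
            contexts.append(
                RegionYearContext(
                    region=str(row["region"]),
                    year=int(row["year"]),
                    population=float(row["population"]),
                    area_by_class={lc: float(row[f"{lc.value}_area"]) for lc in LAND_CLASSES},
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: line {i + 2}: {exc}") from None
    return contexts


def read_factors_csv(path: str | Path) -> FactorTable:
    df = _read_csv(path, _FACTOR_COLS)
    eq: dict[LandClass, float] = {}
    yf: dict[LandClass, float] = {}
    for i, row in df.iterrows():
        try:
            lc = parse_land_class(str(row["land_class"]))
        except ValueError as exc:
            raise SchemaError(f"{path}: line {i + 2}: {exc}") from None
        eq[lc] = float(row["equivalence_factor"])
        yf[lc] = float(row["yield_factor"])
    try:
        return FactorTable(equivalence=eq, yield_=yf)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def read_panel(
    consumption: str | Path, context: str | Path, factors: str | Path
) -> ConsumptionPanel:
    return ConsumptionPanel(
        records=read_consumption_csv(consumption),
        contexts=read_context_csv(context),
        factors=read_factors_csv(factors),
    )


def _fmt(x: float, ndigits: int | None = None) -> str:
    if isinstance(x, float) and math.isnan(x):
        return ""
    if ndigits is not None:
        return f"{x:.{ndigits}f}"
    return f"{x:.6g}"


def _write(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def write_consumption_csv(records: list[ConsumptionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "region": r.region,
                "year": r.year,
                "item": r.item,
                "land_class": r.land_class.value,
                "quantity": _fmt(r.quantity),
                "global_avg_yield": _fmt(r.global_avg_yield),
            }
            for r in records
        ],
        columns=_CONSUMPTION_COLS,
    )
    _write(df, path)


def write_context_csv(contexts: list[RegionYearContext], path: str | Path) -> None:
    rows = []
    for c in contexts:
        row = {"region": c.region, "year": c.year, "population": _fmt(c.population)}
        for lc in LAND_CLASSES:
            row[f"{lc.value}_area"] = _fmt(c.area_by_class.get(lc, 0.0))
        rows.append(row)
    _write(pd.DataFrame(rows, columns=_CONTEXT_COLS), path)


def write_factors_csv(factors: FactorTable, path: str | Path) -> None:
    rows = [
        {
            "land_class": lc.value,
            "equivalence_factor": _fmt(factors.equivalence[lc]),
            "yield_factor": _fmt(factors.yield_[lc]),
        }
        for lc in LAND_CLASSES
    ]
    _write(pd.DataFrame(rows, columns=_FACTOR_COLS), path)


def write_footprints_csv(fvs: list[FootprintVector], path: str | Path) -> None:
    rows = []
    for fv in fvs:
        for lc in LAND_CLASSES:
            rows.append(
                {
                    "region": fv.region,
                    "year": fv.year,
                    "land_class": lc.value,
                    "ef_per_capita": _fmt(fv.ef.get(lc, 0.0)),
                    "bc_per_capita": _fmt(fv.bc.get(lc, 0.0)),
                }
            )
    _write(
        pd.DataFrame(rows, columns=["region", "year", "land_class", "ef_per_capita", "bc_per_capita"]),
        path,
    )


def read_footprints_csv(path: str | Path) -> list[FootprintVector]:
    df = _read_csv(path, ["region", "year", "land_class", "ef_per_capita", "bc_per_capita"])
    out = []
    for (region, year), grp in df.groupby(["region", "year"], sort=True):
        ef = {}
        bc = {}
        for _, row in grp.iterrows():
            lc = parse_land_class(str(row["land_class"]))
            ef[lc] = float(row["ef_per_capita"])
            bc[lc] = float(row["bc_per_capita"])
        out.append(FootprintVector(region=str(region), year=int(year), ef=ef, bc=bc))
    return out


def write_ef3d_csv(results, path: str | Path) -> None:
    rows = []
    for r in results:
        row = {
            "region": r.region,
            "year": r.year,
            "ef_depth": _fmt(r.ef_depth, 4),
            "ef_size": _fmt(r.ef_size, 4),
            "ef_3d": _fmt(r.ef_3d, 4),
            "gamma_flow_regional": _fmt(r.gamma_flow_regional, 4),
            "lambda_regional": _fmt(r.lambda_regional, 4),
        }
        for lc in LAND_CLASSES:
            row[f"gamma_{lc.value}"] = _fmt(r.gamma_flow_by_class[lc], 4)
            row[f"lambda_{lc.value}"] = _fmt(r.lambda_by_class[lc], 4)
        rows.append(row)
    _write(pd.DataFrame(rows), path)


def write_indices_csv(indices, path: str | Path) -> None:
    rows = [
        {
            "region": s.region,
            "year": s.year,
            "efdi": _fmt(s.efdi, 4),
            "i_comprehensive": _fmt(s.i_comprehensive, 4),
            "eti": _fmt(s.eti, 4),
            "eti_grade": s.eti_grade,
            "ecc": _fmt(s.ecc, 4),
        }
        for s in indices
    ]
    _write(pd.DataFrame(rows), path)


def write_grey_degrees_csv(results, path: str | Path) -> None:
    """``results`` is a list of (region, GreyRelationResult)."""
    rows = []
    for region, res in results:
        for label, degree in res.degrees.items():
            rows.append(
                {
                    "region": region,
                    "comparison_series": label,
                    "degree": _fmt(degree, 4),
                    "rho": _fmt(res.rho),
                }
            )
    _write(pd.DataFrame(rows, columns=["region", "comparison_series", "degree", "rho"]), path)


def write_forecast_csv(rows: list[dict], path: str | Path) -> None:
    df = pd.DataFrame(
        rows,
        columns=["region", "index", "year", "observed_or_forecast", "value", "C", "p", "grade"],
    )
    for col, nd in (("value", 4), ("C", 4), ("p", 4)):
        df[col] = df[col].map(lambda x: _fmt(float(x), nd))
    _write(df, path)


def write_correlations_csv(corr: pd.DataFrame, path: str | Path) -> None:
    out = corr.round(4)
    out.insert(0, "series", corr.index)
    _write(out, path)
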