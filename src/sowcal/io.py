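"""Readers and writers for the tabular trial formats, plus packaged fixtures.

The packaged fixtures transcribe the published composition and energy tables
of the ten-barley gestating-sow trial:

* ``barley10.csv``      — chemical composition of the ten barley samples (% DM)
* ``diets.csv``         — formulation and nutrient levels of the 11 diets
* ``diet_energy.csv``   — per-diet energy balance, RQ and DE/ME/NE
* ``barley_energy.csv`` — per-barley digestibility and DE/ME/NE
"""

from __future__ import annotations

import dataclasses
import warnings
from datetime import datetime
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Union

import pandas as pd

from .datamodel import (
    ANALYTES,
    Basis,
    ChemicalComposition,
    CollectionKind,
    CollectionRecord,
    DataQualityWarning,
    DietFormulation,
    GasExchangeRecord,
    SowPeriod,
    State,
)

PathLike = Union[str, Path]

#: case-insensitive header synonyms -> canonical analyte names
ANALYTE_SYNONYMS: Dict[str, str] = {
    "dm": "dm", "dry matter": "dm", "dm_pct": "dm",
    "ge": "gross_energy", "gross energy": "gross_energy",
    "gross_energy": "gross_energy", "ge_mj_kg": "gross_energy",
    "cp": "cp", "crude protein": "cp",
    "ndf": "ndf", "andf": "ndf", "neutral detergent fiber": "ndf",
    "adf": "adf", "acid detergent fiber": "adf",
    "ash": "ash",
    "ee": "ee", "ether extract": "ee", "fat": "ee",
    "starch": "starch",
    "idf": "idf", "insoluble dietary fiber": "idf",
    "sdf": "sdf", "soluble dietary fiber": "sdf",
    "tdf": "tdf", "total dietary fiber": "tdf",
    "ca": "ca", "calcium": "ca",
    "p": "p", "phosphorus": "p",
}

AMINO_ACIDS = (
    "lys", "met", "thr", "val", "ile", "leu", "trp", "phe", "his", "arg",
    "pro", "tyr", "ser", "gly", "asp", "ala", "cys", "glu",
)


class FormatError(ValueError):
    """The file does not match the expected tabular schema."""


def fixture_path(name: str) -> Path:
    """Absolute path of a packaged fixture CSV."""
    return Path(str(resources.files("sowcal").joinpath("data", name)))


def _canonical(column: str) -> str:
    return ANALYTE_SYNONYMS.get(column.strip().lower(), column.strip().lower())


def read_composition_table(
    path: PathLike, basis: Basis = Basis.DM
) -> List[ChemicalComposition]:
    """Read a composition CSV into :class:`ChemicalComposition` records.

    Headers are matched case-insensitively through a synonym table; unknown
    numeric columns are kept in ``extras``. Soft-invariant violations are
    reported as :class:`DataQualityWarning` naming the row, never dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    cols = {_canonical(c): c for c in df.columns}
    if "sample_id" not in cols:
        raise FormatError(f"{path}: missing mandatory column 'sample_id'")
    if "dm" not in cols:
        raise FormatError(f"{path}: missing mandatory column 'dm'")

    records: List[ChemicalComposition] = []
    for idx, row in df.iterrows():
        sample_id = str(row[cols["sample_id"]])
        kwargs: Dict[str, object] = {}
        aas: Dict[str, float] = {}
        extras: Dict[str, float] = {}
        for canon, original in cols.items():
            if canon in ("sample_id", "basis"):
                continue
            raw = row[original]
            if pd.isna(raw):
                continue
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric value {raw!r} in row {idx + 1}, "
                    f"column {original!r}"
                ) from None
            if canon == "dm":
                kwargs["dm_pct"] = value
            elif canon in ANALYTES:
                kwargs[canon] = value
            elif canon in AMINO_ACIDS:
                aas[canon] = value
            else:
                extras[canon] = value
        rec = ChemicalComposition(
            sample_id=sample_id, basis=basis, amino_acids=aas, extras=extras,
            **kwargs,  # type: ignore[arg-type]
        )
        for issue in rec.validate():
            warnings.warn(f"row {idx + 1}: {issue}", DataQualityWarning, stacklevel=2)
        records.append(rec)
    return records


def convert_basis(c: ChemicalComposition, target: Basis) -> ChemicalComposition:
    """Re-express a composition on the other reporting basis.

    as-fed -> DM multiplies every analyte (and gross energy) by 100/DM%;
    the inverse direction multiplies by DM%/100. Round-trips are exact to
    floating precision.
    """
    if c.basis is target:
        return dataclasses.replace(c)
    if c.dm_pct <= 0:
        raise ValueError(f"{c.sample_id}: cannot convert basis with dm_pct <= 0")
    factor = 100.0 / c.dm_pct if target is Basis.DM else c.dm_pct / 100.0
    updates: Dict[str, object] = {"basis": target}
    for name in ("gross_energy", "cp", "ndf", "adf", "ash", "ee", "starch",
                 "idf", "sdf", "tdf", "ca", "p"):
        v = getattr(c, name)
        if v is not None:
            updates[name] = v * factor
    updates["amino_acids"] = {k: v * factor for k, v in c.amino_acids.items()}
    updates["extras"] = {k: v * factor for k, v in c.extras.items()}
    return dataclasses.replace(c, **updates)  # type: ignore[arg-type]


def composition_frame(records: Sequence[ChemicalComposition]) -> pd.DataFrame:
    """Analyte matrix (samples x analytes) for correlation/regression work."""
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id}
        for name in ("dm_pct", "cp", "ndf", "adf", "ash", "ee", "starch",
                     "idf", "sdf", "tdf", "ca", "p", "gross_energy"):
            row[name] = getattr(r, name)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def read_diet_table(path: PathLike) -> List[DietFormulation]:
    """Read the wide diet-formulation CSV into :class:`DietFormulation`."""
    df = pd.read_csv(path)
    mineral_cols = ["dicalcium_phosphate", "limestone", "salt", "premix"]
    diets: List[DietFormulation] = []
    for _, row in df.iterrows():
        components = {"corn": float(row["corn"]), "soybean_meal": float(row["soybean_meal"])}
        for c in mineral_cols:
            components[c] = float(row[c])
        barley_id = row.get("barley_id")
        incl = float(row.get("barley_incl", 0.0) or 0.0)
        if isinstance(barley_id, str) and barley_id:
            components[barley_id] = incl
        diets.append(
            DietFormulation(
                diet_id=str(row["diet_id"]),
                components=components,
                substitution_rate=incl / 100.0,
                basal_ref=None if incl == 0.0 else "Basal",
            )
        )
    return diets


def load_barley_composition() -> List[ChemicalComposition]:
    """The ten-barley composition table, % DM basis."""
    return read_composition_table(fixture_path("barley10.csv"), basis=Basis.DM)


def load_diet_formulations() -> List[DietFormulation]:
    return read_diet_table(fixture_path("diets.csv"))


def load_diet_energy() -> pd.DataFrame:
    """Per-diet energy balance table (metabolic-BW rates, RQ, DE/ME/NE)."""
    return pd.read_csv(fixture_path("diet_energy.csv")).set_index("diet_id")


def load_barley_energy() -> pd.DataFrame:
    """Per-barley digestibility and energy values."""
    return pd.read_csv(fixture_path("barley_energy.csv")).set_index("ingredient_id")


def read_gas_csv(path: PathLike) -> List[GasExchangeRecord]:
    """Read a gas time-series CSV (sow_id, ISO timestamp, differential
    concentrations, flow, state)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"sow_id", "timestamp", "o2_conc", "co2_conc", "ch4_conc", "flow_l_min", "state"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = [
        GasExchangeRecord(
            sow_id=str(r.sow_id),
            timestamp=r.timestamp.to_pydatetime(),
            o2_conc=float(r.o2_conc),
            co2_conc=float(r.co2_conc),
            ch4_conc=float(r.ch4_conc),
            flow_l_min=float(r.flow_l_min),
            state=State(r.state),
        )
        for r in df.itertuples()
    ]
    last: Dict[str, datetime] = {}
    for rec in records:
        prev = last.get(rec.sow_id)
        if prev is not None and rec.timestamp <= prev:
            raise FormatError(
                f"{path}: timestamps not strictly increasing for sow {rec.sow_id}"
            )
        last[rec.sow_id] = rec.timestamp
    return records


def read_collection_csv(path: PathLike) -> List[CollectionRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            CollectionRecord(
                sow_id=str(row["sow_id"]),
                period=int(row["period"]),
                kind=CollectionKind(row["kind"]),
                mass_kg_d=float(row.get("mass_kg_d", 0.0) or 0.0),
                ge_mj_kg=_opt(row.get("ge_mj_kg")),
                ge_mj_d=_opt(row.get("ge_mj_d")),
                n_g_d=float(row.get("n_g_d", 0.0) or 0.0),
                dm_pct=_opt(row.get("dm_pct")),
            )
        )
    return records


def read_sow_periods_csv(path: PathLike) -> List[SowPeriod]:
    df = pd.read_csv(path)
    return [
        SowPeriod(
            sow_id=str(r.sow_id),
            period=int(r.period),
            diet_id=str(r.diet_id),
            bw_kg=float(r.bw_kg),
            dm_intake_kg_d=float(r.dm_intake_kg_d),
            feed_ge_mj_kg_dm=float(r.feed_ge_mj_kg_dm),
            n_intake_g_d=float(r.n_intake_g_d) if hasattr(r, "n_intake_g_d") else None,
        )
        for r in df.itertuples()
    ]


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or pd.isna(value):
        return None
    return float(value)


def write_results(results: Iterable[object], path: PathLike, precision: int = 6) -> None:
    """Write a homogeneous collection of result dataclasses as tidy CSV.

    Column order follows field declaration order, floats are rendered with a
    fixed number of decimals so re-reading reproduces the table within the
    printed precision.
    """
    results = list(results)
    if not results:
        raise ValueError("nothing to write")
    first = results[0]
    if isinstance(first, pd.DataFrame):
        raise TypeError("pass dataclass records, not a DataFrame")
    fields = [f.name for f in dataclasses.fields(first)]  # type: ignore[arg-type]
    rows = []
    for r in results:
        row = {}
        for name in fields:
            v = getattr(r, name)
            if isinstance(v, dict):
                for k, sub in sorted(v.items()):
                    row[f"{name}.{k}"] = sub
            elif isinstance(v, list):
                row[name] = ";".join(str(x) for x in v)
            elif isinstance(v, Enum):
                row[name] = v.value
            else:
                row[name] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format=f"%.{precision}f")
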