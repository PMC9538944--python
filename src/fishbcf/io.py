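"""CSV readers/writers with strict schema validation.

All unit conversion happens here, once, at the boundary: in vitro sampling
times arrive in minutes and are converted to hours; everything downstream is
in the package's internal units (h for in vitro, d for in vivo, kg, L).
Files are UTF-8 with '.' as the decimal separator.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .depletion import DepletionTimecourse
from .errors import SchemaError
from .tg305 import FishSeries, WaterSeries

DEPLETION_COLUMNS = (
    "run_id", "species", "chemical", "cell_state", "condition",
    "replicate", "time_min", "concentration",
)
WATER_COLUMNS = ("sample_date_day", "phase", "conc_ng_L")
FISH_COLUMNS = ("day", "phase", "fish_id", "conc_ng_kg", "weight_g")


def _read_csv(path: str | Path, columns: tuple[str, ...], numeric: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in columns]
    if extra:
        raise SchemaError(f"{path.name}: unexpected column(s) {extra}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path.name}: non-numeric value in column '{col}' at row {bad[0] + 2}"
            )
        if coerced.isna().any():
            row = int(coerced.index[coerced.isna()][0]) + 2
            raise SchemaError(f"{path.name}: empty cell in column '{col}' at row {row}")
        df[col] = coerced
    return df


def read_depletion_csv(path: str | Path) -> list[DepletionTimecourse]:
    """Read depletion assay data; one record per (run, condition, replicate).

    Times are given in minutes in the file and converted to hours here.
    """
    df = _read_csv(path, DEPLETION_COLUMNS, ("replicate", "time_min", "concentration"))
    records = []
    keys = ["run_id", "species", "chemical", "cell_state", "condition", "replicate"]
    for key, grp in df.groupby(keys, sort=False):
        dup = grp["time_min"].duplicated()
        if dup.any():
            t = grp.loc[dup, "time_min"].iloc[0]
            raise SchemaError(
                f"duplicate (replicate, time) key: replicate {key[-1]} time_min {t}"
            )
        grp = grp.sort_values("time_min")
        records.append(
            DepletionTimecourse(
                run_id=str(key[0]),
                species=str(key[1]),
                chemical=str(key[2]),
                cell_state=str(key[3]),
                condition=str(key[4]),
                replicate_id=int(key[5]),
                times=grp["time_min"].to_numpy(dtype=float) / 60.0,
                concentrations=grp["concentration"].to_numpy(dtype=float),
            )
        )
    return records


def write_depletion_csv(path: str | Path, records: list[DepletionTimecourse]) -> None:
    rows = []
    for tc in records:
        for t, c in zip(tc.times, tc.concentrations):
            rows.append(
                {
                    "run_id": tc.run_id,
                    "species": tc.species,
                    "chemical": tc.chemical,
                    "cell_state": tc.cell_state,
                    "condition": tc.condition,
                    "replicate": tc.replicate_id,
                    "time_min": t * 60.0,
                    "concentration": c,
                }
            )
    pd.DataFrame(rows, columns=list(DEPLETION_COLUMNS)).to_csv(path, index=False)


def read_water_csv(path: str | Path, phase: str = "uptake") -> WaterSeries:
    df = _read_csv(path, WATER_COLUMNS, ("sample_date_day", "conc_ng_L"))
    sel = df[df["phase"] == phase].sort_values("sample_date_day")
    return WaterSeries(
        days=sel["sample_date_day"].to_numpy(dtype=float),
        concentrations=sel["conc_ng_L"].to_numpy(dtype=float),
        phase=phase,
    )


def write_water_csv(path: str | Path, ws: WaterSeries) -> None:
    pd.DataFrame(
        {
            "sample_date_day": ws.days,
            "phase": ws.phase,
            "conc_ng_L": ws.concentrations,
        }
    ).to_csv(path, index=False)


def read_fish_csv(path: str | Path) -> FishSeries:
    df = _read_csv(path, FISH_COLUMNS, ("day", "conc_ng_kg", "weight_g"))
    return FishSeries(df)


def write_fish_csv(path: str | Path, fs: FishSeries) -> None:
    fs.data[list(FISH_COLUMNS)].to_csv(path, index=False)
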