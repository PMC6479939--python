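"""Delimited-text readers and writers for every pipeline table.

All tables are UTF-8 CSV or TSV; the delimiter is chosen by file
extension (.csv → comma, anything else → tab).  Decimal points only.
Every writer's output round-trips through the matching reader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .isotopes import ChamberGeometry, IsotopeMeasurement, Pool, Stage, Treatment
from .flux import Gas, GasSampleSeries

MEASUREMENT_COLUMNS = [
    "pool",
    "treatment",
    "stage",
    "day",
    "replicate",
    "delta_permil",
    "pool_c_mass_g",
]

GAS_COLUMNS = ["gas", "day", "time_h", "conc_ppm", "temp_C"]


def _sep(path: str | Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _read(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=_sep(path), **kw)
    except FileNotFoundError:
        raise
    except Exception as exc:  # surface the offending file in parse errors
        raise ValueError(f"could not parse table {path}: {exc}") from exc


def _require(df: pd.DataFrame, columns: Sequence[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"table {path} is missing columns {missing}")


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = _read(path)
    _require(df, MEASUREMENT_COLUMNS, path)
    bad = set(df["pool"]) - {p.value for p in Pool}
    if bad:
        raise ValueError(f"table {path} has unknown pools {sorted(bad)}")
    bad = set(df["treatment"]) - {t.value for t in Treatment}
    if bad:
        raise ValueError(f"table {path} has unknown treatments {sorted(bad)}")
    return df[MEASUREMENT_COLUMNS].copy()


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    df[MEASUREMENT_COLUMNS].to_csv(path, sep=_sep(path), index=False)


def measurements_to_objects(df: pd.DataFrame) -> list[IsotopeMeasurement]:
    out = []
    for row in df.itertuples(index=False):
        mass = getattr(row, "pool_c_mass_g", None)
        out.append(
            IsotopeMeasurement(
                pool=Pool(row.pool),
                treatment=Treatment(row.treatment),
                stage=Stage(row.stage),
                day=int(row.day),
                replicate=int(row.replicate),
                delta_permil=float(row.delta_permil),
                pool_c_mass_g=None if mass is None or pd.isna(mass) else float(mass),
            )
        )
    return out


def read_gas_table(path: str | Path) -> pd.DataFrame:
    df = _read(path)
    _require(df, GAS_COLUMNS, path)
    return df


def write_gas_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = (["treatment"] if "treatment" in df.columns else []) + GAS_COLUMNS
    df[cols].to_csv(path, sep=_sep(path), index=False)


def gas_table_to_series(
    df: pd.DataFrame, geometry: ChamberGeometry | None = None
) -> list[tuple[dict, GasSampleSeries]]:
    """Group a gas table into per-closure series.

    Returns (key, series) pairs where key holds the grouping labels
    (gas, day and, when present, treatment)."""
    geometry = geometry or ChamberGeometry()
    keys = ["gas", "day"] + (["treatment"] if "treatment" in df.columns else [])
    out = []
    for key_vals, sub in df.groupby(keys, sort=True):
        key = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        sub = sub.sort_values("time_h")
        series = GasSampleSeries(
            gas=Gas(key["gas"]),
            times_h=tuple(sub["time_h"].astype(float)),
            conc_ppm=tuple(sub["conc_ppm"].astype(float)),
            temperature_c=float(sub["temp_C"].iloc[0]),
            geometry=geometry,
            day=int(key["day"]),
        )
        out.append((key, series))
    return out


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Taxa as rows, samples as columns; first column holds taxon labels."""
    return _read(path, index_col=0)


def write_abundance(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep(path))


read_environment = read_abundance
write_environment = write_abundance
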