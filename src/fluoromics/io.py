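"""Reading and writing instrument-style delimited tables.

Instrument exports vary, so readers accept a small :class:`TableDialect`
(delimiter, time unit, header rows) instead of guessing.  All writers emit
plain delimited text with a one-line header; generator writers also record
the seed in a JSON sidecar (``<file>.meta.json``).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .containers import FluorescenceTransient, LightCurveDataset, OmicsFeatureTable
from .errors import ValidationError

__all__ = [
    "TableDialect",
    "read_transient_table",
    "write_transient_table",
    "read_light_curve_table",
    "write_light_curve_table",
    "read_omics_tables",
    "write_omics_tables",
    "write_sidecar",
]

_TIME_FACTORS = {"s": 1.0, "ms": 1e-3, "us": 1e-6, "µs": 1e-6}


@dataclass(frozen=True)
class TableDialect:
    """How to parse a two-column transient export.

    ``time_unit`` may be None when the header itself declares the unit as a
    ``time_<unit>`` column name (e.g. ``time_ms``).
    """

    delimiter: str = "\t"
    time_unit: str | None = None
    header_rows: int = 1
    comment: str = "#"


def _resolve_time_unit(colname: str, dialect: TableDialect) -> float:
    if dialect.time_unit is not None:
        unit = dialect.time_unit
    elif "_" in colname:
        unit = colname.rsplit("_", 1)[1]
    else:
        raise ValidationError(
            "time unit not declared: use a 'time_<unit>' header or set "
            "TableDialect.time_unit to 's', 'ms' or 'us'"
        )
    try:
        return _TIME_FACTORS[unit]
    except KeyError:
        raise ValidationError(f"unknown time unit {unit!r}; expected s, ms or us") from None


def read_transient_table(
    path: str | Path, dialect: TableDialect = TableDialect(), label: str = ""
) -> FluorescenceTransient:
    """Read a two-column time/fluorescence table into a transient.

    Times are converted to seconds, rows sorted by time, and duplicate
    timestamps collapsed by mean fluorescence.  Non-numeric cells raise a
    parse error naming the offending row; coverage of the cardinal-point
    window (300 µs – 30 ms) is enforced by the container.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=dialect.delimiter, comment=dialect.comment or None,
        header=dialect.header_rows - 1 if dialect.header_rows else None,
        skip_blank_lines=True,
    )
    if df.shape[1] < 2:
        raise ValidationError(f"{path.name}: expected two columns, found {df.shape[1]}")
    df = df.iloc[:, :2]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path.name}: non-numeric value in column {col!r} at data row "
                f"{int(bad[0]) + 1}"
            )
        df[col] = coerced
    df = df.dropna()
    factor = _resolve_time_unit(str(df.columns[0]), dialect)
    df.columns = ["time", "fluorescence"]
    df["time"] = df["time"] * factor
    df = df.groupby("time", as_index=False, sort=True)["fluorescence"].mean()
    return FluorescenceTransient(
        time=df["time"].to_numpy(), fluorescence=df["fluorescence"].to_numpy(), label=label
    )


def write_transient_table(
    transient: FluorescenceTransient, path: str | Path, delimiter: str = "\t"
) -> Path:
    """Write a transient as a two-column table with times in seconds."""
    path = Path(path)
    df = pd.DataFrame({"time_s": transient.time, "fluorescence": transient.fluorescence})
    df.to_csv(path, sep=delimiter, index=False, float_format="%.10g")
    return path


def read_light_curve_table(
    path: str | Path, delimiter: str = "\t", label: str = ""
) -> LightCurveDataset:
    """Read a PAR-stepped light-curve table.

    Format: comment header lines ``# F0=<val>`` and ``# Fm=<val>`` carrying
    the dark-adapted reference, then columns par, f, fm_prime.
    """
    path = Path(path)
    dark: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                dark[key.strip().lower()] = float(val)
    if "f0" not in dark or "fm" not in dark:
        raise ValidationError(f"{path.name}: missing '# F0=' / '# Fm=' dark header lines")
    df = pd.read_csv(path, sep=delimiter, comment="#")
    required = {"par", "f", "fm_prime"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path.name}: need columns {sorted(required)}")
    return LightCurveDataset(
        f0=dark["f0"], fm=dark["fm"],
        par=df["par"].to_numpy(), f=df["f"].to_numpy(),
        fm_prime=df["fm_prime"].to_numpy(), label=label,
    )


def write_light_curve_table(
    ds: LightCurveDataset, path: str | Path, delimiter: str = "\t"
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# F0={ds.f0:.10g}\n# Fm={ds.fm:.10g}\n")
        pd.DataFrame({"par": ds.par, "f": ds.f, "fm_prime": ds.fm_prime}).to_csv(
            fh, sep=delimiter, index=False, float_format="%.10g"
        )
    return path


def read_omics_tables(
    values_path: str | Path,
    design_path: str | Path,
    layer: str,
    annotations_path: str | Path | None = None,
    delimiter: str = "\t",
) -> OmicsFeatureTable:
    """Read a feature × sample matrix plus its (sample, group) design file."""
    values = pd.read_csv(values_path, sep=delimiter, index_col=0)
    design_df = pd.read_csv(design_path, sep=delimiter)
    if not {"sample", "group"}.issubset(design_df.columns):
        raise ValidationError("design file needs 'sample' and 'group' columns")
    design = design_df.set_index("sample")["group"]
    annotations = (
        pd.read_csv(annotations_path, sep=delimiter, index_col=0)
        if annotations_path is not None
        else None
    )
    return OmicsFeatureTable(layer=layer, values=values, design=design,
                             annotations=annotations)


def write_omics_tables(
    table: OmicsFeatureTable, values_path: str | Path, design_path: str | Path,
    delimiter: str = "\t",
) -> None:
    table.values.to_csv(values_path, sep=delimiter, index_label="feature")
    design = table.design.rename_axis("sample").rename("group").reset_index()
    design.to_csv(design_path, sep=delimiter, index=False)


def write_sidecar(path: str | Path, seed: int, **extra) -> Path:
    """Record generation provenance (seed and parameters) next to an artifact."""
    meta = Path(str(path) + ".meta.json")
    meta.write_text(json.dumps({"seed": int(seed), **extra}, indent=2, sort_keys=True))
    return meta
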