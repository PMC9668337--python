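"""Delimiter-separated tables for spectra, SAS, phenotypes and pedigrees.

All tables are plain text with a mandatory header row; the delimiter is
auto-detected among comma and tab on read.  Spectra/SAS tables carry key
columns ``subject, session, hemi`` followed by ``ev0001..evK`` (or
``sas0001..sasK``) value columns, and an optional ``# normalization=...``
comment line recording the eigenvalue normalization.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required key column is missing for the requested schema."""


_SCHEMA_KEYS = {
    "spectra": ["subject", "session", "hemi"],
    "sas": ["subject", "session"],
    "phenotypes": ["subject"],
    "pedigree": ["subject", "family", "zygosity"],
}


def value_columns(df: pd.DataFrame, prefix: str = "ev") -> list[str]:
    """Names of the numeric value columns, in index order."""
    cols = [c for c in df.columns if c.startswith(prefix) and c[len(prefix):].isdigit()]
    return sorted(cols, key=lambda c: int(c[len(prefix):]))


def spectra_frame(rows: dict, k: int, prefix: str = "ev",
                  normalization: str = "none") -> pd.DataFrame:
    """Assemble a spectra/SAS table from ``{(subject, session, hemi): values}``."""
    cols = [f"{prefix}{i:04d}" for i in range(1, k + 1)]
    recs = []
    for key, values in rows.items():
        values = np.asarray(values, dtype=float)
        if values.size != k:
            raise ValueError(f"row {key}: expected {k} values, got {values.size}")
        rec = dict(zip(["subject", "session", "hemi"][: len(key)], key))
        rec.update(dict(zip(cols, values)))
        recs.append(rec)
    df = pd.DataFrame.from_records(recs)
    df.attrs["normalization"] = normalization
    return df


def _detect_delim(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","
    return ","


def read_table(path, schema: str = "spectra") -> pd.DataFrame:
    """Read a typed table, checking the key columns required by ``schema``."""
    path = Path(path)
    if schema not in _SCHEMA_KEYS:
        raise ValueError(f"unknown schema {schema!r}")
    normalization: Optional[str] = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "normalization=" in first:
        normalization = first.split("normalization=", 1)[1].strip()
    df = pd.read_csv(path, sep=_detect_delim(path), comment="#",
                     float_precision="round_trip")
    ncols = df.shape[1]
    bad = df.apply(lambda r: r.notna().size != ncols, axis=1)
    if bad.any():
        raise ValueError(f"{path}: ragged rows detected")
    missing = [c for c in _SCHEMA_KEYS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: schema {schema!r} requires columns {missing}")
    if normalization is not None:
        df.attrs["normalization"] = normalization
    return df


def write_table(df: pd.DataFrame, path, schema: str = "spectra",
                delimiter: str = ",") -> None:
    """Write a table; numeric values keep 15+ significant digits."""
    path = Path(path)
    missing = [c for c in _SCHEMA_KEYS.get(schema, []) if c not in df.columns]
    if missing:
        raise SchemaError(f"schema {schema!r} requires columns {missing}")
    with open(path, "w") as fh:
        norm = df.attrs.get("normalization")
        if norm is not None:
            fh.write(f"# normalization={norm}\n")
        df.to_csv(fh, sep=delimiter, index=False, float_format="%.17g")
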