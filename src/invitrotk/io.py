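"""CSV reading and writing for the measurement and chemical tables.

Files are comma-separated UTF-8 with a header row and ``.`` decimal marks.
Reading validates against the table invariants in :mod:`invitrotk.datamodel`
and raises with row-indexed diagnostics on failure, so downstream stages can
assume clean input.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

from .datamodel import (
    CHEMICAL_COLUMNS,
    MEASUREMENT_COLUMNS,
    SchemaError,
    validate_chemicals,
    validate_measurements,
)

__all__ = ["read_measurements", "read_chemicals", "write_table"]

_PathLike = Union[str, Path]

_SCHEMAS = {
    "measurements": (MEASUREMENT_COLUMNS, validate_measurements),
    "chemicals": (CHEMICAL_COLUMNS, validate_chemicals),
}


def read_measurements(path: _PathLike, schema: str = "measurements") -> pd.DataFrame:
    """Read and validate a table of MS measurements.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    schema : {"measurements", "chemicals"}
        Which table schema to validate against.

    Returns
    -------
    pandas.DataFrame
        Canonicalised table (column order and dtypes fixed).
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    _, validator = _SCHEMAS[schema]
    raw = pd.read_csv(
        path,
        dtype={"chem_id": str, "batch_id": str} if schema == "measurements" else {"chem_id": str},
        float_precision="round_trip",
    )
    return validator(raw)


def read_chemicals(path: _PathLike) -> pd.DataFrame:
    """Read and validate a chemicals table; see :func:`read_measurements`."""
    return read_measurements(path, schema="chemicals")


def write_table(df: pd.DataFrame, path: _PathLike) -> None:
    """Write a table as UTF-8 CSV.

    Floats use the shortest round-trip representation, so write→read is
    lossless and repeated write→read→write is byte-stable.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
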