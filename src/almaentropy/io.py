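"""Readers and writers for the pipeline's plain-text formats.

All CSVs are UTF-8, comma-separated with ``.`` decimals and LF endings;
strings containing commas (measure names like "Ki (nM)") are quoted.
Floats serialize at full shortest-round-trip precision so a write/read
cycle is bit-stable.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import DataError
from .records import ENDPOINT_COLUMNS, EndpointRecord, frame_to_records

__all__ = [
    "read_smiles",
    "read_endpoints",
    "read_endpoints_frame",
    "write_endpoints",
    "write_csv",
]


def read_smiles(path: str | Path) -> list[tuple[str, str]]:
    """Read molecules as (id, SMILES) pairs.

    Accepts either a tab-separated SMILES file (``<smiles><TAB><id>`` per
    line, id optional) or a CSV with ``compound_id`` and ``smiles``
    columns, sniffed from the header.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    first = path.open().readline()
    if "compound_id" in first and "smiles" in first:
        frame = pd.read_csv(path, dtype=str)
        return [(r.compound_id, r.smiles) for r in frame.itertuples(index=False)]
    out = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        smiles = parts[0]
        cid = parts[1] if len(parts) > 1 else f"mol{lineno}"
        out.append((cid, smiles))
    if not out:
        raise DataError(f"{path} contains no molecules")
    return out


def read_endpoints_frame(path: str | Path) -> pd.DataFrame:
    """Endpoint CSV as a DataFrame, validating header and label values.

    Extra columns are tolerated with a warning; labels must be 0, 1 or
    blank, and violations are reported with their line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ENDPOINT_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(
            f"{path}: malformed header, missing columns {missing}"
        )
    extra = [c for c in frame.columns if c not in ENDPOINT_COLUMNS]
    if extra:
        warnings.warn(
            f"{path}: ignoring extra columns {extra}", stacklevel=2
        )
        frame = frame[list(ENDPOINT_COLUMNS)]
    bad_lines = [
        i + 2  # header is line 1
        for i, v in enumerate(frame["label"])
        if v not in ("", "0", "1")
    ]
    if bad_lines:
        raise DataError(
            f"{path}: label values must be 0, 1 or blank; offending lines "
            f"{bad_lines[:10]}"
        )
    frame["label"] = (
        frame["label"].replace("", pd.NA).astype("Int64")
    )
    return frame


def read_endpoints(path: str | Path) -> list[EndpointRecord]:
    """Endpoint CSV as typed records."""
    return frame_to_records(read_endpoints_frame(path))


def write_endpoints(frame: pd.DataFrame, path: str | Path) -> None:
    write_csv(frame[list(ENDPOINT_COLUMNS)], path)


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame with full-precision floats and LF endings."""
    frame.to_csv(
        path,
        index=False,
        lineterminator="\n",
        quoting=csv.QUOTE_MINIMAL,
        float_format=None,  # pandas uses repr-faithful formatting
    )
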