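"""Delimited-file I/O shared by all pipeline stages.

One flat UTF-8 table per stage, wide layout (one column per variable),
header row with the exact canonical variable codes.  Empty cells and "NA"
are the canonical missing markers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .schema import VARIABLE_ORDER

MISSING_TOKENS = ("", "NA")

#: columns a raw input table must provide
REQUIRED_RAW_COLUMNS = ("site_id",) + VARIABLE_ORDER


class InputFormatError(ValueError):
    """The input table violates the expected layout."""


def read_sites(path: str | Path, delimiter: str = ",",
               na_tokens: Sequence[str] = MISSING_TOKENS) -> pd.DataFrame:
    """Read a site table; pressure columns are kept as-is (tokens allowed)."""
    df = pd.read_csv(
        path,
        sep=delimiter,
        na_values=list(na_tokens),
        keep_default_na=False,
        dtype={"site_id": str},
    )
    if "site_id" not in df.columns:
        raise InputFormatError(f"{path}: missing required column 'site_id'")
    return df


def require_pressure_columns(df: pd.DataFrame, source: str = "input") -> None:
    missing = [c for c in REQUIRED_RAW_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(
            f"{source}: missing required column(s) {', '.join(missing)}"
        )


def write_table(df: pd.DataFrame, path: str | Path, delimiter: str = ",",
                index: bool = False, index_label: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, index=index, index_label=index_label,
              na_rep="NA", lineterminator="\n")
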