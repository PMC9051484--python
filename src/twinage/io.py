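"""CSV dialects for twin tables.

The domain has no standard on-disk format for twin data, so two plain-CSV
dialects are normative for this package:

* **long** — one row per assessment of one twin::

      family_id,twin,zygosity,wave,age,birth_year,scanner,ethnicity,phenotype

  ``twin`` is 1 or 2, ``zygosity`` is ``MZ``/``DZ``, ``scanner`` a category
  (e.g. ``1.5T``/``3T``).

* **wide** — one row per twin pair, one column per (variable, twin) slot::

      family_id,zygosity,t1_a,...,tT_a,t1_b,...,tT_b

  Empty fields are missing values.  Variable names other than ``t1..tT``
  (e.g. interval labels) are allowed; twin columns must end in ``_a``/``_b``.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

LONG_COLUMNS = [
    "family_id",
    "twin",
    "zygosity",
    "wave",
    "age",
    "birth_year",
    "scanner",
    "ethnicity",
    "phenotype",
]


def wide_variable_names(wide: pd.DataFrame) -> list[str]:
    """Phenotype variable names from a wide table's ``*_a`` columns (in order)."""
    names = [c[:-2] for c in wide.columns if c.endswith("_a")]
    missing_b = [v for v in names if f"{v}_b" not in wide.columns]
    if missing_b:
        raise ValueError(f"wide table lacks twin-b columns for {missing_b}")
    if not names:
        raise ValueError("wide table has no '*_a' phenotype columns")
    return names


def wide_columns(var_names: list[str]) -> list[str]:
    return (
        ["family_id", "zygosity"]
        + [f"{v}_a" for v in var_names]
        + [f"{v}_b" for v in var_names]
    )


def read_long(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long table {path} lacks columns {missing}")
    return df


def write_long(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_wide(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    wide_variable_names(df)  # validates shape
    if "zygosity" not in df.columns:
        raise ValueError(f"wide table {path} lacks a zygosity column")
    return df


def write_wide(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep="")
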