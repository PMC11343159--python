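"""Plain-text IO: TSV tables, JSON models, validation on read.

All tabular data travel as TSV with a header row and an id column;
floats are written at 12 significant digits.  Readers validate headers,
reject duplicate ids and non-numeric cells, and (for square matrices)
check symmetry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_table",
    "read_table",
    "read_matrix",
    "write_json",
    "read_json",
]

_FLOAT_FMT = "%.12g"


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_table(path, numeric: bool = True) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate ids in {path}: {dupes[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate column labels in {path}")
    if numeric:
        try:
            df = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return df


def read_matrix(path, atol: float = 1e-8) -> pd.DataFrame:
    """Read a dense symmetric matrix (parcel-id header both ways)."""
    df = read_table(path, numeric=True)
    if list(df.index) != list(df.columns):
        raise ValueError(f"matrix in {path} is not labeled square")
    m = df.to_numpy(dtype=float)
    asym = np.abs(m - m.T).max()
    if asym > atol:
        raise ValueError(f"matrix in {path} asymmetric (max asymmetry {asym:.3e})")
    return df


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_default)


def _default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
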