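"""Dataset serialization: long-format CSV with header ``cluster,condition,y[,w]``."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .datagen import NestedDataset
from .exceptions import DataFormatError

__all__ = ["write_dataset_csv", "read_dataset_csv"]

_REQUIRED = ("cluster", "condition", "y")


def write_dataset_csv(data: NestedDataset, path: Union[str, Path]) -> None:
    """Write one observation per row, RFC-4180, '.' decimal, header required."""
    data.to_frame().to_csv(path, index=False)


def read_dataset_csv(path: Union[str, Path], design: str = "B") -> NestedDataset:
    """Read and validate a dataset CSV.

    The header must be exactly ``cluster,condition,y`` optionally followed by
    ``w``.  Condition codes are restricted to {0, 1}; ``w`` must be constant
    within each cluster.  Malformed rows are reported with their 1-based data
    row number.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # parse-level failure
        raise DataFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    cols = list(frame.columns)
    if cols not in (list(_REQUIRED), list(_REQUIRED) + ["w"]):
        raise DataFormatError(
            f"{path}: header must be 'cluster,condition,y[,w]', got {','.join(cols)}"
        )
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy().any(axis=1))[0][0]) + 1
        raise DataFormatError(f"{path}: non-numeric value in data row {row}")
    if numeric[list(_REQUIRED)].isna().to_numpy().any():
        row = int(np.argwhere(numeric[list(_REQUIRED)].isna().to_numpy().any(axis=1))[0][0]) + 1
        raise DataFormatError(f"{path}: missing value in data row {row}")
    cond = numeric["condition"]
    if not cond.isin((0, 1)).all():
        row = int(np.argwhere(~cond.isin((0, 1)).to_numpy())[0][0]) + 1
        raise DataFormatError(
            f"{path}: condition must be 0 or 1 (data row {row} has {frame['condition'].iloc[row - 1]!r})"
        )
    clus = numeric["cluster"]
    if ((clus < 0) | (clus != clus.astype(np.int64))).any():
        row = int(np.argwhere(((clus < 0) | (clus != clus.astype(np.int64))).to_numpy())[0][0]) + 1
        raise DataFormatError(f"{path}: cluster ids must be non-negative integers (data row {row})")
    ds = NestedDataset(
        cluster=clus.to_numpy(np.int64),
        condition=cond.to_numpy(np.int64),
        y=numeric["y"].to_numpy(np.float64),
        design=design,
        w=numeric["w"].to_numpy(np.float64) if "w" in cols else None,
    )
    ds.validate()
    ds.balanced = ds.is_balanced()
    return ds
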