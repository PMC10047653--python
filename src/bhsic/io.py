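"""Reading delimited sample tables into :class:`~bhsic.statistic.CISample`."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .statistic import CISample

__all__ = ["ColumnSpec", "read_sample", "write_sample"]


@dataclass(frozen=True)
class ColumnSpec:
    """Disjoint column names assigning table columns to the x, y, z blocks."""

    x_columns: tuple[str, ...]
    y_columns: tuple[str, ...]
    z_columns: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in ("x_columns", "y_columns", "z_columns"):
            cols = tuple(getattr(self, name))
            object.__setattr__(self, name, cols)
            if not cols:
                raise ValueError(f"{name} must be non-empty")
        all_cols = self.x_columns + self.y_columns + self.z_columns
        if len(set(all_cols)) != len(all_cols):
            raise ValueError("x, y, z column lists must be disjoint")

    @property
    def all_columns(self) -> tuple[str, ...]:
        return self.x_columns + self.y_columns + self.z_columns


def _read_table(path) -> pd.DataFrame:
    # comma or tab only; decide from the header line
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def read_sample(path, spec: ColumnSpec) -> CISample:
    """Read a CSV/TSV file (header row required) into a validated sample.

    Missing columns, non-numeric cells, and missing values in the selected
    columns raise descriptive errors; fewer than two complete rows is an
    error as well.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path)

    missing = [c for c in spec.all_columns if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing columns {missing}; available: {list(df.columns)}"
        )

    sel = df[list(spec.all_columns)].apply(pd.to_numeric, errors="coerce")
    bad = sel.isna()
    if bad.to_numpy().any():
        rows = np.flatnonzero(bad.any(axis=1))
        col = bad.columns[bad.iloc[rows[0]].to_numpy()][0]
        raise ValueError(
            f"{path.name}: {len(rows)} row(s) with missing or non-numeric "
            f"values in selected columns (first: row {rows[0]}, column {col!r})"
        )
    if len(sel) < 2:
        raise ValueError(f"{path.name}: need at least 2 complete rows, got {len(sel)}")

    return CISample(
        sel[list(spec.x_columns)].to_numpy(float),
        sel[list(spec.y_columns)].to_numpy(float),
        sel[list(spec.z_columns)].to_numpy(float),
    )


def write_sample(sample: CISample, path, spec: ColumnSpec | None = None) -> ColumnSpec:
    """Write a sample to CSV (x1.., y1.., z1.. columns); returns the spec."""
    if spec is None:
        spec = ColumnSpec(
            tuple(f"x{i+1}" for i in range(sample.x.shape[1])),
            tuple(f"y{i+1}" for i in range(sample.y.shape[1])),
            tuple(f"z{i+1}" for i in range(sample.z.shape[1])),
        )
    data = np.hstack([sample.x, sample.y, sample.z])
    pd.DataFrame(data, columns=list(spec.all_columns)).to_csv(path, index=False)
    return spec
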