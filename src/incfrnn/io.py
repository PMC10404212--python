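"""Tabular I/O: descriptor tables as CSV or ARFF, pool snapshots as CSV.

ARFF support covers the numeric-attributes-plus-one-nominal-class subset
that instance-based learning workflows exchange; no ARFF library is
bundled with the scientific stack this package targets, so the dialect is
implemented here directly (header of ``@attribute`` lines, comma-separated
``@data`` rows, ``%`` comments).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .pool import TrainingPool

__all__ = [
    "read_table",
    "write_table",
    "write_pool_csv",
    "read_pool_csv",
]


class TableFormatError(ValueError):
    """Malformed table file; the message names the offending line."""


def read_table(path, fmt: str | None = None, class_column: str = "class") -> pd.DataFrame:
    """Read a descriptor table (numeric features + one nominal class column).

    ``fmt`` is ``"csv"`` or ``"arff"``; inferred from the suffix when None.
    The class attribute is identified by the name ``class`` or, failing
    that, the last non-numeric column.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        table = pd.read_csv(path, float_precision="round_trip")
    elif fmt == "arff":
        table = _read_arff(path)
    else:
        raise ValueError(f"unknown table format {fmt!r}")
    if class_column not in table.columns:
        nominal = [c for c in table.columns if table[c].dtype == object]
        if not nominal:
            raise TableFormatError(f"{path}: no class column found")
        table = table.rename(columns={nominal[-1]: class_column})
    feats = [c for c in table.columns if c != class_column]
    for c in feats:
        try:
            table[c] = pd.to_numeric(table[c])
        except (ValueError, TypeError) as exc:
            def _numeric(v) -> bool:
                try:
                    float(v)
                    return True
                except (TypeError, ValueError):
                    return False

            bad = ~table[c].apply(_numeric)
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
            raise TableFormatError(
                f"{path}: non-numeric value in column {c!r} at line {line}"
            ) from exc
    return table


def write_table(table: pd.DataFrame, path, fmt: str | None = None,
                class_column: str = "class", relation: str = "descriptor") -> None:
    """Write a descriptor table as CSV or ARFF (lossless round-trip)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        table.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "arff":
        path.write_text(_to_arff(table, class_column, relation))
    else:
        raise ValueError(f"unknown table format {fmt!r}")


def _to_arff(table: pd.DataFrame, class_column: str, relation: str) -> str:
    buf = _io.StringIO()
    buf.write(f"@relation {relation}\n\n")
    for c in table.columns:
        if c == class_column:
            values = sorted(map(str, pd.unique(table[c])))
            buf.write(f"@attribute {c} {{{','.join(values)}}}\n")
        else:
            buf.write(f"@attribute {c} numeric\n")
    buf.write("\n@data\n")
    for _, row in table.iterrows():
        cells = [
            str(row[c]) if c == class_column else repr(float(row[c]))
            for c in table.columns
        ]
        buf.write(",".join(cells) + "\n")
    return buf.getvalue()


def _read_arff(path: Path) -> pd.DataFrame:
    names: list[str] = []
    kinds: list[str] = []
    rows: list[list] = []
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("@relation"):
                continue
            if low.startswith("@attribute"):
                if in_data:
                    raise TableFormatError(
                        f"{path}:{lineno}: @attribute after @data"
                    )
                parts = line.split(None, 2)
                if len(parts) < 3:
                    raise TableFormatError(
                        f"{path}:{lineno}: malformed @attribute line"
                    )
                names.append(parts[1])
                kinds.append("nominal" if parts[2].startswith("{") else "numeric")
                continue
            if low.startswith("@data"):
                in_data = True
                continue
            if not in_data:
                raise TableFormatError(f"{path}:{lineno}: data before @data")
            cells = [c.strip() for c in line.split(",")]
            if len(cells) != len(names):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(names)} cells, got {len(cells)}"
                )
            parsed = []
            for cell, kind in zip(cells, kinds):
                if kind == "numeric":
                    try:
                        parsed.append(float(cell))
                    except ValueError:
                        raise TableFormatError(
                            f"{path}:{lineno}: non-numeric cell {cell!r}"
                        ) from None
                else:
                    parsed.append(cell)
            rows.append(parsed)
    if not names:
        raise TableFormatError(f"{path}: no @attribute declarations")
    return pd.DataFrame(rows, columns=names)


def write_pool_csv(pool: TrainingPool, path) -> None:
    """Snapshot a training pool (features, label, counter, insertion index)."""
    pool.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_pool_csv(path) -> TrainingPool:
    """Rebuild a training pool from a snapshot written by write_pool_csv."""
    return TrainingPool.from_frame(
        pd.read_csv(path, float_precision="round_trip")
    )
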