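"""Reading and writing differential-results tables.

Input is a delimited text file (delimiter sniffed from the ``.csv``/``.tsv``
extension or given explicitly) whose columns are mapped onto the package's
standardized schema through a :class:`ColumnMap`.  The default map follows
the DESeq2 results dialect: ``log2FoldChange``, ``pvalue``, ``padj``,
``baseMean``.  Exactly one of the fc / log2fc columns may be mapped; the
other is derived.  Unmapped columns pass through untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .plot_builders import as_results_table
from .transforms import DomainPolicy, fold_change_units

logger = logging.getLogger("madfc")

__all__ = ["ColumnMap", "read_results", "write_table"]


class ColumnMapError(ValueError):
    """A mapped column is absent or the map is inconsistent."""


@dataclass(frozen=True)
class ColumnMap:
    """Names of the input columns carrying each standardized field.

    ``feature_id=None`` uses the file's first column.  Set ``fc`` (and
    ``log2fc=None``) for tables carrying raw fold-change ratios.
    """

    feature_id: Optional[str] = None
    fc: Optional[str] = None
    log2fc: Optional[str] = "log2FoldChange"
    pvalue: str = "pvalue"
    padj: Optional[str] = "padj"
    base_mean: Optional[str] = "baseMean"

    def __post_init__(self):
        if (self.fc is None) == (self.log2fc is None):
            raise ColumnMapError("exactly one of fc / log2fc must be mapped")


def _sep_for(path: Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    if path.suffix.lower() == ".csv":
        return ","
    return "\t"


def read_results(path, colmap: Optional[ColumnMap] = None,
                 policy: DomainPolicy = "propagate",
                 sep: Optional[str] = None) -> pd.DataFrame:
    """Read a delimited differential-results file into the standard schema.

    Returns a DataFrame with ``feature_id``, ``fc``, ``log2fc``, ``pvalue``
    and, where mapped and present, ``padj`` and ``base_mean``; extra
    columns are preserved.  Counts of missing/out-of-domain rows are logged.
    """
    colmap = colmap or ColumnMap()
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")

    mapping = {}
    for field in ("feature_id", "fc", "log2fc", "pvalue", "padj", "base_mean"):
        src = getattr(colmap, field)
        if field == "feature_id" and src is None:
            src = df.columns[0]
        if src is None:
            continue
        if src not in df.columns:
            if field in ("padj", "base_mean"):
                continue  # optional fields may simply be absent
            raise ColumnMapError(
                f"{path}: mapped column {src!r} for {field} not found; "
                f"available headers: {list(df.columns)}")
        mapping[src] = field

    out = df.rename(columns=mapping)
    out = as_results_table(out, policy=policy)

    n_bad_fc = int((~np.isfinite(out["fc"].to_numpy(dtype=float))
                    | (out["fc"].to_numpy(dtype=float) <= 0)).sum())
    n_missing_p = int(out["pvalue"].isna().sum())
    logger.info("read %d rows from %s (%d out-of-domain fold changes, %d missing p-values)",
                len(out), path, n_bad_fc, n_missing_p)
    return out


def write_table(table: pd.DataFrame, path, *, add_madfc: bool = False,
                sep: Optional[str] = None) -> Path:
    """Write a standardized results table as delimited text.

    Columns are emitted in the DESeq2 dialect so the file round-trips
    through :func:`read_results` with the default column map.  With
    ``add_madfc`` a ``madfc`` column of fold-change-unit coordinates is
    appended.
    """
    path = Path(path)
    df = table.copy()
    if add_madfc:
        df["madfc"] = fold_change_units(df["fc"].to_numpy(dtype=float),
                                        policy="propagate")
    rename = {"log2fc": "log2FoldChange", "base_mean": "baseMean"}
    df = df.rename(columns={k: v for k, v in rename.items() if k in df})
    lead = [c for c in ("feature_id", "baseMean", "log2FoldChange", "fc",
                        "pvalue", "padj", "madfc") if c in df.columns]
    df = df[lead + [c for c in df.columns if c not in lead]]
    df.to_csv(path, sep=_sep_for(path, sep), index=False)
    return path
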