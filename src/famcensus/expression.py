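"""RNA-seq expression categorization.

Per-gene, per-library FPKM values are placed in three classes — lowly
expressed (FPKM <= 5), moderately expressed (5 < FPKM <= 200) and highly
expressed (FPKM > 200) — and a per-gene expressed/not-expressed flag is
derived (by default: at least 1 FPKM in at least one library).  The
gene x library matrix keeps replicate libraries (suffix letters) as
separate columns and tracks missing combinations explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from famcensus.config import ExpressionConfig

CATEGORIES = ("low", "moderate", "high")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    library_id: str
    fpkm: float

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValueError("fpkm must be >= 0")


def categorize(fpkm: float, cfg: ExpressionConfig | None = None) -> str:
    """Class of a single FPKM value; boundaries land in the lower class."""
    cfg = cfg or ExpressionConfig()
    if fpkm < 0 or not np.isfinite(fpkm):
        raise ValueError(f"fpkm must be a finite non-negative number, got {fpkm}")
    if fpkm <= cfg.low_max:
        return "low"
    if fpkm <= cfg.moderate_max:
        return "moderate"
    return "high"


def _as_frame(table: "pd.DataFrame | Iterable[ExpressionRecord]") -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table.copy()
        required = {"gene_id", "library_id", "fpkm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"expression table missing columns: {sorted(missing)}")
    else:
        df = pd.DataFrame(
            [(r.gene_id, r.library_id, r.fpkm) for r in table],
            columns=["gene_id", "library_id", "fpkm"],
        )
    if (df["fpkm"] < 0).any():
        raise ValueError("negative FPKM values present")
    return df


def categorize_table(
    table: "pd.DataFrame | Iterable[ExpressionRecord]",
    cfg: ExpressionConfig | None = None,
) -> pd.DataFrame:
    """Long-form table with a ``category`` column added."""
    cfg = cfg or ExpressionConfig()
    df = _as_frame(table)
    df["category"] = [categorize(v, cfg) for v in df["fpkm"]]
    return df


def expressed_flags(
    table: "pd.DataFrame | Iterable[ExpressionRecord]",
    cfg: ExpressionConfig | None = None,
) -> pd.Series:
    """Per-gene expressed flag: FPKM >= threshold in enough libraries."""
    cfg = cfg or ExpressionConfig()
    df = _as_frame(table)
    if df.empty:
        return pd.Series(dtype=bool, name="expressed")
    hits = (
        df.assign(above=df["fpkm"] >= cfg.expressed_min_fpkm)
        .groupby("gene_id")["above"]
        .sum()
    )
    flags = hits >= cfg.expressed_min_libraries
    flags.name = "expressed"
    return flags


def expression_matrix(
    table: "pd.DataFrame | Iterable[ExpressionRecord]",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dense gene x library FPKM matrix plus a missingness mask.

    Missing (gene, library) combinations are filled with 0 and marked True
    in the mask.  Duplicate rows for the same combination are an error —
    replicate libraries must carry distinct library ids (suffix letters).
    """
    df = _as_frame(table)
    if df.duplicated(["gene_id", "library_id"]).any():
        dup = df[df.duplicated(["gene_id", "library_id"])].iloc[0]
        raise ValueError(
            f"duplicate expression row for ({dup['gene_id']}, {dup['library_id']})"
        )
    if df.empty:
        empty = pd.DataFrame()
        return empty, empty.astype(bool)
    mat = df.pivot(index="gene_id", columns="library_id", values="fpkm")
    mask = mat.isna()
    return mat.fillna(0.0), mask
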