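"""Differential-expression thresholding and gene-set bookkeeping.

Turns per-gene (log2 fold change, adjusted p) tables into directional gene
sets, and provides the intersection / inclusion-exclusion helpers used when
combining DEG sets from independent contrasts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEGRecord",
    "GeneSet",
    "read_deg_table",
    "filter_deg",
    "intersect_sets",
    "union_count",
    "write_gene_list",
    "write_summary",
]


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression statistics."""

    gene_id: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not self.gene_id or not self.gene_id.strip():
            raise ValueError("gene_id must be non-empty")
        if not np.isnan(self.padj) and not 0.0 <= self.padj <= 1.0:
            raise ValueError(f"padj must lie in [0, 1], got {self.padj!r}")


@dataclass
class GeneSet:
    """A named set of gene symbols with a direction tag (up/down/any)."""

    name: str
    members: set[str] = field(default_factory=set)
    direction: str = "any"

    _DIRECTIONS = ("up", "down", "any")

    def __post_init__(self) -> None:
        if self.direction not in self._DIRECTIONS:
            raise ValueError(
                f"direction must be one of {self._DIRECTIONS}, got {self.direction!r}"
            )
        self.members = {str(m).strip() for m in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


def read_deg_table(
    path: str | Path,
    gene_col: str = "gene_id",
    lfc_col: str = "log2fc",
    padj_col: str = "padj",
) -> pd.DataFrame:
    """Read a DE result TSV and normalise its column names.

    Returns a frame with columns ``gene_id``, ``log2fc``, ``padj``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in (gene_col, lfc_col, padj_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out = df[[gene_col, lfc_col, padj_col]].rename(
        columns={gene_col: "gene_id", lfc_col: "log2fc", padj_col: "padj"}
    )
    out["gene_id"] = out["gene_id"].astype(str).str.strip()
    if out["gene_id"].duplicated().any():
        dups = out.loc[out["gene_id"].duplicated(), "gene_id"].unique()
        raise ValueError(f"{path}: duplicate gene_id entries: {list(dups)[:5]}")
    return out


def filter_deg(
    table: pd.DataFrame,
    lfc_thresh: float = 1.0,
    padj_thresh: float = 0.05,
    name: str = "deg",
) -> tuple[GeneSet, GeneSet]:
    """Split a DE table into up- and down-regulated gene sets.

    Both inequalities are strict: up requires ``log2fc > lfc_thresh`` and
    ``padj < padj_thresh``; down mirrors with ``log2fc < -lfc_thresh``.
    Rows with missing statistics are dropped (count logged as a warning).
    """
    if table.empty:
        raise ValueError("DE table is empty")
    if lfc_thresh <= 0 or padj_thresh <= 0:
        raise ValueError("thresholds must be positive")

    lfc = pd.to_numeric(table["log2fc"], errors="coerce")
    padj = pd.to_numeric(table["padj"], errors="coerce")
    valid = lfc.notna() & padj.notna()
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("filter_deg(%s): dropped %d rows with missing statistics", name, n_dropped)

    genes = table["gene_id"].astype(str).str.strip()
    sig = valid & (padj < padj_thresh)
    up = GeneSet(f"{name}:up", set(genes[sig & (lfc > lfc_thresh)]), "up")
    down = GeneSet(f"{name}:down", set(genes[sig & (lfc < -lfc_thresh)]), "down")
    return up, down


def filter_summary(
    table: pd.DataFrame, lfc_thresh: float = 1.0, padj_thresh: float = 0.05
) -> dict:
    """JSON-ready summary of a filtering pass: {n_input, n_up, n_down, n_dropped}."""
    up, down = filter_deg(table, lfc_thresh, padj_thresh)
    lfc = pd.to_numeric(table["log2fc"], errors="coerce")
    padj = pd.to_numeric(table["padj"], errors="coerce")
    return {
        "n_input": int(len(table)),
        "n_up": len(up),
        "n_down": len(down),
        "n_dropped": int((lfc.isna() | padj.isna()).sum()),
    }


def intersect_sets(a: GeneSet, b: GeneSet) -> GeneSet:
    """Intersection of two gene sets with matching direction tags."""
    if a.direction != b.direction:
        raise ValueError(
            f"cannot intersect sets with different directions: "
            f"{a.direction!r} vs {b.direction!r}"
        )
    return GeneSet(f"({a.name} & {b.name})", a.members & b.members, a.direction)


def union_count(size_a: int, size_b: int, size_intersection: int) -> int:
    """Inclusion-exclusion union size from two set sizes and their overlap."""
    if min(size_a, size_b, size_intersection) < 0:
        raise ValueError("sizes must be non-negative")
    if size_intersection > min(size_a, size_b):
        raise ValueError(
            f"intersection ({size_intersection}) cannot exceed the smaller set "
            f"(min({size_a}, {size_b}))"
        )
    return size_a + size_b - size_intersection


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
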