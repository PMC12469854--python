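"""Assembly of the target-gene universe from multiple curated sources.

Each source table passes through a source-specific row filter, labels are
canonicalized and deduplicated, then converted through a user-supplied ID
mapping; the surviving IDs (deduplicated once more, sorted) define the
feature index used everywhere downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SOURCE_TAGS = (
    "deg_gse72815",
    "deg_gse141595",
    "genage",
    "longevitymap",
    "cellage",
    "agingatlas",
)

__all__ = [
    "SOURCE_TAGS",
    "SourceEntry",
    "SourceRules",
    "GeneUniverse",
    "canonical_label",
    "load_source",
    "assemble",
    "convert_ids",
    "read_id_mapping",
    "build_universe",
]


def canonical_label(label: str) -> str:
    """Canonical form used for label-level dedup: strip + uppercase."""
    return str(label).strip().upper()


@dataclass(frozen=True)
class SourceEntry:
    gene_label: str
    source_tag: str

    def __post_init__(self) -> None:
        if not self.gene_label or not self.gene_label.strip():
            raise ValueError("gene_label must be non-empty")
        if self.source_tag not in SOURCE_TAGS:
            raise ValueError(
                f"unknown source_tag {self.source_tag!r}; expected one of {SOURCE_TAGS}"
            )


@dataclass
class SourceRules:
    """Column names and per-source filter settings for one source table.

    ``direction`` only applies to the DEG sources (up keeps logFC > lfc_thresh,
    down keeps logFC < -lfc_thresh).
    """

    gene_col: str = "gene"
    filter_col: str | None = None
    direction: str = "up"
    lfc_thresh: float = 1.0


_DEFAULT_FILTER_COLS = {
    "longevitymap": "Association",
    "cellage": "Senescence Effect",
    "deg_gse72815": "logFC",
    "deg_gse141595": "logFC",
}


def load_source(
    path: str | Path, source_tag: str, rules: SourceRules | None = None
) -> list[SourceEntry]:
    """Load one source TSV, applying its row filter.

    longevitymap keeps only Association == "significant" (case-insensitive);
    cellage drops Senescence Effect == "Unclear"; DEG sources keep rows whose
    logFC clears the directional strict threshold; genage and agingatlas
    pass through unfiltered.
    """
    if source_tag not in SOURCE_TAGS:
        raise ValueError(f"unknown source_tag {source_tag!r}; expected one of {SOURCE_TAGS}")
    rules = rules or SourceRules()
    df = pd.read_csv(path, sep="\t")
    if rules.gene_col not in df.columns:
        raise ValueError(f"{path}: missing gene column {rules.gene_col!r}")

    filter_col = rules.filter_col or _DEFAULT_FILTER_COLS.get(source_tag)
    if source_tag in ("longevitymap", "cellage", "deg_gse72815", "deg_gse141595"):
        if filter_col not in df.columns:
            raise ValueError(f"{path}: missing filter column {filter_col!r} for {source_tag}")

    if source_tag == "longevitymap":
        keep = df[filter_col].astype(str).str.strip().str.lower() == "significant"
        df = df[keep]
    elif source_tag == "cellage":
        keep = df[filter_col].astype(str).str.strip().str.lower() != "unclear"
        df = df[keep]
    elif source_tag in ("deg_gse72815", "deg_gse141595"):
        lfc = pd.to_numeric(df[filter_col], errors="coerce")
        if rules.direction == "up":
            df = df[lfc > rules.lfc_thresh]
        elif rules.direction == "down":
            df = df[lfc < -rules.lfc_thresh]
        else:
            raise ValueError(f"direction must be 'up' or 'down', got {rules.direction!r}")

    labels = df[rules.gene_col].astype(str).str.strip()
    labels = labels[labels != ""]
    return [SourceEntry(lbl, source_tag) for lbl in labels]


def assemble(entries: Sequence[SourceEntry]) -> tuple[int, list[str]]:
    """Merge entries from all sources: raw total plus first-occurrence dedup.

    Labels are canonicalized (strip + uppercase) before comparison; the
    deduplicated list preserves first-occurrence order.
    """
    if not entries:
        raise ValueError("no source entries to assemble")
    total = len(entries)
    seen: dict[str, None] = {}
    for e in entries:
        seen.setdefault(canonical_label(e.gene_label), None)
    return total, list(seen)


@dataclass
class GeneUniverse:
    """Ordered, deduplicated gene-ID list defining stable feature indices."""

    genes: list[str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("universe genes must be unique")
        if self.genes != sorted(self.genes):
            raise ValueError("universe genes must be lexicographically sorted")
        self.index = {g: i for i, g in enumerate(self.genes)}

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "GeneUniverse":
        return cls(sorted(set(ids)))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def write(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{g}\n" for g in self.genes))

    @classmethod
    def read(cls, path: str | Path) -> "GeneUniverse":
        ids = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
        return cls.from_ids(ids)


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Two-column TSV (label, id) -> dict; duplicate labels are an error."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: mapping needs two columns (label, id)")
    labels = df.iloc[:, 0].astype(str).map(canonical_label)
    if labels.duplicated().any():
        dups = labels[labels.duplicated()].unique()
        raise ValueError(f"{path}: duplicate mapping keys: {list(dups)[:5]}")
    return dict(zip(labels, df.iloc[:, 1].astype(str).str.strip()))


def convert_ids(labels: Sequence[str], mapping: Mapping[str, str]) -> GeneUniverse:
    """Map labels through the ID table, dropping unmapped ones.

    Two labels may map to one ID, so the result is deduplicated again.
    Mapping keys are compared on canonicalized labels.
    """
    canon_map: dict[str, str] = {}
    for k, v in mapping.items():
        ck = canonical_label(k)
        if ck in canon_map:
            raise ValueError(f"ID mapping has duplicate keys after canonicalization: {k!r}")
        canon_map[ck] = v
    mapped, n_dropped = [], 0
    for lbl in labels:
        ident = canon_map.get(canonical_label(lbl))
        if ident is None:
            n_dropped += 1
        else:
            mapped.append(ident)
    if n_dropped:
        logger.warning("convert_ids: dropped %d unmappable label(s)", n_dropped)
    return GeneUniverse.from_ids(mapped)


def build_universe(
    source_paths: Mapping[str, str | Path],
    mapping: Mapping[str, str],
    rules: Mapping[str, SourceRules] | None = None,
) -> tuple[GeneUniverse, dict]:
    """Full pipeline: load every source, assemble, convert; returns summary too."""
    rules = rules or {}
    entries: list[SourceEntry] = []
    per_source: dict[str, int] = {}
    for tag, path in source_paths.items():
        src = load_source(path, tag, rules.get(tag))
        per_source[tag] = len(src)
        entries.extend(src)
    total, dedup = assemble(entries)
    universe = convert_ids(dedup, mapping)
    summary = {
        "total": total,
        "after_dedup": len(dedup),
        "after_id_conversion": len(universe),
        "per_source_counts": per_source,
    }
    return universe, summary


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
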