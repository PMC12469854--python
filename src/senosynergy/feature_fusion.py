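"""Drug-pair / cell-line feature construction and standardization.

A drug becomes a binary target-membership vector over the gene universe;
a combination row is the concatenation [x_A | x_B | x_cell]; a Standardizer
fitted on training rows z-scores every feature (population std, zero-variance
features pinned to std 1).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geneset_assembly import GeneUniverse

logger = logging.getLogger(__name__)

__all__ = [
    "DrugRecord",
    "CellLineProfile",
    "Standardizer",
    "FeatureSpace",
    "canonical_drug_name",
    "drug_vector",
    "fuse",
    "load_drug_targets",
    "load_expression",
]

_WS = re.compile(r"\s+")


def canonical_drug_name(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Strip, case-fold, collapse internal whitespace; then apply synonym map."""
    canon = _WS.sub(" ", str(name).strip()).casefold()
    if synonyms:
        canon = synonyms.get(canon, canon)
    return canon


@dataclass
class DrugRecord:
    name: str
    targets: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.name = canonical_drug_name(self.name)
        if not self.name:
            raise ValueError("drug name must be non-empty")
        if not self.targets:
            logger.warning("drug %r has no targets", self.name)


@dataclass
class CellLineProfile:
    name: str
    expression: np.ndarray

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.ndim != 1:
            raise ValueError("expression must be a 1-D vector")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError(f"cell line {self.name!r} has non-finite expression values")


def drug_vector(drug: DrugRecord, universe: GeneUniverse) -> np.ndarray:
    """Binary membership vector of the drug's targets over the universe."""
    if len(universe) == 0:
        raise ValueError("universe is empty")
    vec = np.zeros(len(universe), dtype=float)
    outside = 0
    for t in drug.targets:
        i = universe.index.get(t)
        if i is None:
            outside += 1
        else:
            vec[i] = 1.0
    if outside:
        logger.warning(
            "drug %r: %d target(s) outside the universe ignored", drug.name, outside
        )
    return vec


def fuse(
    drugA: DrugRecord,
    drugB: DrugRecord,
    cell: CellLineProfile,
    universe: GeneUniverse,
) -> np.ndarray:
    """Fused feature row [x_A | x_B | x_cell], length 3 * |universe|."""
    if cell.expression.shape[0] != len(universe):
        raise ValueError(
            f"cell profile length {cell.expression.shape[0]} does not match "
            f"universe size {len(universe)}"
        )
    return np.concatenate(
        [drug_vector(drugA, universe), drug_vector(drugB, universe), cell.expression]
    )


class Standardizer:
    """Per-feature z-scoring fitted once on training rows.

    Uses the population standard deviation (ddof 0); zero-variance features
    store std 1 so their standardized value is exactly 0.
    """

    def __init__(self) -> None:
        self.means: np.ndarray | None = None
        self.stds: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.means is not None

    def fit(self, rows: np.ndarray) -> "Standardizer":
        rows = np.asarray(rows, dtype=float)
        if rows.ndim != 2 or rows.shape[0] == 0:
            raise ValueError("fit expects a non-empty 2-D matrix")
        if self.fitted:
            raise RuntimeError("Standardizer is fitted exactly once")
        self.means = rows.mean(axis=0)
        stds = rows.std(axis=0, ddof=0)
        stds[stds == 0.0] = 1.0
        self.stds = stds
        return self

    def transform(self, rows: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("Standardizer must be fitted before use")
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[1] != self.means.shape[0]:
            raise ValueError("row width does not match fitted feature count")
        return (rows - self.means) / self.stds

    def inverse_transform(self, rows: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("Standardizer must be fitted before use")
        return np.atleast_2d(np.asarray(rows, dtype=float)) * self.stds + self.means

    def to_json(self, path: str | Path | None = None) -> str:
        if not self.fitted:
            raise RuntimeError("cannot serialize an unfitted Standardizer")
        payload = json.dumps(
            {"means": self.means.tolist(), "stds": self.stds.tolist()}, indent=2
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "Standardizer":
        raw = str(source)
        text = raw if raw.lstrip().startswith("{") else Path(source).read_text()
        obj = json.loads(text)
        s = cls()
        s.means = np.asarray(obj["means"], dtype=float)
        s.stds = np.asarray(obj["stds"], dtype=float)
        if np.any(s.stds <= 0):
            raise ValueError("stds must be positive")
        return s


@dataclass
class FeatureSpace:
    """Bundles the drug table, cell-line profiles and universe for row lookup."""

    drugs: Mapping[str, DrugRecord]
    profiles: Mapping[str, CellLineProfile]
    universe: GeneUniverse

    def drug(self, name: str) -> DrugRecord:
        rec = self.drugs.get(canonical_drug_name(name))
        if rec is None:
            raise KeyError(f"drug {name!r} not found in the drug-target table")
        return rec

    def profile(self, name: str) -> CellLineProfile:
        prof = self.profiles.get(name)
        if prof is None:
            raise KeyError(f"cell line {name!r} not found in the expression matrix")
        return prof

    def row(self, drugA: str, drugB: str, cell_line: str) -> np.ndarray:
        return fuse(self.drug(drugA), self.drug(drugB), self.profile(cell_line), self.universe)


def load_drug_targets(
    path: str | Path,
    synonyms: Mapping[str, str] | None = None,
    drug_col: str = "drug",
    target_col: str = "target_gene",
) -> dict[str, DrugRecord]:
    """One (drug, target_gene) pair per row -> canonical name -> DrugRecord."""
    df = pd.read_csv(path, sep="\t")
    for col in (drug_col, target_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    drugs: dict[str, DrugRecord] = {}
    for name, group in df.groupby(df[drug_col].map(lambda n: canonical_drug_name(n, synonyms))):
        targets = {str(t).strip() for t in group[target_col] if str(t).strip()}
        drugs[name] = DrugRecord(name, targets)
    return drugs


def load_expression(path: str | Path, universe: GeneUniverse) -> dict[str, CellLineProfile]:
    """Genes-by-cell-lines TSV (first column = gene IDs) -> aligned profiles.

    Genes absent from the matrix are filled with 0; matrix genes outside the
    universe are ignored.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    profiles = {}
    for cell in df.columns:
        vec = np.zeros(len(universe))
        col = df[cell]
        for gene, value in col.items():
            i = universe.index.get(gene)
            if i is not None:
                vec[i] = float(value)
        profiles[str(cell)] = CellLineProfile(str(cell), vec)
    return profiles


def mean_profile(profiles: Iterable[CellLineProfile], name: str = "MEAN") -> CellLineProfile:
    mats = np.stack([p.expression for p in profiles])
    return CellLineProfile(name, mats.mean(axis=0))
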