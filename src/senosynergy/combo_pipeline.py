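"""Senolytic-pair enumeration, training-set filtering, prediction and ranking.

The application stage: all unordered pairs of a senolytic list are formed,
pairs whose members are not both present in the training drug table are
dropped, the remaining pairs are scored with the trained regressor in a
chosen cell-line context, and rows above a strict score threshold are ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .feature_fusion import FeatureSpace, canonical_drug_name, mean_profile

logger = logging.getLogger(__name__)

__all__ = [
    "ComboRecord",
    "PredictionRow",
    "enumerate_pairs",
    "filter_known",
    "rank_and_threshold",
    "predict_combinations",
]


@dataclass(frozen=True)
class ComboRecord:
    """One (drugA, drugB, cell line) unit; score present for training rows."""

    drugA: str
    drugB: str
    cell_line: str
    score: float | None = None

    def __post_init__(self) -> None:
        if canonical_drug_name(self.drugA) == canonical_drug_name(self.drugB):
            raise ValueError(f"self-pair not allowed: {self.drugA!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((canonical_drug_name(self.drugA), canonical_drug_name(self.drugB))))


@dataclass(frozen=True)
class PredictionRow:
    drugA: str
    drugB: str
    predicted_score: float
    rank: int = 0


def enumerate_pairs(drugs: Sequence[str]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered pairs, lexicographically ordered by pair.

    Names are canonicalized for the duplicate check; the original spellings
    are preserved in the output.
    """
    canon = [canonical_drug_name(d) for d in drugs]
    seen: dict[str, str] = {}
    dups = []
    for orig, c in zip(drugs, canon):
        if c in seen:
            dups.append(orig)
        seen[c] = orig
    if dups:
        raise ValueError(f"duplicate drug names after canonicalization: {dups}")
    ordered = sorted(drugs, key=canonical_drug_name)
    return list(combinations(ordered, 2))


def filter_known(
    pairs: Iterable[tuple[str, str]], training_drugs: Iterable[str]
) -> list[tuple[str, str]]:
    """Keep exactly the pairs with BOTH members in the training drug set."""
    known = {canonical_drug_name(d) for d in training_drugs}
    return [
        (a, b)
        for a, b in pairs
        if canonical_drug_name(a) in known and canonical_drug_name(b) in known
    ]


def rank_and_threshold(
    rows: Sequence[PredictionRow], threshold: float = 8.0
) -> list[PredictionRow]:
    """Keep rows with score strictly above threshold; rank by descending score.

    Ties broken lexicographically by (drugA, drugB); ranks run 1..k.
    """
    kept = [r for r in rows if r.predicted_score > threshold]
    kept.sort(key=lambda r: (-r.predicted_score, r.drugA, r.drugB))
    return [
        PredictionRow(r.drugA, r.drugB, r.predicted_score, rank=i)
        for i, r in enumerate(kept, 1)
    ]


def predict_combinations(
    model,
    senolytics: Sequence[str],
    features: FeatureSpace,
    training_drugs: Iterable[str],
    cell_line: str = "MEAN",
    threshold: float = 8.0,
) -> list[PredictionRow]:
    """End-to-end application stage: enumerate -> filter -> predict -> rank.

    ``cell_line`` names a profile from the expression matrix, or "MEAN" for
    the mean profile over all training cell lines.
    """
    from .synergy_model import predict_pair

    pairs = enumerate_pairs(senolytics)
    kept = filter_known(pairs, training_drugs)
    logger.info(
        "predict_combinations: %d pairs enumerated, %d retained after the "
        "training-set membership filter", len(pairs), len(kept),
    )
    if cell_line == "MEAN":
        cell = mean_profile(features.profiles.values())
    else:
        cell = features.profile(cell_line)
    rows = [
        PredictionRow(
            a, b, predict_pair(model, features.drug(a), features.drug(b), cell, features.universe)
        )
        for a, b in kept
    ]
    return rank_and_threshold(rows, threshold)


def rows_to_frame(rows: Sequence[PredictionRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drugA_Name": [r.drugA for r in rows],
            "drug_B_Name": [r.drugB for r in rows],
            "Predicted_Synergy_Score": [r.predicted_score for r in rows],
            "rank": [r.rank for r in rows],
        }
    )


def write_ranked(rows: Sequence[PredictionRow], path: str | Path) -> None:
    rows_to_frame(rows).to_csv(path, sep="\t", index=False)
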