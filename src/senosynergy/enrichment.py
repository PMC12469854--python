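"""Over-representation analysis with Benjamini-Hochberg correction.

One-sided hypergeometric upper-tail test of a study gene set against
annotation terms (GMT collections) within a declared background universe,
BH-adjusted across all tested terms, then filtered to terms hit by at
least ``min_count`` study genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .deg_sets import GeneSet
from .geneset_assembly import GeneUniverse

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTerm",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
    "read_gmt",
    "results_to_frame",
]

NAMESPACES = ("BP", "CC", "MF", "pathway")


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    description: str
    members: frozenset[str]
    namespace: str = "pathway"

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(f"namespace must be one of {NAMESPACES}")


@dataclass
class EnrichmentResult:
    term_id: str
    description: str
    hit_genes: set[str]
    p_value: float
    p_adjusted: float
    count: int = field(init=False)

    def __post_init__(self) -> None:
        self.count = len(self.hit_genes)
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("p_adjusted must be >= p_value")


def hypergeom_upper_tail(x: int, n: int, K: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= x <= min(n, K) and n <= N and K <= N):
        raise ValueError(
            f"invalid hypergeometric instance: x={x}, n={n}, K={K}, N={N}"
        )
    # sf(x-1) = P(X >= x)
    return float(hypergeom.sf(x - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down, cap at 1
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def enrich(
    study: GeneSet,
    terms: Sequence[AnnotationTerm],
    universe: GeneUniverse,
    min_count: int = 2,
) -> list[EnrichmentResult]:
    """ORA of ``study`` against ``terms`` with ``universe`` as background.

    Study genes outside the universe are dropped with a warning. BH runs
    across ALL tested terms; the min_count filter applies afterwards.
    Output sorted by descending count, then ascending p, then term_id.
    """
    if len(universe) == 0:
        raise ValueError("universe is empty")
    study_in = study.members & set(universe.genes)
    n_out = len(study.members) - len(study_in)
    if n_out:
        logger.warning("enrich: %d study gene(s) outside the universe dropped", n_out)

    N, n = len(universe), len(study_in)
    tested: list[tuple[AnnotationTerm, set[str], float]] = []
    for term in terms:
        members_in = set(term.members) & set(universe.genes)
        hits = members_in & study_in
        p = hypergeom_upper_tail(len(hits), n, len(members_in), N)
        tested.append((term, hits, p))

    adjusted = bh_adjust([p for _, _, p in tested])
    results = [
        EnrichmentResult(term.term_id, term.description, hits, p, padj)
        for (term, hits, p), padj in zip(tested, adjusted)
        if len(hits) >= min_count
    ]
    results.sort(key=lambda r: (-r.count, r.p_value, r.term_id))
    return results


def read_gmt(path: str | Path, namespace: str = "pathway") -> list[AnnotationTerm]:
    """Read a GMT file: term_id <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    terms = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        term_id = fields[0].strip()
        if term_id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate term_id {term_id!r}")
        seen.add(term_id)
        members = frozenset(g.strip() for g in fields[2:] if g.strip())
        terms.append(AnnotationTerm(term_id, fields[1].strip(), members, namespace))
    return terms


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view with slash-joined hit genes (ID / Description / Gene ID / Count / p / p.adjust)."""
    return pd.DataFrame(
        {
            "ID": [r.term_id for r in results],
            "Description": [r.description for r in results],
            "Gene ID": ["/".join(sorted(r.hit_genes)) for r in results],
            "Count": [r.count for r in results],
            "p": [r.p_value for r in results],
            "p.adjust": [r.p_adjusted for r in results],
        }
    )
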