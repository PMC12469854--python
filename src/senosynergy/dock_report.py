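"""Docking-report post-processing: mode parsing, reference selection, RMSD classes.

Accepts Vina-style mode tables (whitespace-aligned stdout or TSV), selects
the reference mode by minimum binding affinity, and partitions the remaining
modes into structurally similar vs deviating by an RMSD lower-bound cutoff.
No docking is run here.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

__all__ = [
    "DockMode",
    "parse_mode_table",
    "reference_mode",
    "classify_modes",
    "report",
]

# Vina prints ASCII '-'; extracted tables often carry U+2212
_MINUS = {ord("−"): "-", ord("–"): "-"}


@dataclass(frozen=True)
class DockMode:
    mode: int
    affinity: float  # kcal/mol
    rmsd_lb: float  # Angstrom
    rmsd_ub: float  # Angstrom

    def __post_init__(self) -> None:
        if self.mode <= 0:
            raise ValueError("mode numbers are positive")
        if self.rmsd_lb < 0 or self.rmsd_ub < 0:
            raise ValueError("RMSD bounds are non-negative")
        if self.rmsd_lb > self.rmsd_ub:
            raise ValueError(
                f"mode {self.mode}: rmsd_lb ({self.rmsd_lb}) exceeds rmsd_ub ({self.rmsd_ub})"
            )


_HEADER = re.compile(r"^\s*(mode|[-+=_\s|]+$|affinity|\(kcal/mol\)|rmsd|\|)", re.I)


def parse_mode_table(text: str) -> list[DockMode]:
    """Parse a mode table from raw text (TSV or whitespace-aligned columns)."""
    modes: list[DockMode] = []
    seen: set[int] = set()
    for lineno, raw in enumerate(str(text).splitlines(), 1):
        line = raw.translate(_MINUS).strip()
        if not line or _HEADER.match(line):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 4:
            raise ValueError(f"line {lineno}: expected 4 columns, got {len(fields)}")
        try:
            mode = int(fields[0])
            affinity, rmsd_lb, rmsd_ub = (float(f) for f in fields[1:])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed numeric field ({exc})") from None
        if mode in seen:
            raise ValueError(f"line {lineno}: duplicate mode {mode}")
        seen.add(mode)
        try:
            modes.append(DockMode(mode, affinity, rmsd_lb, rmsd_ub))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    if not modes:
        raise ValueError("no data rows found in mode table")
    return modes


def parse_mode_file(path: str | Path) -> list[DockMode]:
    return parse_mode_table(Path(path).read_text())


def reference_mode(modes: Sequence[DockMode]) -> DockMode:
    """Mode with minimum (most negative) affinity; ties go to the lowest mode number."""
    if not modes:
        raise ValueError("no modes given")
    return min(modes, key=lambda m: (m.affinity, m.mode))


def classify_modes(
    modes: Sequence[DockMode],
    ref: DockMode,
    rmsd_threshold: float = 10.0,
) -> dict:
    """Partition non-reference modes by RMSD lower bound against ``rmsd_threshold``.

    Returns {"similar", "deviating", "affinity_span"} where affinity_span is
    the (min, max) affinity over the reference plus the similar modes.
    """
    if ref not in modes:
        raise ValueError("reference mode must be one of the given modes")
    similar = [m for m in modes if m is not ref and m != ref and m.rmsd_lb < rmsd_threshold]
    deviating = [m for m in modes if m != ref and m not in similar]
    span_modes = [ref, *similar]
    affinities = [m.affinity for m in span_modes]
    return {
        "similar": similar,
        "deviating": deviating,
        "affinity_span": (min(affinities), max(affinities)),
    }


def report(modes: Sequence[DockMode], rmsd_threshold: float = 10.0) -> dict:
    """JSON-ready summary: reference mode, similarity classes, affinity span."""
    ref = reference_mode(modes)
    cls = classify_modes(modes, ref, rmsd_threshold)
    as_dict = lambda m: {
        "mode": m.mode, "affinity": m.affinity, "rmsd_lb": m.rmsd_lb, "rmsd_ub": m.rmsd_ub
    }
    return {
        "reference": as_dict(ref),
        "similar": [as_dict(m) for m in cls["similar"]],
        "deviating": [as_dict(m) for m in cls["deviating"]],
        "affinity_span": list(cls["affinity_span"]),
        "rmsd_threshold": rmsd_threshold,
    }


def write_report(modes: Sequence[DockMode], path: str | Path, rmsd_threshold: float = 10.0) -> None:
    Path(path).write_text(json.dumps(report(modes, rmsd_threshold), indent=2) + "\n")
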