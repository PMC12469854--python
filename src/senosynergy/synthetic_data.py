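"""Seeded synthetic generators for every pipeline input.

Provides a drug/gene/cell-line "world" with a known ground-truth synergy
function, planted differential-expression tables, and multi-source gene
tables with controlled duplication and unmappable labels — so the full
pipeline is exercisable and gradeable without any external downloads.

Ground-truth synergy for a combo (A, B, c):

    S = beta0 + beta1 * |T_A ∩ T_B| + beta2 * h_A * h_B + Normal(0, sigma^2)

where T_X is drug X's target set and h_X = |T_X ∩ M_c| counts targets inside
cell line c's vulnerability module M_c (whose genes are shifted +2 in the
expression profile). The formula is symmetric in A and B and is recoverable
from the fused features, which makes model-recovery checks meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .combo_pipeline import ComboRecord
from .feature_fusion import CellLineProfile, DrugRecord
from .geneset_assembly import SOURCE_TAGS, GeneUniverse, canonical_label

__all__ = [
    "SyntheticConfig",
    "World",
    "ComboSet",
    "gen_world",
    "gen_combos",
    "gen_deg_tables",
    "gen_source_tables",
    "write_fixture_dir",
]


@dataclass
class SyntheticConfig:
    n_genes: int = 60
    n_drugs: int = 40
    targets_per_drug_mean: float = 8.0
    n_cell_lines: int = 6
    module_size: int = 12
    beta0: float = 0.0
    beta1: float = 1.0
    beta2: float = 0.5
    sigma: float = 1.0
    n_combos: int = 1000
    duplication_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_drugs", "n_cell_lines", "module_size", "n_combos"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0.0 <= self.duplication_rate < 1.0:
            raise ValueError("duplication_rate must lie in [0, 1)")
        if self.module_size > self.n_genes:
            raise ValueError("module_size cannot exceed n_genes")


@dataclass
class World:
    universe: GeneUniverse
    drugs: dict[str, DrugRecord]
    cells: dict[str, CellLineProfile]
    modules: dict[str, frozenset[str]]
    config: SyntheticConfig


@dataclass
class ComboSet:
    records: list[ComboRecord]
    true_scores: np.ndarray  # noiseless ground truth, aligned with records


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # one seeded stream per generation call; streams keyed off the config seed
    return np.random.default_rng([config.seed, stream])


def gen_world(config: SyntheticConfig) -> World:
    """Universe, drug-target sets, and cell-line profiles with planted modules."""
    rng = _rng(config, 0)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    universe = GeneUniverse.from_ids(gene_ids)

    drugs: dict[str, DrugRecord] = {}
    for d in range(config.n_drugs):
        k = max(1, int(rng.poisson(config.targets_per_drug_mean)))
        k = min(k, config.n_genes)
        targets = set(rng.choice(gene_ids, size=k, replace=False))
        name = f"drug-{d:03d}"
        drugs[name] = DrugRecord(name, targets)

    cells: dict[str, CellLineProfile] = {}
    modules: dict[str, frozenset[str]] = {}
    for c in range(config.n_cell_lines):
        name = f"cell-{c:02d}"
        expr = rng.normal(0.0, 1.0, size=config.n_genes)
        module = frozenset(rng.choice(gene_ids, size=config.module_size, replace=False))
        for g in module:
            expr[universe.index[g]] += 2.0
        cells[name] = CellLineProfile(name, expr)
        modules[name] = module
    return World(universe, drugs, cells, modules, config)


def true_score(world: World, drugA: str, drugB: str, cell: str) -> float:
    """Noiseless ground-truth synergy of a combination."""
    cfg = world.config
    ta, tb = world.drugs[drugA].targets, world.drugs[drugB].targets
    module = world.modules[cell]
    h_a, h_b = len(ta & module), len(tb & module)
    return cfg.beta0 + cfg.beta1 * len(ta & tb) + cfg.beta2 * h_a * h_b


def gen_combos(world: World, config: SyntheticConfig | None = None) -> ComboSet:
    """Sample labelled combination records over distinct (pair, cell) triples."""
    config = config or world.config
    rng = _rng(config, 1)
    drug_names = sorted(world.drugs)
    if len(drug_names) < 2:
        raise ValueError("need at least 2 drugs to form combinations")
    cell_names = sorted(world.cells)
    pairs = list(combinations(drug_names, 2))
    total = len(pairs) * len(cell_names)
    if config.n_combos > total:
        raise ValueError(
            f"n_combos={config.n_combos} exceeds the {total} distinct (pair, cell) triples"
        )
    chosen = rng.choice(total, size=config.n_combos, replace=False)
    records, truths = [], np.empty(config.n_combos)
    noise = rng.normal(0.0, config.sigma, size=config.n_combos) if config.sigma > 0 else None
    for j, flat in enumerate(chosen):
        (a, b), cell = pairs[flat // len(cell_names)], cell_names[flat % len(cell_names)]
        s = true_score(world, a, b, cell)
        truths[j] = s
        label = s + (noise[j] if noise is not None else 0.0)
        records.append(ComboRecord(a, b, cell, score=label))
    return ComboSet(records, truths)


# ---------------------------------------------------------------------------
# differential-expression tables with planted up/down/null genes
# ---------------------------------------------------------------------------

def _planted_rows(rng, genes, kind):
    rows = []
    for g in genes:
        if kind == "up":
            rows.append((g, rng.uniform(1.2, 3.0), rng.uniform(0.0, 0.04)))
        elif kind == "down":
            rows.append((g, -rng.uniform(1.2, 3.0), rng.uniform(0.0, 0.04)))
        else:  # null: fails either the fold-change or the p-value cutoff
            if rng.random() < 0.5:
                rows.append((g, rng.uniform(-0.8, 0.8), rng.uniform(0.0, 1.0)))
            else:
                rows.append((g, rng.uniform(-3.0, 3.0), rng.uniform(0.11, 1.0)))
    return rows


def gen_deg_tables(
    config: SyntheticConfig,
    n_up: tuple[int, int] = (20, 20),
    n_down: tuple[int, int] = (10, 10),
    n_common_up: int = 8,
    n_common_down: int = 2,
    n_null: int = 70,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """A pair of DE tables with planted truth and a controlled intersection.

    Planted up genes draw log2fc ~ U(1.2, 3) and padj ~ U(0, 0.04) (always
    pass the default filter), down genes are mirrored, and null genes always
    fail. ``n_common_up``/``n_common_down`` genes are planted in BOTH tables.
    """
    if n_common_up > min(n_up) or n_common_down > min(n_down):
        raise ValueError("common counts cannot exceed the per-table planted counts")
    if max(n_up) + max(n_down) + n_null > 10_000:
        raise ValueError("planted counts too large")
    rng = _rng(config, 2)

    def syms(prefix, n):
        return [f"{prefix}{i:04d}" for i in range(n)]

    common_up = syms("CUP", n_common_up)
    common_down = syms("CDN", n_common_down)
    truth = {"up": [], "down": [], "common_up": common_up, "common_down": common_down}
    tables = []
    for t in range(2):
        up = common_up + syms(f"UP{t}_", n_up[t] - n_common_up)
        down = common_down + syms(f"DN{t}_", n_down[t] - n_common_down)
        null = syms(f"NL{t}_", n_null)
        rows = (
            _planted_rows(rng, up, "up")
            + _planted_rows(rng, down, "down")
            + _planted_rows(rng, null, "null")
        )
        order = rng.permutation(len(rows))
        df = pd.DataFrame(
            [rows[i] for i in order], columns=["gene_id", "log2fc", "padj"]
        )
        truth["up"].append(sorted(up))
        truth["down"].append(sorted(down))
        tables.append(df)
    return tables[0], tables[1], truth


# ---------------------------------------------------------------------------
# six-source gene tables with duplicates and unmappable labels
# ---------------------------------------------------------------------------

def gen_source_tables(
    config: SyntheticConfig, unmappable_fraction: float = 0.1
) -> tuple[dict[str, pd.DataFrame], dict[str, str], dict]:
    """Six source tables, an ID mapping, and the generator's ground truth.

    Each table carries the column its loader filters on (plus decoy rows that
    the filter must remove); surviving labels are duplicated at
    ``duplication_rate`` (re-emitted lowercased, to exercise canonicalization)
    and ``unmappable_fraction`` of distinct labels is left out of the mapping.
    """
    if not 0.0 <= unmappable_fraction <= 1.0:
        raise ValueError("unmappable_fraction must lie in [0, 1]")
    rng = _rng(config, 3)
    pool = [f"SYM{i:05d}" for i in range(max(4 * config.n_genes, 40))]
    per_source = max(5, config.n_genes // 2)

    tables: dict[str, pd.DataFrame] = {}
    kept: list[str] = []  # labels surviving each source's filter, with duplicates
    for tag in SOURCE_TAGS:
        labels = list(rng.choice(pool, size=per_source, replace=False))
        dup = [l.lower() for l in labels if rng.random() < config.duplication_rate]
        rows = []
        if tag == "longevitymap":
            for l in labels + dup:
                rows.append({"gene": l, "Association": "significant"})
            for l in rng.choice(pool, size=per_source // 2, replace=False):
                rows.append({"gene": l, "Association": "non-significant"})
        elif tag == "cellage":
            effects = ("Induces", "Inhibits")
            for l in labels + dup:
                rows.append({"gene": l, "Senescence Effect": effects[int(rng.integers(2))]})
            for l in rng.choice(pool, size=per_source // 2, replace=False):
                rows.append({"gene": l, "Senescence Effect": "Unclear"})
        elif tag in ("deg_gse72815", "deg_gse141595"):
            for l in labels + dup:
                rows.append({"gene": l, "logFC": float(rng.uniform(1.2, 3.0))})
            for l in rng.choice(pool, size=per_source // 2, replace=False):
                rows.append({"gene": l, "logFC": float(rng.uniform(-0.9, 0.9))})
        else:  # genage / agingatlas pass through
            for l in labels + dup:
                rows.append({"gene": l})
        df = pd.DataFrame(rows)
        if tag in ("longevitymap", "cellage") or tag.startswith("deg_"):
            df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
        tables[tag] = df
        kept.extend(labels + dup)

    distinct = sorted({canonical_label(l) for l in kept})
    n_unmappable = int(round(unmappable_fraction * len(distinct)))
    unmappable = set(rng.choice(distinct, size=n_unmappable, replace=False)) if n_unmappable else set()
    mapping = {
        lbl: f"ID{i:05d}" for i, lbl in enumerate(distinct) if lbl not in unmappable
    }
    truth = {
        "total_kept_entries": len(kept),
        "distinct_labels": distinct,
        "n_distinct": len(distinct),
        "unmappable_labels": sorted(unmappable),
        "universe_ids": sorted(mapping.values()),
    }
    return tables, mapping, truth


# ---------------------------------------------------------------------------
# fixture-directory writer (backs `senosynergy simulate`)
# ---------------------------------------------------------------------------

def write_fixture_dir(config: SyntheticConfig, outdir: str | Path) -> dict:
    """Write every synthetic input as TSV/text plus a truth.json; returns truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    world = gen_world(config)
    combos = gen_combos(world)

    world.universe.write(out / "universe.txt")
    pd.DataFrame(
        [(d, t) for d, rec in sorted(world.drugs.items()) for t in sorted(rec.targets)],
        columns=["drug", "target_gene"],
    ).to_csv(out / "drug_targets.tsv", sep="\t", index=False)
    expr = pd.DataFrame(
        {name: prof.expression for name, prof in sorted(world.cells.items())},
        index=world.universe.genes,
    )
    expr.index.name = "gene_id"
    expr.to_csv(out / "expression.tsv", sep="\t")
    pd.DataFrame(
        [(r.drugA, r.drugB, r.cell_line, r.score) for r in combos.records],
        columns=["drugA", "drugB", "cell_line", "score"],
    ).to_csv(out / "combos.tsv", sep="\t", index=False)

    deg_a, deg_b, deg_truth = gen_deg_tables(config)
    deg_a.to_csv(out / "deg_table_a.tsv", sep="\t", index=False)
    deg_b.to_csv(out / "deg_table_b.tsv", sep="\t", index=False)

    sources, mapping, source_truth = gen_source_tables(config)
    for tag, df in sources.items():
        df.to_csv(out / f"source_{tag}.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(mapping.items()), columns=["label", "id"]).to_csv(
        out / "id_mapping.tsv", sep="\t", index=False
    )

    truth = {
        "config": asdict(config),
        "modules": {c: sorted(m) for c, m in world.modules.items()},
        "true_scores": combos.true_scores.tolist(),
        "deg": deg_truth,
        "sources": source_truth,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth
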