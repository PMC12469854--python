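"""Loaders for the small published-data fixtures shipped with the package.

These are plain-text snapshots of printed result tables: the common
up/down-regulated gene lists, the pathway-enrichment table, the top ranked
synergy predictions, the ten-mode docking report, and the senolytic drug
list with proposed targets.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .dock_report import DockMode, parse_mode_table

__all__ = [
    "common_upregulated_genes",
    "common_downregulated_genes",
    "pathway_enrichment_table",
    "top_synergy_predictions",
    "docking_modes",
    "senolytic_drugs",
]


def _text(name: str) -> str:
    return resources.files("senosynergy.data").joinpath(name).read_text()


def _table(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("senosynergy.data").joinpath(name)) as p:
        return pd.read_csv(p, sep="\t")


def common_upregulated_genes() -> list[str]:
    """Gene symbols upregulated in both aging contrasts."""
    return [l.strip() for l in _text("common_upregulated_genes.txt").splitlines() if l.strip()]


def common_downregulated_genes() -> list[str]:
    return [l.strip() for l in _text("common_downregulated_genes.txt").splitlines() if l.strip()]


def pathway_enrichment_table() -> pd.DataFrame:
    """Columns: term_id, description, gene_ids (slash-joined), count."""
    return _table("aging_pathway_enrichment.tsv")


def top_synergy_predictions() -> pd.DataFrame:
    """Columns: drugA_Name, drug_B_Name, Predicted_Synergy_Score."""
    return _table("top_synergy_predictions.tsv")


def docking_modes() -> list[DockMode]:
    """The ten-mode nitazoxanide/mTOR docking table."""
    return parse_mode_table(_text("nitazoxanide_mtor_docking.tsv"))


def senolytic_drugs() -> pd.DataFrame:
    """Columns: drug_name, proposed_targets (comma-joined free text)."""
    return _table("senolytic_drugs.tsv")
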