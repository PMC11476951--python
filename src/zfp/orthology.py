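"""Orthologue-conservation summaries for the ZFP catalogue.

Orthologue pairings (a BioMart-style export: one row per gene x target
species, empty orthologue id meaning no match) are collapsed to
presence/absence per gene and species.  One-to-many pairings therefore
count once, and duplicate rows are harmless.  Confidence flags, when
present in an export, are ignored.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotation import GROUPS, ZfpGene, round_half_up

logger = logging.getLogger(__name__)


def read_orthologue_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns gene_id, target_species, orthologue_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "target_species", "orthologue_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"orthologue table missing columns: {sorted(missing)}")
    return df


def _matched_genes(orth: pd.DataFrame, species: str) -> set[str]:
    sub = orth[(orth["target_species"] == species) & (orth["orthologue_id"] != "")]
    return set(sub["gene_id"])


def conservation_by_group(
    catalogue: Sequence[ZfpGene], orth: pd.DataFrame, species: str
) -> pd.DataFrame:
    """Per-group orthologue conservation: (n_total, n_matched, percent).

    A gene is matched iff it has at least one non-empty orthologue id for
    *species*.  Genes absent from the orthologue table count as unmatched
    (their number is logged).  Groups with zero genes are excluded.
    Percentages are rounded half-up to one decimal.
    """
    available = sorted(orth["target_species"].unique())
    if species not in available:
        raise ValueError(
            f"species {species!r} not in orthologue table; available: {available}"
        )
    matched = _matched_genes(orth, species)
    listed = set(orth["gene_id"])
    absent = sum(1 for g in catalogue if g.gene_id not in listed)
    if absent:
        logger.info("%d catalogue genes absent from orthologue table (unmatched)", absent)

    rows = []
    for group in GROUPS:
        genes = [g for g in catalogue if g.group == group]
        if not genes:
            continue
        n_matched = sum(1 for g in genes if g.gene_id in matched)
        rows.append(
            {
                "group": group,
                "n_total": len(genes),
                "n_matched": n_matched,
                "percent": round_half_up(100.0 * n_matched / len(genes)),
            }
        )
    return pd.DataFrame(rows)


def conservation_overall(
    catalogue: Sequence[ZfpGene], orth: pd.DataFrame, species: str
) -> tuple[int, int, float]:
    """Catalogue-wide (n_total, n_matched, percent) for one species."""
    table = conservation_by_group(catalogue, orth, species)
    n_total = int(table["n_total"].sum())
    n_matched = int(table["n_matched"].sum())
    return n_total, n_matched, round_half_up(100.0 * n_matched / n_total)


def lineage_specific_genes(
    catalogue: Sequence[ZfpGene], orth: pd.DataFrame, species_list: Sequence[str]
) -> list[str]:
    """Genes with no orthologue in any of the listed species.

    An empty species list is a vacuous condition and yields no calls.
    """
    if not species_list:
        return []
    matched_any: set[str] = set()
    for species in species_list:
        matched_any |= _matched_genes(orth, species)
    return [g.gene_id for g in catalogue if g.gene_id not in matched_any]
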