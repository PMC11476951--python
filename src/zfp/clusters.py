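"""Distance-based detection of genomic ZFP gene clusters.

Zinc-finger genes — KRAB-ZFPs in particular — expand by local tandem
duplication and therefore sit in genomic blocks.  Following the standard
interval-merge convention (BEDtools ``merge -d``), genes on the same
sequence are merged transitively whenever the boundary-to-boundary gap is
strictly below ``max_gap`` (default 250 kb); merged blocks with at least
``min_genes`` members (default 3) are reported as clusters.  Strand is
ignored, and unplaced scaffolds are treated as ordinary sequences.
Clusters are named ``C{chrom}C{ordinal}`` left-to-right per sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotation import ZfpGene

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 250_000
DEFAULT_MIN_GENES = 3


@dataclass
class ClusterBlock:
    """A genomic block of clustered ZFP genes with composition counts."""

    cluster_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    members: list[str]  # gene ids sorted by start coordinate
    n_total: int
    n_by_group: dict[str, int]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("block end must exceed start")
        if self.n_total != len(self.members):
            raise ValueError("n_total disagrees with member list")
        if sum(self.n_by_group.values()) != self.n_total:
            raise ValueError("group counts must sum to n_total")


def _chrom_ordinal_name(chrom: str, ordinal: int) -> str:
    label = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return f"C{label}C{ordinal}"


def detect_clusters(
    catalogue: Sequence[ZfpGene],
    max_gap: int = DEFAULT_MAX_GAP,
    min_genes: int = DEFAULT_MIN_GENES,
) -> list[ClusterBlock]:
    """Merge genes within *max_gap* into blocks; keep blocks of >= *min_genes*.

    The gap is measured between interval boundaries (start of the next gene
    minus the running maximum end of the growing block; overlap counts as
    gap 0), and merging is transitive, which makes the result identical to
    the connected components of the pairwise interval-distance graph.
    Genes lacking coordinates are excluded with a logged warning.
    """
    placed = [g for g in catalogue if g.has_coordinates]
    skipped = len(catalogue) - len(placed)
    if skipped:
        logger.warning("%d genes without coordinates excluded from clustering", skipped)

    blocks: list[ClusterBlock] = []
    by_chrom: dict[str, list[ZfpGene]] = {}
    for g in placed:
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        runs: list[list[ZfpGene]] = []
        current: list[ZfpGene] = []
        block_end = None
        for g in genes:
            if current and g.start - block_end < max_gap:
                current.append(g)
                block_end = max(block_end, g.end)
            else:
                if current:
                    runs.append(current)
                current = [g]
                block_end = g.end
        if current:
            runs.append(current)

        ordinal = 0
        for run in runs:
            if len(run) < min_genes:
                continue
            ordinal += 1
            groups: dict[str, int] = {}
            for g in run:
                groups[g.group] = groups.get(g.group, 0) + 1
            blocks.append(
                ClusterBlock(
                    cluster_id=_chrom_ordinal_name(chrom, ordinal),
                    chrom=chrom,
                    start=min(g.start for g in run),
                    end=max(g.end for g in run),
                    members=[g.gene_id for g in run],
                    n_total=len(run),
                    n_by_group=groups,
                )
            )
    return blocks


def cluster_composition(
    blocks: Sequence[ClusterBlock],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-block composition table plus a global summary.

    The summary reports the number of blocks, the total genes residing in
    blocks, and how many of those are KRAB-ZFPs.
    """
    rows = []
    for b in blocks:
        row = {
            "cluster_id": b.cluster_id,
            "chrom": b.chrom,
            "start": b.start,
            "end": b.end,
            "n_total": b.n_total,
        }
        for group, n in sorted(b.n_by_group.items()):
            row[f"n_{group}"] = n
        rows.append(row)
    table = pd.DataFrame(rows)
    if not table.empty:
        count_cols = [c for c in table.columns if c.startswith("n_") and c != "n_total"]
        table[count_cols] = table[count_cols].fillna(0).astype(int)
    summary = {
        "n_clusters": len(blocks),
        "n_genes_in_clusters": int(sum(b.n_total for b in blocks)),
        "n_krab_in_clusters": int(sum(b.n_by_group.get("KRAB", 0) for b in blocks)),
    }
    return table, summary


def blocks_to_bed(blocks: Sequence[ClusterBlock], path: str | Path) -> None:
    """Export blocks as 6-column BED (0-based half-open; score = gene count)."""
    with Path(path).open("w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.cluster_id}\t{b.n_total}\t.\n")
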