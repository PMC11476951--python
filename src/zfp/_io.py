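"""Round-tripping catalogue TSVs back into gene objects."""

from __future__ import annotations

import pandas as pd

from .annotation import DomainHit, IsoformAnnotation, ZfpGene


def catalogue_from_frame(df: pd.DataFrame) -> list[ZfpGene]:
    """Rebuild ZfpGene objects from a catalogue table.

    Reconstructs just enough of each canonical isoform (its zinc-finger
    count and effector set) for downstream clustering, orthology and
    enrichment; per-domain coordinates are not stored in the TSV and are
    synthesised schematically.
    """
    genes: list[ZfpGene] = []
    for row in df.itertuples(index=False):
        iso_id = str(row.canonical_isoform)
        effectors = (
            [] if pd.isna(row.effectors) or row.effectors == ""
            else str(row.effectors).split(",")
        )
        hits = [
            DomainHit(iso_id, eff, 5 + 60 * i, 45 + 60 * i, 1e-10, 50.0)
            for i, eff in enumerate(effectors)
        ]
        hits += [
            DomainHit(iso_id, "ZF_C2H2", 400 + 24 * i, 422 + 24 * i, 1e-8, 25.0)
            for i in range(int(row.zf_count))
        ]
        iso = IsoformAnnotation(
            isoform_id=iso_id, gene_id=str(row.gene_id), length=900, hits=hits
        )
        genes.append(
            ZfpGene(
                gene_id=str(row.gene_id),
                canonical=iso,
                group=str(row.group),
                chrom=None if pd.isna(row.chrom) else str(row.chrom),
                start=None if pd.isna(row.start) else int(row.start),
                end=None if pd.isna(row.end) else int(row.end),
                strand=None if pd.isna(row.strand) else str(row.strand),
            )
        )
    return genes
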