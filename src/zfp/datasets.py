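"""Published summary statistics for the chicken C2H2-ZFP family.

These are the printed counts from a genome-wide survey of chicken
(GRCg7b, Ensembl 106) C2H2 zinc-finger proteins: group composition of the
301-gene catalogue, orthologue-match counts against human and zebra
finch, the tissue-specificity tally over 101 RNA-seq datasets spanning 32
tissues, and the blastoderm-enriched gene composition.  They serve as
inputs for reproducing the survey's headline ratios through this
package's summary functions, and as the scale template for the synthetic
generator.

Helpers here materialise the counts into catalogue/orthologue objects so
the ratio computations run through the same code paths as any user data.
"""

from __future__ import annotations

import pandas as pd

from .annotation import DomainHit, IsoformAnnotation, ZfpGene

#: Group composition of the 301 annotated chicken C2H2-ZFPs.
CHICKEN_GROUP_COUNTS: dict[str, int] = {
    "KRAB": 39,
    "BTB": 43,
    "SET": 14,
    "HOMEO": 4,
    "PHD": 2,
    "SCAN": 1,
    "ZF_ONLY": 198,
}

#: Genes with a human orthologue, per group (232 of 301 overall).
HUMAN_ORTHOLOGUE_MATCHED: dict[str, int] = {
    "KRAB": 5,  # 12.8% of 39
    "BTB": 41,  # 95.3% of 43
    "SET": 13,  # 92.9% of 14
    "HOMEO": 4,
    "PHD": 2,
    "SCAN": 0,
    "ZF_ONLY": 167,  # 84.3% of 198
}

#: KRAB-ZFPs with a zebra-finch orthologue (87.2% of the 39 lack one).
ZEBRA_FINCH_KRAB_MATCHED = 5

#: Genes with significantly enriched expression in >=1 of the 32 tissues.
TISSUE_SPECIFIC_GENES = 196

#: Composition of the 74 blastoderm-enriched C2H2-ZFPs.
BLASTODERM_ENRICHED: dict[str, int] = {
    "KRAB": 27,
    "ZF_ONLY": 38,
    "BTB": 6,
    "SET": 2,
    "PHD": 1,
}

#: Human benchmark: 394 of 677 human C2H2-ZFPs carry a KRAB domain.
HUMAN_KRAB_BENCHMARK = (394, 677)

#: Gene-cluster survey: 12 clusters holding 73 genes, 33 of them KRAB.
CLUSTER_SURVEY = {"n_clusters": 12, "n_genes_in_clusters": 73, "n_krab_in_clusters": 33}

#: The largest cluster (chromosome 29): 21 genes, 16 of them KRAB-ZFPs.
LARGEST_CLUSTER = {"n_total": 21, "n_krab": 16}


def _placeholder_gene(gene_id: str, group: str) -> ZfpGene:
    """A minimal catalogue entry carrying only identity and group label."""
    effector_hits = []
    if group != "ZF_ONLY":
        effector_hits.append(
            DomainHit(f"{gene_id}.1", group, 10, 50, 1e-10, 60.0)
        )
    hits = effector_hits + [
        DomainHit(f"{gene_id}.1", "ZF_C2H2", 100, 122, 1e-8, 25.0)
    ]
    iso = IsoformAnnotation(
        isoform_id=f"{gene_id}.1", gene_id=gene_id, length=400, hits=hits
    )
    return ZfpGene(gene_id=gene_id, canonical=iso, group=group)


def reference_catalogue() -> list[ZfpGene]:
    """The 301-gene chicken catalogue as group-labelled placeholder genes."""
    catalogue = []
    for group, n in CHICKEN_GROUP_COUNTS.items():
        for i in range(n):
            catalogue.append(_placeholder_gene(f"{group}_{i:03d}", group))
    return catalogue


def reference_orthologue_table() -> pd.DataFrame:
    """Presence/absence orthologue rows matching the published match counts.

    For human, the per-group matched counts are materialised directly; for
    zebra finch only the KRAB row counts are published, so non-KRAB genes
    are marked matched (the survey found them broadly conserved) — only
    KRAB percentages should be read off the zebra-finch column.
    """
    rows = []
    for group, n in CHICKEN_GROUP_COUNTS.items():
        matched_h = HUMAN_ORTHOLOGUE_MATCHED[group]
        matched_z = ZEBRA_FINCH_KRAB_MATCHED if group == "KRAB" else n
        for i in range(n):
            gene_id = f"{group}_{i:03d}"
            rows.append(
                (gene_id, "human", f"ENSG_{gene_id}" if i < matched_h else "")
            )
            rows.append(
                (gene_id, "zebra_finch", f"ENSTG_{gene_id}" if i < matched_z else "")
            )
    return pd.DataFrame(rows, columns=["gene_id", "target_species", "orthologue_id"])
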