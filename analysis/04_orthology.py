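"""Orthologue conservation of the catalogue across target species.

Joins the simulated partial orthologue table onto the catalogue, reports
per-group conservation percentages for each species, and lists
lineage-specific genes (no orthologue in any mammalian target).  In the
simulation, KRAB-ZFPs are generated with a low match rate (~13%), so
they should dominate the lineage-specific list.  Writes
results/orthology_<species>.tsv and results/lineage_specific.txt.
"""

import argparse
from pathlib import Path

from zfp._io import catalogue_from_frame
from zfp.annotation import read_catalogue
from zfp.orthology import (
    conservation_by_group,
    conservation_overall,
    lineage_specific_genes,
    read_orthologue_table,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--catalogue", default="results/catalogue.tsv")
    ap.add_argument("--orth", default="results/sim/orthologues.tsv")
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    genes = catalogue_from_frame(read_catalogue(args.catalogue))
    orth = read_orthologue_table(args.orth)
    out = Path(args.out_dir)

    for species in sorted(orth["target_species"].unique()):
        table = conservation_by_group(genes, orth, species)
        table.to_csv(out / f"orthology_{species}.tsv", sep="\t", index=False)
        n, k, pct = conservation_overall(genes, orth, species)
        print(f"\n{species}: {k}/{n} genes matched ({pct}%)")
        print(table.to_string(index=False))

    specific = lineage_specific_genes(genes, orth, ["human"])
    (out / "lineage_specific.txt").write_text("\n".join(specific) + "\n")
    group_of = {g.gene_id: g.group for g in genes}
    n_krab = sum(group_of[g] == "KRAB" for g in specific)
    print(f"\n{len(specific)} genes lack a human orthologue; {n_krab} are KRAB-ZFPs")


if __name__ == "__main__":
    main()
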