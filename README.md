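# zfp — C2H2 zinc-finger protein family annotation and expression profiling

C2H2 zinc-finger proteins (C2H2-ZFPs) are the largest class of eukaryotic
transcription factors.  Each carries a tandem array of Cys2His2 zinc
fingers that contacts DNA, often paired with an N-terminal effector
domain (KRAB, BTB/POZ, SCAN, SET, Homeodomain or PHD) that determines its
regulatory activity.  KRAB-ZFPs in particular evolve fast: they expand by
local tandem duplication into genomic clusters and are frequently
lineage-specific.  Characterising a genome's ZFP complement therefore
means answering several linked questions: which genes carry which domain
architectures, where they cluster in the genome, how conserved they are
across species, and where they are expressed.

This package implements that workflow end to end for bulk RNA-seq and
Pfam-scan inputs, with a synthetic-data generator providing ground truth
for every stage.  It was built around a genome-wide survey of the chicken
ZFP family (301 genes, 39 of them KRAB-ZFPs, profiled over 101 RNA-seq
datasets from 32 tissues); the published summary counts of that survey
ship in `zfp.datasets` and all of its headline ratios are reproduced by
the package's own summary functions.

## What it computes

* **Catalogue annotation** (`zfp.annotation`) — parses `hmmsearch
  --domtblout` output (independent E-value ≤ 0.05), selects one canonical
  isoform per gene (effector-bearing isoforms preferred, then most zinc
  fingers, then longest), and assigns a single effector-group label.
* **Cluster detection** (`zfp.clusters`) — transitively merges genes
  whose interval gap is < 250 kb and reports blocks of ≥ 3 genes
  (`C{chrom}C{ordinal}` naming).
* **Orthologue conservation** (`zfp.orthology`) — per-group percentages
  of genes with an orthologue in a target species; lineage-specific gene
  lists.
* **Alignment conservation** (`zfp.conservation`) — per-position
  Jensen–Shannon divergence of an alignment column distribution *P*
  against a background *Q*:
  `JSD(P,Q) = H(λP + (1−λ)Q) − λH(P) − (1−λ)H(Q)`, λ = 0.5, normalised
  to [0, 1] and down-weighted by the column's gap fraction.
* **Expression pipeline** (`zfp.expression`) — TPM (columns sum to 10⁶),
  abundance filtering (drop genes with TPM < 1 everywhere or > 10,000
  anywhere), TMM between-sample normalisation, average-linkage sample
  clustering on 1 − Pearson(log₂(TPM+1)), and one-vs-rest
  tissue-specificity calling (negative-binomial Wald test,
  Benjamini–Hochberg FDR < 0.05, log₂FC > 1 up in the focal tissue).
* **Enrichment statistics** (`zfp.enrichment`) — exact one-sided binomial
  test P(X ≥ k | n, p₀) for over-representation of a ZFP group among a
  tissue's enriched genes.
* **Synthetic data** (`zfp.simulate`) — seeded generators for every input
  above, with ground-truth tables.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study
(outputs land in `results/`):

```sh
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_annotate_catalogue.py
python analysis/03_detect_clusters.py
python analysis/04_orthology.py
python analysis/05_alignment_conservation.py
python analysis/06_expression.py
python analysis/07_enrichment.py
```

Step 03 recovers the planted cluster exactly:

```
1 cluster(s) holding 21 genes (16 KRAB-ZFPs)
cluster_id chrom   start     end  n_total  n_KRAB  n_ZF_ONLY
     C29C1    29 1000000 3569582       21      16          5
```

i.e. a single block on chromosome 29 spanning ~2.6 Mb whose 21 genes
include 16 KRAB-ZFPs — the shape of the largest chicken KRAB-ZFP cluster.
Step 06 reports `60/60 (100.0% sensitivity)` recovery of the planted
tissue-specific genes and ranks KRAB lowest in mean expression, and step
07 prints

```
simulated blastoderm: k=16/17 KRAB at background p0=0.263 -> one-sided binomial p=6.51e-09
survey blastoderm: k=27/74 KRAB at background p0=0.1296 -> one-sided binomial p=2.5e-07
```

meaning KRAB-ZFPs are strongly over-represented among blastoderm-enriched
genes both in the simulation (where that bias was planted) and in the
published survey configuration.

The same operations are available as a CLI (`zfp annotate`,
`zfp clusters`, `zfp orthology`, `zfp conserve`, `zfp express`,
`zfp enrich`, `zfp simulate`).

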