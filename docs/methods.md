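# Methods

This note documents the models and procedures implemented in `zfp`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that matter at the margins.

## Catalogue annotation

Input is the per-domain table (`--domtblout`) of hmmsearch runs against
seven Pfam profiles: zf-C2H2 (PF00096) plus the effector domains BTB/POZ
(PF00651), Homeodomain (PF00046), KRAB (PF01352), PHD (PF00628), SCAN
(PF02023) and SET (PF00856).  Hits are filtered on the per-domain
**independent E-value** at 0.05, matching hmmsearch's `-E 0.05 -incE
0.05` inclusion semantics; envelope coordinates are used.  A gene
qualifies as a C2H2-ZFP when any isoform carries ≥ 1 passing zinc-finger
hit.

Canonical-isoform selection applies, in order: (0) restrict to isoforms
with ≥ 1 zinc-finger hit — without this, rule 1 could select an
effector-only splice form with no DNA-binding array, which would be a
contradiction for a zinc-finger catalogue; (1) if an effector domain is
present on some but not all survivors, keep the effector-bearing ones;
(2) keep the largest zinc-finger count; (3) keep the longest; remaining
ties break on lexicographically smallest isoform id so the selection is
deterministic and independent of input order.

When several effector domains co-occur on the canonical isoform, the
single group label is assigned by the fixed priority KRAB > SCAN > BTB >
SET > HOMEO > PHD.  Disjoint group labels require *some* rule and none is
standard; the full effector set is retained on the isoform annotation so
multi-effector genes can always be audited.  Percentages are reported
half-up at one decimal, the convention used in survey reporting.

Coordinate tables arrive 1-based inclusive (BioMart convention) and are
normalised internally to 0-based half-open.  The gene interval is the
canonical isoform's transcript span.

## Cluster detection

Genes on the same sequence are merged transitively when the
boundary-to-boundary gap (next start minus running maximum end; overlap
counts as 0) is strictly below 250 kb, i.e. `bedtools merge -d`
semantics; blocks with ≥ 3 genes are reported.  Because the running block
end is the maximum member end, this sweep is provably identical to the
connected components of the pairwise interval-distance graph, which is
how the tests check it.  Strand is ignored and unplaced scaffolds are
ordinary sequences, so clusters can be called on scaffolds.  Whether the
published 250-kb rule measured start-to-start or boundary-to-boundary
distance is not documented; boundary-to-boundary is the implemented
choice because it is what interval-merge tooling does.

## Orthologue conservation

Orthologue pairing rows (gene, target species, orthologue id; empty id =
no match) collapse to presence/absence: one-to-many pairings count once
and duplicate rows are harmless.  Confidence flags present in some
exports are ignored.  Genes absent from the table count as unmatched
(logged).  A gene is *lineage-specific* with respect to a species list
when it matches in none of them; an empty list vacuously yields no calls.

## Jensen–Shannon conservation scoring

For each alignment column with residue distribution *P* (gaps and
non-standard letters excluded; no pseudocount) and background *Q*
(default uniform over the 20 amino acids; a file-supplied background is
accepted),

    JSD(P, Q) = H(λP + (1−λ)Q) − λ·H(P) − (1−λ)·H(Q),   λ = 0.5,

with H the Shannon entropy in bits.  The divergence is bounded by the
binary entropy of λ (1 bit at λ = 0.5), attained exactly when P and Q
have disjoint supports; dividing by that bound maps scores to [0, 1].
Note that a single-residue column scored against a *uniform* background
does not reach 1.0 (the supports overlap in one letter); it merely
maximises the score among columns, which is what the tests assert.
Gap handling: gaps are excluded from P rather than treated as a 21st
symbol, and with the gap penalty on (default) the score is multiplied by
the column's non-gap fraction, so gappy columns cannot appear conserved.
Scores are reported only at columns where the reference row is ungapped,
in 1-based ungapped-reference coordinates.  An optional symmetric moving
average (half-width *w*, off by default) is provided; no smoothing is
applied by default because every unsmoothed value is directly verifiable
against a per-column oracle.

## Expression pipeline

**TPM.** Per sample, `rate_g = count_g / length_g`;
`TPM_g = 10⁶ · rate_g / Σ rate`.  Columns sum to 10⁶ by construction.

**Filtering.** Genes with TPM < 1 in all samples (unexpressed) or
> 10,000 in any sample (quantification artefacts) are dropped; both
counts are logged.

**TMM.** Reference sample: upper quartile closest to the mean upper
quartile.  For each sample vs the reference, per-gene
`M = log₂(x_s/x_r)` and `A = ½·log₂(x_s·x_r)` over genes positive in
both; the most extreme 30% of M and 5% of A (totals, split evenly over
both tails) are trimmed; the factor is 2^(precision-weighted mean of the
retained M), with binomial-sampling inverse-variance weights
`w = (N_s−x)/(N_s·x) + (N_r−x_r)/(N_r·x_r)`.  Factors are rescaled to
geometric mean 1.  M is computed on the matrix values as given (not
re-normalised per column), so a sample that is a pure c-fold scaling of
the reference gets factor exactly c before rescaling.  With fewer than
10 genes surviving the trim the factor falls back to 1 with a warning.
Normalised values are `TPM / factor`.

**Sample clustering.** Distance 1 − Pearson correlation between samples
on log₂(value+1); average linkage (the defaults of common heatmap
tooling).  A constant sample vector makes correlation undefined and is
an error.  The dendrogram exports to Newick with each child branch
carrying half the merge distance.

**Tissue-specificity calling.** The unit of replication is the sample;
tissue labels come from a sample sheet.  For each tissue T, genes are
tested T-vs-rest on counts scaled by effective size factors (library
size × TMM factor on CPM, geometric mean 1):

* *Dispersion*: per-gene method-of-moments estimate from the pooled
  within-group variance, `α = (s² − μ)/μ²`, clipped to [0, 10], then
  shrunk 50/50 toward a least-squares trend `α(μ) = a₀ + a₁/μ` fitted
  across genes.  The shrinkage stabilises the n = 3 gene-wise estimates
  without making strong distributional claims.
* *Statistic*: Wald z on `log₂FC = log₂((μ_T + ½)/(μ_rest + ½))` with
  delta-method standard error from the NB variance `μ/s_i + αμ²`
  (pseudocount ½ guards zero means).
* *Correction*: Benjamini–Hochberg across genes within each T-vs-rest
  comparison; a gene is **enriched** in T iff FDR < 0.05 and
  log₂FC > +1 (up in T), the standard "enriched expression" reading of a
  two-sided |log₂FC| > 1 screen.

This test is intentionally self-contained rather than a reimplementation
of a published DE tool; it is validated by its operating characteristics
on synthetic data: ≥ 90% sensitivity on planted log₂FC = 3 genes at
n = 3 per tissue and dispersion 0.1 (measured ≈ 100%), and ≤ 5% of genes
called anywhere on fully null matrices (measured ≈ 0.02%), both averaged
over ten seeds.  It uses a single normalisation path (TMM-scaled
counts); raw-count size-factor alternatives were not layered on top to
keep the pipeline auditable.

**Group/tissue summaries.** Per-gene mean expression with group labels
(for ranking groups), per-tissue means over catalogue genes, and a gene ×
tissue-mean matrix row-z-scored (population sd; constant rows yield NaN
rather than an arbitrary 0).

## Binomial enrichment

P(X ≥ k | n, p₀) by the exact upper tail, one-sided because the question
is over-representation; no continuity correction.  The background p₀ is
the group's share of the **full** annotated catalogue, not the
expression-filtered subset.  For the published survey configuration
(k = 27 KRAB among n = 74 blastoderm-enriched genes, p₀ = 39/301) the
p-value is ≈ 2.5 × 10⁻⁷.

## Synthetic data

The generator (`zfp.simulate`) emulates the *structure* of the survey's
inputs at desk scale, with every parameter seeded:

* **Catalogue**: 80 genes, group proportions mirroring the chicken
  family (KRAB ≈ 13%), 1–3 isoforms per gene with variant isoforms
  deliberately exercising each canonical-selection rule, one planted
  cluster of 21 genes (16 KRAB) with gaps drawn inside the merge
  distance, scatter genes separated by ≥ 2 Mb so no unplanned cluster
  can form, and ~30% decoy domain hits with E-values above threshold.
  Infeasible cluster layouts (footprint exceeding the chromosome) are a
  config error.
* **Orthologues**: Bernoulli matches at the survey's per-group rates
  (human KRAB 12.8%, BTB 95.3%, …).
* **Counts**: 2,000 genes × 6 tissues × 3 replicates (the survey's 32
  tissues collapsed for desk speed); log-normal baselines (median ≈ 150
  counts, log-sd 1); log-normal library-size factors (sd 0.3) to
  exercise TMM; NB dispersion 0.1, typical of bulk RNA-seq across
  outbred individuals; 60 planted tissue-specific genes at log₂FC = 3.
* **Alignments**: 11 sequences × 200 columns, per-column substitution at
  rate 0.4 (0.05 inside conserved blocks), gaps injected only at
  requested columns and never in the reference.

What the generator does **not** emulate: real protein sequence
composition (alignment columns are i.i.d.), isoform-level expression,
overdispersion heterogeneity across genes (a single common dispersion is
used), batch effects, and correlated tissues.  Passing tests therefore
demonstrate the correctness of the computations and the caller's error
control under a well-specified NB world, not performance on real
chicken data.

## Numerical choices and edge cases

* E-values print at two significant figures in domtblout, so round-trips
  are exact in coordinates and identities, approximate (≤ 5%) in
  E-values.
* Percentage rounding is decimal half-up, not banker's rounding.
* All-gap alignment columns are undefined for JSD and are skipped by the
  profile (impossible at reference-ungapped columns).
* A sample with zero total rate is an error naming the sample (TPM);
  a single-tissue design and a tissue with zero samples are errors for
  the caller.
* Every stochastic component takes an explicit seed; default 1.

## Problem sizes

Defaults throughout (80-gene catalogues, 2,000-gene count matrices, ten
simulation seeds for operating characteristics) are chosen so the entire
suite and the acceptance script each run in well under a minute on one
CPU while leaving the statistical checks comfortably powered.
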