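"""Synthetic fixtures with known ground truth for every pipeline stage.

The generator emulates, in miniature, the input structure of a
genome-wide ZFP survey: an hmmsearch domtblout with planted domain
architectures (multi-isoform genes exercising each canonical-selection
rule, plus decoy hits above the E-value threshold), clustered genomic
coordinates with one block shaped like the largest chicken KRAB-ZFP
cluster (21 genes, 16 KRAB), partial orthologue tables with per-group
match rates, negative-binomial count matrices with planted
tissue-specific genes, and mutated protein alignments with conserved
blocks.  Every output is written as plain text and round-trips through
the corresponding parser; every run is reproducible from the seed.

Default shape parameters mirror the published chicken survey scaled to
desk size: seven groups with KRAB at roughly 13% of genes, 32 tissues
collapsed to 6, log-normal library-size factors (sd 0.3) to exercise
TMM, and gene-level dispersion 0.1 typical of bulk RNA-seq across
outbred individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    ACCESSION_OF_PROFILE,
    QUERY_OF_PROFILE,
    DomainHit,
)

#: Profile model lengths used when writing domtblout query columns.
_QLEN = {
    "ZF_C2H2": 23,
    "BTB": 111,
    "HOMEO": 57,
    "KRAB": 42,
    "PHD": 52,
    "SCAN": 84,
    "SET": 131,
}

TISSUES_DEFAULT = ("blastoderm", "testis", "ovary", "brain", "liver", "muscle")


@dataclass
class ClusterSpec:
    """One planted genomic cluster: where, how many genes, which groups."""

    chrom: str
    n_genes: int
    n_krab: int = 0
    gap_range: tuple[int, int] = (20_000, 240_000)  # bp between gene boundaries
    span_range: tuple[int, int] = (5_000, 30_000)  # gene length in bp

    def __post_init__(self) -> None:
        if self.n_krab > self.n_genes:
            raise ValueError("n_krab cannot exceed n_genes")


@dataclass
class SimConfig:
    """Parameters of the synthetic study, with survey-scaled defaults."""

    seed: int = 1
    # --- catalogue ---
    n_genes: int = 80
    group_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "KRAB": 0.13,
            "BTB": 0.14,
            "SET": 0.05,
            "HOMEO": 0.013,
            "PHD": 0.007,
            "SCAN": 0.003,
            "ZF_ONLY": 0.657,
        }
    )
    n_isoforms_range: tuple[int, int] = (1, 3)
    cluster_spec: list[ClusterSpec] = field(
        default_factory=lambda: [ClusterSpec(chrom="29", n_genes=21, n_krab=16)]
    )
    chrom_length: int = 200_000_000
    decoy_rate: float = 0.3  # extra hits failing the E-value threshold
    # --- orthologues ---
    orthologue_match_rate: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "human": {
                "KRAB": 0.128, "BTB": 0.953, "SET": 0.929, "HOMEO": 1.0,
                "PHD": 1.0, "SCAN": 0.0, "ZF_ONLY": 0.843,
            },
            "zebra_finch": {
                "KRAB": 0.128, "BTB": 0.96, "SET": 0.95, "HOMEO": 1.0,
                "PHD": 1.0, "SCAN": 1.0, "ZF_ONLY": 0.9,
            },
        }
    )
    # --- expression ---
    n_expr_genes: int = 2000
    tissues: tuple[str, ...] = TISSUES_DEFAULT
    replicates_per_tissue: int = 3
    nb_dispersion: float = 0.1
    baseline_log_mean: float = float(np.log(150.0))
    baseline_log_sd: float = 1.0
    libsize_log_sd: float = 0.3
    n_planted: int = 60
    planted_lfc: float = 3.0
    planted_effects: list[tuple[str, str, float]] | None = None

    def __post_init__(self) -> None:
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"group proportions must sum to 1, got {total}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.replicates_per_tissue < 1:
            raise ValueError("need >= 1 replicate per tissue")
        for spec in self.cluster_spec:
            footprint = spec.n_genes * (spec.span_range[1] + spec.gap_range[1])
            if footprint > self.chrom_length:
                raise ValueError(
                    f"cluster on {spec.chrom}: {spec.n_genes} genes x max "
                    f"{spec.span_range[1] + spec.gap_range[1]} bp exceeds "
                    f"chromosome length {self.chrom_length}"
                )


# ---------------------------------------------------------------------------
# domtblout writing

def _domtbl_line(hit: DomainHit, tlen: int, dom_i: int, dom_of: int, desc: str) -> str:
    query = QUERY_OF_PROFILE[hit.profile]
    acc = ACCESSION_OF_PROFILE[hit.profile]
    qlen = _QLEN[hit.profile]
    fields = [
        hit.isoform_id, "-", str(tlen), query, acc, str(qlen),
        f"{hit.i_evalue:.2g}", f"{hit.score + 1.0:.1f}", "0.1",
        str(dom_i), str(dom_of),
        f"{hit.i_evalue / 10:.2g}", f"{hit.i_evalue:.2g}",
        f"{hit.score:.1f}", "0.1",
        "1", str(qlen),
        str(hit.env_start), str(hit.env_end),
        str(hit.env_start), str(hit.env_end),
        "0.95", desc,
    ]
    return " ".join(fields)


def write_domtblout(
    hits: Sequence[DomainHit],
    path: str | Path,
    isoform_lengths: dict[str, int] | None = None,
) -> None:
    """Write hits in the standard 23-column hmmsearch domtblout layout."""
    counts: dict[tuple[str, str], int] = {}
    for h in hits:
        key = (h.isoform_id, h.profile)
        counts[key] = counts.get(key, 0) + 1
    seen: dict[tuple[str, str], int] = {}
    with Path(path).open("w") as fh:
        fh.write("# target name accession tlen query name accession qlen "
                 "E-value score bias # of c-Evalue i-Evalue score bias "
                 "hmm_from hmm_to ali_from ali_to env_from env_to acc "
                 "description of target\n")
        fh.write("#" + "-" * 40 + "\n")
        for h in hits:
            key = (h.isoform_id, h.profile)
            seen[key] = seen.get(key, 0) + 1
            tlen = (isoform_lengths or {}).get(h.isoform_id, h.env_end + 20)
            fh.write(
                _domtbl_line(h, tlen, seen[key], counts[key], "synthetic protein") + "\n"
            )
        fh.write("#\n# Program: hmmsearch\n")


# ---------------------------------------------------------------------------
# catalogue simulation

@dataclass
class _IsoPlan:
    isoform_id: str
    effectors: tuple[str, ...]
    zf_count: int
    length: int


def _plan_isoforms(
    rng: np.random.Generator, gene_id: str, group: str, n_iso: int
) -> tuple[list[_IsoPlan], str]:
    """Lay out isoforms so the intended canonical wins by the stated rules."""
    zf = int(rng.integers(3, 13))
    length = int(rng.integers(350, 700))
    effectors = () if group == "ZF_ONLY" else (group,)
    canonical = _IsoPlan(f"{gene_id}.1", effectors, zf, length)
    plans = [canonical]
    variants = ["fewer_zf", "shorter"]
    if group != "ZF_ONLY":
        variants += ["no_effector", "no_zf"]
    for j in range(2, n_iso + 1):
        kind = variants[int(rng.integers(0, len(variants)))]
        if kind == "fewer_zf":
            # more residues but fewer fingers: rule 2 must beat rule 3
            plans.append(
                _IsoPlan(f"{gene_id}.{j}", effectors,
                         max(zf - int(rng.integers(1, 3)), 1), length + 50)
            )
        elif kind == "shorter":
            plans.append(
                _IsoPlan(f"{gene_id}.{j}", effectors, zf,
                         length - int(rng.integers(10, 60)))
            )
        elif kind == "no_effector":
            plans.append(_IsoPlan(f"{gene_id}.{j}", (), zf + 1, length))
        else:  # no_zf: effector retained but the ZF array is spliced out
            plans.append(_IsoPlan(f"{gene_id}.{j}", effectors, 0, length - 100))
    return plans, canonical.isoform_id


def _hits_for_isoform(rng: np.random.Generator, plan: _IsoPlan) -> list[DomainHit]:
    hits: list[DomainHit] = []
    pos = 5
    for eff in plan.effectors:
        width = _QLEN[eff]
        hits.append(
            DomainHit(plan.isoform_id, eff, pos, pos + width - 1,
                      float(10.0 ** rng.uniform(-30, -4)),
                      float(np.round(rng.uniform(30, 120), 1)))
        )
        pos += width + 10
    zf_start = max(plan.length - 24 * plan.zf_count - 5, pos)
    for _ in range(plan.zf_count):
        hits.append(
            DomainHit(plan.isoform_id, "ZF_C2H2", zf_start, zf_start + 22,
                      float(10.0 ** rng.uniform(-12, -4)),
                      float(np.round(rng.uniform(15, 40), 1)))
        )
        zf_start += 24
    return hits


@dataclass
class CatalogueSim:
    """Paths and ground truth of one simulated annotation input set."""

    domtbl_path: Path
    coords_path: Path
    truth_path: Path
    truth: pd.DataFrame  # gene_id, group, canonical_isoform, chrom, cluster_id
    hits: list[DomainHit]
    decoys: list[DomainHit]


def simulate_catalogue(cfg: SimConfig, out_dir: str | Path) -> CatalogueSim:
    """Write a domtblout + coordinate table with known gene-level truth.

    Cluster genes are placed first (per ``cfg.cluster_spec``, with gaps
    strictly inside the merge distance); the remaining genes are scattered
    across other chromosomes with multi-megabase gaps so no unplanned
    cluster can form.  Decoy hits with i-Evalue above 0.05 are interleaved
    to exercise the parser's threshold.
    """
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # group assignment: planted clusters first, scatter genes by proportion
    gene_plans: list[tuple[str, str, str | None]] = []  # (gene_id, group, cluster_id)
    gid = 0
    for ci, spec in enumerate(cfg.cluster_spec, start=1):
        label = f"planted_{spec.chrom}_{ci}"
        for j in range(spec.n_genes):
            gid += 1
            group = "KRAB" if j < spec.n_krab else "ZF_ONLY"
            gene_plans.append((f"G{gid:04d}", group, label))
    n_scatter = cfg.n_genes - gid
    if n_scatter < 0:
        raise ValueError("cluster_spec places more genes than n_genes")
    groups = list(cfg.group_proportions)
    probs = np.array([cfg.group_proportions[g] for g in groups])
    for _ in range(n_scatter):
        gid += 1
        group = groups[int(rng.choice(len(groups), p=probs))]
        gene_plans.append((f"G{gid:04d}", group, None))

    # genomic placement
    coords_rows = []
    placements: dict[str, tuple[str, int, int, str]] = {}
    idx = 0
    for ci, spec in enumerate(cfg.cluster_spec, start=1):
        pos = 1_000_000
        for j in range(spec.n_genes):
            gene_id, group, _ = gene_plans[idx]
            idx += 1
            span = int(rng.integers(*spec.span_range))
            strand = "+" if rng.random() < 0.5 else "-"
            placements[gene_id] = (spec.chrom, pos, pos + span, strand)
            pos += span + int(rng.integers(*spec.gap_range))
    scatter_chroms = [str(c) for c in range(1, 29)]
    cursor: dict[str, int] = {}
    for gene_id, group, _ in gene_plans[idx:]:
        chrom = scatter_chroms[int(rng.integers(0, len(scatter_chroms)))]
        pos = cursor.get(chrom, 500_000)
        span = int(rng.integers(5_000, 30_000))
        strand = "+" if rng.random() < 0.5 else "-"
        placements[gene_id] = (chrom, pos, pos + span, strand)
        cursor[chrom] = pos + span + int(rng.integers(2_000_000, 5_000_000))

    # isoforms, hits, decoys
    all_hits: list[DomainHit] = []
    decoys: list[DomainHit] = []
    iso_lengths: dict[str, int] = {}
    truth_rows = []
    for gene_id, group, cluster_id in gene_plans:
        chrom, start, end, strand = placements[gene_id]
        n_iso = int(rng.integers(cfg.n_isoforms_range[0], cfg.n_isoforms_range[1] + 1))
        plans, canonical_id = _plan_isoforms(rng, gene_id, group, n_iso)
        zf_canonical = next(p.zf_count for p in plans if p.isoform_id == canonical_id)
        for plan in plans:
            iso_lengths[plan.isoform_id] = plan.length
            coords_rows.append(
                (gene_id, plan.isoform_id, chrom, start + 1, end, strand, plan.length)
            )
            all_hits.extend(_hits_for_isoform(rng, plan))
            if rng.random() < cfg.decoy_rate:
                prof = ("KRAB", "BTB", "SET", "ZF_C2H2")[int(rng.integers(0, 4))]
                decoys.append(
                    DomainHit(plan.isoform_id, prof, 1, _QLEN[prof],
                              float(np.round(rng.uniform(0.06, 5.0), 3)),
                              float(np.round(rng.uniform(2, 12), 1)))
                )
        truth_rows.append(
            {
                "gene_id": gene_id, "group": group,
                "canonical_isoform": canonical_id, "zf_count": zf_canonical,
                "chrom": chrom, "start": start, "end": end,
                "cluster_id": cluster_id or "",
            }
        )

    # interleave decoys deterministically among real hits
    combined: list[DomainHit] = list(all_hits)
    for d in decoys:
        combined.insert(int(rng.integers(0, len(combined) + 1)), d)

    domtbl_path = out_dir / "scan.domtblout"
    coords_path = out_dir / "coords.tsv"
    truth_path = out_dir / "catalogue_truth.tsv"
    write_domtblout(combined, domtbl_path, iso_lengths)
    pd.DataFrame(
        coords_rows,
        columns=["gene_id", "isoform_id", "chrom", "start", "end", "strand", "length"],
    ).to_csv(coords_path, sep="\t", index=False)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(truth_path, sep="\t", index=False)
    return CatalogueSim(domtbl_path, coords_path, truth_path, truth, all_hits, decoys)


def simulate_orthologues(
    cfg: SimConfig, truth: pd.DataFrame, out_path: str | Path | None = None
) -> pd.DataFrame:
    """Partial orthologue table with per-group/species match rates."""
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for species, rates in cfg.orthologue_match_rate.items():
        for row in truth.itertuples(index=False):
            matched = rng.random() < rates.get(row.group, 0.5)
            rows.append(
                (row.gene_id, species, f"ORTH_{species}_{row.gene_id}" if matched else "")
            )
    table = pd.DataFrame(rows, columns=["gene_id", "target_species", "orthologue_id"])
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table


# ---------------------------------------------------------------------------
# expression simulation

@dataclass
class CountsSim:
    counts_path: Path
    lengths_path: Path
    samples_path: Path
    truth_path: Path
    counts: pd.DataFrame
    lengths: pd.Series
    tissue_of: pd.Series
    truth: pd.DataFrame  # gene_id, tissue, log2fc


def simulate_counts(
    cfg: SimConfig,
    out_dir: str | Path | None = None,
    genes: Sequence[str] | None = None,
    baseline_scale: dict[str, float] | None = None,
) -> CountsSim:
    """Negative-binomial counts with planted tissue-specific genes.

    mean_gs = baseline_g * 2^lfc (if sample s is in the planted tissue)
    * libsize-factor_s; counts ~ NB(mean, dispersion) (Poisson in the
    dispersion -> 0 limit).  Library-size factors are log-normal
    (sd ``libsize_log_sd``) to give TMM something to undo.
    *baseline_scale* multiplies selected genes' baseline means, e.g. to
    emulate a group expressed below the family average.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n = cfg.n_expr_genes
    gene_ids = list(genes) if genes is not None else [f"EG{i:05d}" for i in range(1, n + 1)]
    n = len(gene_ids)
    samples, tissue_labels = [], []
    for t in cfg.tissues:
        for r in range(1, cfg.replicates_per_tissue + 1):
            samples.append(f"{t}_rep{r}")
            tissue_labels.append(t)
    tissue_of = pd.Series(tissue_labels, index=samples)

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)
    libfactor = rng.lognormal(0.0, cfg.libsize_log_sd, size=len(samples))
    if baseline_scale:
        idx = {g: i for i, g in enumerate(gene_ids)}
        for g, f in baseline_scale.items():
            if g in idx:
                baseline[idx[g]] *= f

    if cfg.planted_effects is not None:
        effects = list(cfg.planted_effects)
    else:
        planted_idx = rng.choice(n, size=min(cfg.n_planted, n), replace=False)
        effects = [
            (gene_ids[i], cfg.tissues[int(rng.integers(0, len(cfg.tissues)))], cfg.planted_lfc)
            for i in sorted(planted_idx)
        ]
    lfc_of: dict[tuple[str, str], float] = {(g, t): l for g, t, l in effects}

    mu = np.outer(baseline, libfactor)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for (g, t), l in lfc_of.items():
        cols = [j for j, s in enumerate(samples) if tissue_of[s] == t]
        mu[gene_index[g], cols] *= 2.0 ** l

    if cfg.nb_dispersion < 1e-8:
        counts_arr = rng.poisson(mu)
    else:
        r = 1.0 / cfg.nb_dispersion
        p = r / (r + mu)
        counts_arr = rng.negative_binomial(r, p)
    counts = pd.DataFrame(counts_arr, index=gene_ids, columns=samples)
    lengths = pd.Series(rng.integers(500, 5001, size=n), index=gene_ids, name="length")
    truth = pd.DataFrame(effects, columns=["gene_id", "tissue", "log2fc"])

    paths = [Path("/dev/null")] * 4
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = [
            out_dir / "counts.tsv", out_dir / "lengths.tsv",
            out_dir / "samples.tsv", out_dir / "de_truth.tsv",
        ]
        counts.rename_axis("gene_id").to_csv(paths[0], sep="\t")
        lengths.rename_axis("gene_id").to_frame().to_csv(paths[1], sep="\t")
        pd.DataFrame({"sample_id": samples, "tissue": tissue_labels}).to_csv(
            paths[2], sep="\t", index=False
        )
        truth.to_csv(paths[3], sep="\t", index=False)
    return CountsSim(*paths, counts=counts, lengths=lengths, tissue_of=tissue_of, truth=truth)


def read_counts_inputs(
    counts_path: str | Path, lengths_path: str | Path, samples_path: str | Path
):
    """Load counts/lengths/sample-sheet TSVs into a CountMatrix."""
    from .expression import CountMatrix

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0)["length"]
    sheet = pd.read_csv(samples_path, sep="\t")
    tissue_of = pd.Series(sheet["tissue"].to_numpy(), index=sheet["sample_id"])
    return CountMatrix(counts=counts, lengths=lengths, tissue_of=tissue_of)


# ---------------------------------------------------------------------------
# alignment simulation

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class AlignmentSim:
    ids: list[str]
    rows: list[str]
    truth: pd.DataFrame  # position (1-based), conserved (bool)


def simulate_alignment(
    n_seqs: int = 11,
    length: int = 200,
    conserved_blocks: Sequence[tuple[int, int]] = ((20, 60), (120, 180)),
    substitution_rate: float = 0.4,
    conserved_rate: float = 0.05,
    gap_columns: Sequence[int] = (),
    gap_rate: float = 0.5,
    seed: int = 1,
    out_path: str | Path | None = None,
) -> AlignmentSim:
    """Mutate a random reference per column; conserved blocks mutate slowly.

    *conserved_blocks* are 1-based inclusive column ranges.  Gaps are
    injected only in non-reference rows at *gap_columns* (probability
    *gap_rate* per row), so the reference stays ungapped and the profile
    covers every column.
    """
    if not 0.0 <= substitution_rate <= 1.0 or not 0.0 <= conserved_rate <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    ref = aa[rng.integers(0, 20, size=length)]
    conserved = np.zeros(length, dtype=bool)
    for lo, hi in conserved_blocks:
        conserved[lo - 1 : hi] = True
    rate = np.where(conserved, conserved_rate, substitution_rate)

    ids = ["reference"] + [f"species_{i:02d}" for i in range(1, n_seqs)]
    rows = ["".join(ref)]
    gap_cols = set(int(c) for c in gap_columns)
    for _ in range(1, n_seqs):
        seq = ref.copy()
        mutate = rng.random(length) < rate
        if mutate.any():
            # substitute with a uniformly random *different* residue
            offsets = rng.integers(1, 20, size=int(mutate.sum()))
            current = np.searchsorted(aa, seq[mutate])
            seq[mutate] = aa[(current + offsets) % 20]
        chars = list(seq)
        for c in gap_cols:
            if rng.random() < gap_rate:
                chars[c - 1] = "-"
        rows.append("".join(chars))

    truth = pd.DataFrame({"position": np.arange(1, length + 1), "conserved": conserved})
    if out_path is not None:
        with Path(out_path).open("w") as fh:
            for sid, row in zip(ids, rows):
                fh.write(f">{sid}\n{row}\n")
    return AlignmentSim(ids=ids, rows=rows, truth=truth)
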