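"""Build an annotated C2H2 zinc-finger-protein (ZFP) catalogue from domain scans.

The raw input is the per-domain tabular output of ``hmmsearch`` (the
"domtblout" format) produced by scanning a proteome against the Pfam
profiles for the C2H2 zinc finger and its associated effector domains
(KRAB, BTB/POZ, SCAN, SET, Homeodomain, PHD).  From those hits this module

* filters domain matches by independent E-value,
* selects one canonical isoform per gene by a three-rule procedure
  (effector-bearing isoforms preferred, then most zinc fingers, then
  longest), and
* assigns each gene a single effector-domain group label.

Coordinates in the gene coordinate table are expected 1-based inclusive
(BioMart convention) and are normalised internally to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised Pfam profile names (hmmsearch query names) -> internal labels.
PROFILE_OF_QUERY: Mapping[str, str] = {
    "zf-C2H2": "ZF_C2H2",
    "BTB": "BTB",
    "Homeodomain": "HOMEO",
    "KRAB": "KRAB",
    "PHD": "PHD",
    "SCAN": "SCAN",
    "SET": "SET",
}

QUERY_OF_PROFILE: Mapping[str, str] = {v: k for k, v in PROFILE_OF_QUERY.items()}

#: Pfam accessions, written back out by the fixture generator.
ACCESSION_OF_PROFILE: Mapping[str, str] = {
    "ZF_C2H2": "PF00096.30",
    "BTB": "PF00651.34",
    "HOMEO": "PF00046.32",
    "KRAB": "PF01352.30",
    "PHD": "PF00628.32",
    "SCAN": "PF02023.17",
    "SET": "PF00856.31",
}

PROFILES = tuple(PROFILE_OF_QUERY.values())
EFFECTOR_PROFILES = tuple(p for p in PROFILES if p != "ZF_C2H2")

#: Group label priority when several effector domains co-occur on the
#: canonical isoform.  The full effector set is always retained on the
#: isoform annotation so multi-effector genes can be audited.
GROUP_PRIORITY = ("KRAB", "SCAN", "BTB", "SET", "HOMEO", "PHD")

GROUPS = GROUP_PRIORITY + ("ZF_ONLY",)

DEFAULT_EVALUE_MAX = 0.05


class DomtblParseError(ValueError):
    """A malformed line in a domtblout file."""


@dataclass(frozen=True)
class DomainHit:
    """One profile match on one protein isoform (envelope coordinates)."""

    isoform_id: str
    profile: str
    env_start: int  # 1-based inclusive residue index
    env_end: int  # 1-based inclusive
    i_evalue: float  # independent E-value of the domain
    score: float  # bit score

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.env_start > self.env_end:
            raise ValueError(
                f"env_start {self.env_start} > env_end {self.env_end}"
            )
        if self.i_evalue <= 0:
            raise ValueError("i_evalue must be positive")


@dataclass
class IsoformAnnotation:
    """Domain content of one protein isoform of one gene."""

    isoform_id: str
    gene_id: str
    length: int  # residues
    hits: list[DomainHit] = field(default_factory=list)

    @property
    def zf_count(self) -> int:
        return sum(1 for h in self.hits if h.profile == "ZF_C2H2")

    @property
    def effector_domains(self) -> frozenset[str]:
        return frozenset(h.profile for h in self.hits if h.profile != "ZF_C2H2")


@dataclass
class ZfpGene:
    """A C2H2-ZFP gene: canonical isoform, group label, genomic interval."""

    gene_id: str
    canonical: IsoformAnnotation
    group: str
    chrom: str | None = None
    start: int | None = None  # 0-based half-open
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.canonical.zf_count < 1:
            raise ValueError("canonical isoform must carry >=1 zinc finger")
        if self.start is not None and self.end is not None and not self.start < self.end:
            raise ValueError("gene interval requires start < end")

    @property
    def has_coordinates(self) -> bool:
        return self.chrom is not None and self.start is not None and self.end is not None


def parse_domtblout(
    path: str | Path, evalue_max: float = DEFAULT_EVALUE_MAX
) -> list[DomainHit]:
    """Parse an ``hmmsearch --domtblout`` file, keeping hits with i-Evalue <= *evalue_max*.

    The independent E-value is used for filtering, matching hmmsearch's
    per-domain inclusion semantics.  Input order is preserved.  Lines whose
    query profile is not one of the seven tracked domains are ignored.

    Raises
    ------
    DomtblParseError
        If a non-comment line does not have the standard 23-column layout,
        naming the offending line number.
    FileNotFoundError
        If *path* does not exist.
    """
    hits: list[DomainHit] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            # 22 fixed whitespace-separated columns; the 23rd (description
            # of target) is free text and may itself contain spaces.
            fields = line.split(None, 22)
            if len(fields) < 23:
                raise DomtblParseError(
                    f"{path}:{lineno}: expected 23 columns, found {len(fields)}"
                )
            query_name = fields[3]
            profile = PROFILE_OF_QUERY.get(query_name)
            if profile is None:
                logger.debug("%s:%d: ignoring untracked profile %r", path, lineno, query_name)
                continue
            try:
                i_evalue = float(fields[12])
                score = float(fields[13])
                env_start = int(fields[19])
                env_end = int(fields[20])
            except ValueError as exc:
                raise DomtblParseError(f"{path}:{lineno}: {exc}") from exc
            if i_evalue > evalue_max:
                continue
            hits.append(
                DomainHit(
                    isoform_id=fields[0],
                    profile=profile,
                    env_start=env_start,
                    env_end=env_end,
                    i_evalue=i_evalue,
                    score=score,
                )
            )
    return hits


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Read the isoform coordinate table (TSV).

    Expected columns: gene_id, isoform_id, chrom, start, end, strand, length
    with start/end 1-based inclusive.  Returns a DataFrame with coordinates
    normalised to 0-based half-open (start decremented).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "isoform_id", "chrom", "start", "end", "strand", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coordinate table missing columns: {sorted(missing)}")
    df = df.copy()
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df


def build_isoform_annotations(
    hits: Iterable[DomainHit], coords: pd.DataFrame
) -> list[IsoformAnnotation]:
    """Attach domain hits to the isoforms listed in the coordinate table.

    Isoforms with no hits are still returned (they matter for canonical
    selection bookkeeping of multi-isoform genes); hits on isoforms absent
    from the table are dropped with a warning.
    """
    by_isoform: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_isoform.setdefault(h.isoform_id, []).append(h)

    annotations: list[IsoformAnnotation] = []
    known = set()
    for row in coords.itertuples(index=False):
        known.add(row.isoform_id)
        annotations.append(
            IsoformAnnotation(
                isoform_id=row.isoform_id,
                gene_id=row.gene_id,
                length=int(row.length),
                hits=by_isoform.get(row.isoform_id, []),
            )
        )
    orphans = set(by_isoform) - known
    if orphans:
        logger.warning(
            "%d isoforms with domain hits absent from coordinate table", len(orphans)
        )
    return annotations


def select_canonical(isoforms: Sequence[IsoformAnnotation]) -> IsoformAnnotation:
    """Select the canonical isoform of a gene.

    Applied in order, each rule narrowing the candidate set:

    0. only isoforms carrying at least one zinc-finger hit are candidates;
    1. if an effector domain is present on some but not all candidates,
       keep only the effector-bearing ones;
    2. keep the candidates with the largest zinc-finger count;
    3. keep the longest; remaining ties broken by lexicographically
       smallest isoform_id, so the choice is deterministic and
       permutation-invariant.
    """
    candidates = [iso for iso in isoforms if iso.zf_count >= 1]
    if not candidates:
        raise ValueError("no isoform carries a zinc-finger hit")
    with_effector = [iso for iso in candidates if iso.effector_domains]
    if with_effector and len(with_effector) < len(candidates):
        candidates = with_effector
    max_zf = max(iso.zf_count for iso in candidates)
    candidates = [iso for iso in candidates if iso.zf_count == max_zf]
    max_len = max(iso.length for iso in candidates)
    candidates = [iso for iso in candidates if iso.length == max_len]
    return min(candidates, key=lambda iso: iso.isoform_id)


def assign_group(effectors: frozenset[str] | set[str]) -> str:
    """Map an effector-domain set to the single group label (priority order)."""
    for label in GROUP_PRIORITY:
        if label in effectors:
            return label
    return "ZF_ONLY"


def classify_gene(
    isoforms: Sequence[IsoformAnnotation],
    *,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
    strand: str | None = None,
) -> ZfpGene | None:
    """Classify a gene from its isoform annotations.

    Returns ``None`` when no isoform carries a zinc-finger hit (the gene is
    not a C2H2-ZFP).  Otherwise selects the canonical isoform and assigns
    the group from its effector set.
    """
    if not isoforms:
        raise ValueError("empty isoform list")
    gene_ids = {iso.gene_id for iso in isoforms}
    if len(gene_ids) != 1:
        raise ValueError(f"isoforms span several genes: {sorted(gene_ids)}")
    if not any(iso.zf_count >= 1 for iso in isoforms):
        return None
    canonical = select_canonical(isoforms)
    return ZfpGene(
        gene_id=canonical.gene_id,
        canonical=canonical,
        group=assign_group(canonical.effector_domains),
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
    )


def build_catalogue(
    hits: Iterable[DomainHit], coords: pd.DataFrame
) -> list[ZfpGene]:
    """Full catalogue construction: hits + coordinate table -> list of genes.

    The gene interval is the canonical isoform's transcript span from the
    coordinate table.  Genes with no zinc-finger-bearing isoform are
    silently excluded (they are not family members).
    """
    annotations = build_isoform_annotations(hits, coords)
    by_gene: dict[str, list[IsoformAnnotation]] = {}
    for iso in annotations:
        by_gene.setdefault(iso.gene_id, []).append(iso)
    span = coords.set_index("isoform_id")

    catalogue: list[ZfpGene] = []
    for gene_id in sorted(by_gene):
        gene = classify_gene(by_gene[gene_id])
        if gene is None:
            continue
        row = span.loc[gene.canonical.isoform_id]
        gene.chrom = str(row["chrom"])
        gene.start = int(row["start"])
        gene.end = int(row["end"])
        gene.strand = str(row["strand"])
        catalogue.append(gene)
    return catalogue


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (reporting convention for percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_groups(catalogue: Sequence[ZfpGene]) -> pd.DataFrame:
    """Per-group gene counts and percentages (one decimal, half-up).

    Returns an empty frame for an empty catalogue.  Counts partition the
    catalogue: every gene carries exactly one group label.
    """
    if not catalogue:
        return pd.DataFrame(columns=["group", "n", "percent"])
    counts = pd.Series([g.group for g in catalogue]).value_counts()
    counts = counts.reindex([g for g in GROUPS if g in counts.index])
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "group": counts.index,
            "n": counts.to_numpy(),
            "percent": [round_half_up(100.0 * c / total) for c in counts],
        }
    ).reset_index(drop=True)


def catalogue_to_frame(catalogue: Sequence[ZfpGene]) -> pd.DataFrame:
    """One row per gene: the catalogue TSV layout."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in catalogue],
            "group": [g.group for g in catalogue],
            "zf_count": [g.canonical.zf_count for g in catalogue],
            "effectors": [
                ",".join(sorted(g.canonical.effector_domains)) for g in catalogue
            ],
            "canonical_isoform": [g.canonical.isoform_id for g in catalogue],
            "chrom": [g.chrom for g in catalogue],
            "start": [g.start for g in catalogue],
            "end": [g.end for g in catalogue],
            "strand": [g.strand for g in catalogue],
        }
    )


def write_catalogue(catalogue: Sequence[ZfpGene], path: str | Path) -> None:
    catalogue_to_frame(catalogue).to_csv(path, sep="\t", index=False)


def read_catalogue(path: str | Path) -> pd.DataFrame:
    """Read a catalogue TSV written by :func:`write_catalogue`."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
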