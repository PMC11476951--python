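"""Per-position conservation scoring of a protein alignment.

Each alignment column is scored with the Jensen-Shannon divergence between
the column's amino-acid distribution P and a background distribution Q:

    JSD(P, Q) = H(lam*P + (1-lam)*Q) - lam*H(P) - (1-lam)*H(Q)

with H the Shannon entropy in bits and lam = 0.5 by default.  The raw
divergence is bounded by the binary entropy of lam (1 bit at lam = 0.5,
attained when P and Q have disjoint supports), and is normalised by that
bound so scores lie in [0, 1]: 0 means the column looks like background,
1 means a fully conserved residue the background never favours.

Gaps are excluded from the column distribution (not treated as a 21st
symbol); with ``gap_penalty`` on, the score is down-weighted by the
column's non-gap fraction so gappy columns cannot look conserved.  Scores
are reported only at columns where the chosen reference sequence is
ungapped, in 1-based reference coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Uniform background over the 20 amino acids (default; a file-supplied
#: background, e.g. database frequencies, may be passed instead).
UNIFORM_BACKGROUND = np.full(20, 0.05)


@dataclass
class Alignment:
    """A protein multiple sequence alignment with a designated reference row."""

    ids: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        if self.reference_id not in self.ids:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]


def read_alignment(path: str | Path, reference_id: str, fmt: str = "fasta") -> Alignment:
    """Load an aligned FASTA (or Clustal, ``fmt='clustal'``) file."""
    msa = AlignIO.read(str(path), fmt)
    return Alignment(
        ids=[rec.id for rec in msa],
        rows=[str(rec.seq).upper() for rec in msa],
        reference_id=reference_id,
    )


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def jsd_column(
    counts: np.ndarray | Sequence[float],
    background: np.ndarray | Sequence[float] | None = None,
    lam: float = 0.5,
) -> float:
    """Normalised Jensen-Shannon divergence of one column against background.

    *counts* is a length-20 amino-acid count (or frequency) vector; it is
    normalised internally.  *background* must be strictly positive and sum
    to one.  The result is divided by the maximum attainable divergence
    (the binary entropy of lam) and clipped into [0, 1].
    """
    if not 0.0 < lam < 1.0:
        raise ValueError("lam must lie strictly inside (0, 1)")
    counts = np.asarray(counts, dtype=float)
    q = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    if counts.shape != (20,) or q.shape != (20,):
        raise ValueError("counts and background must be length-20 vectors")
    total = counts.sum()
    if total <= 0:
        raise ValueError("column has no residues (all-gap columns must be skipped)")
    if np.any(q <= 0) or not np.isclose(q.sum(), 1.0):
        raise ValueError("background must be strictly positive and sum to 1")
    p = counts / total
    m = lam * p + (1.0 - lam) * q
    jsd = _entropy_bits(m) - lam * _entropy_bits(p) - (1.0 - lam) * _entropy_bits(q)
    bound = -(lam * np.log2(lam) + (1.0 - lam) * np.log2(1.0 - lam))
    return float(np.clip(jsd / bound, 0.0, 1.0))


def profile_conservation(
    aln: Alignment,
    background: np.ndarray | None = None,
    gap_penalty: bool = True,
    lam: float = 0.5,
    window: int = 0,
) -> pd.DataFrame:
    """Conservation profile over the ungapped positions of the reference row.

    Returns a DataFrame with columns ``position`` (1-based index into the
    ungapped reference sequence), ``ref_residue``, ``score`` and
    ``gap_fraction``.  Residues outside the 20-letter alphabet (gaps,
    ambiguity codes) are excluded from the column distribution and counted
    into ``gap_fraction``.  With *window* > 0, scores are smoothed by a
    symmetric moving average of half-width *window* (off by default).
    """
    n_rows = len(aln.rows)
    ref = aln.reference_row
    positions, residues, scores, gap_fracs = [], [], [], []
    pos = 0
    for col_idx in range(aln.n_columns):
        ref_char = ref[col_idx]
        if ref_char == "-":
            continue
        pos += 1
        counts = np.zeros(20)
        for row in aln.rows:
            i = _AA_INDEX.get(row[col_idx])
            if i is not None:
                counts[i] += 1
        gap_fraction = 1.0 - counts.sum() / n_rows
        score = jsd_column(counts, background, lam=lam)
        if gap_penalty:
            score *= 1.0 - gap_fraction
        positions.append(pos)
        residues.append(ref_char)
        scores.append(score)
        gap_fracs.append(gap_fraction)

    score_arr = np.asarray(scores)
    if window > 0 and len(score_arr):
        smoothed = np.empty_like(score_arr)
        for i in range(len(score_arr)):
            lo, hi = max(0, i - window), min(len(score_arr), i + window + 1)
            smoothed[i] = score_arr[lo:hi].mean()
        score_arr = smoothed

    return pd.DataFrame(
        {
            "position": positions,
            "ref_residue": residues,
            "score": score_arr,
            "gap_fraction": gap_fracs,
        }
    )


def read_background(path: str | Path) -> np.ndarray:
    """Read a 20-line TSV of (amino acid, frequency); renormalised to sum 1."""
    df = pd.read_csv(path, sep="\t", header=None, names=["aa", "freq"])
    freq = np.zeros(20)
    for aa, f in zip(df["aa"], df["freq"]):
        freq[_AA_INDEX[str(aa).upper()]] = float(f)
    if np.any(freq <= 0):
        raise ValueError("background must assign positive frequency to all 20 residues")
    return freq / freq.sum()
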