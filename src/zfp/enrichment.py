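"""Group over-representation among tissue-enriched genes.

Given k members of a ZFP group among n tissue-enriched genes and the
group's background proportion p0 in the full catalogue, the one-sided
upper-tail exact binomial p-value P(X >= k | n, p0) tests whether the
group is over-represented.  Exact summation, no continuity correction;
the background proportion is taken from the full annotated catalogue, not
the expression-filtered subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import binomtest

from .annotation import ZfpGene


@dataclass(frozen=True)
class EnrichmentResult:
    group: str | None
    tissue: str | None
    k: int  # group members among tissue-enriched genes
    n: int  # tissue-enriched gene count
    p0: float  # background proportion of the group in the catalogue
    p_value: float


def binomial_enrichment(
    k: int, n: int, p0: float, group: str | None = None, tissue: str | None = None
) -> EnrichmentResult:
    """Exact one-sided binomial test of over-representation, P(X >= k)."""
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"require 0 < p0 < 1, got {p0}")
    # vacuous test: with no trials, P(X >= 0) = 1
    p_value = 1.0 if n == 0 else binomtest(k, n, p0, alternative="greater").pvalue
    return EnrichmentResult(group=group, tissue=tissue, k=k, n=n, p0=p0, p_value=p_value)


def group_enrichment_in_tissue(
    calls: pd.DataFrame, catalogue: Sequence[ZfpGene], tissue: str, group: str
) -> EnrichmentResult:
    """Run the binomial test for one group within one tissue's enriched genes.

    *calls* is the tidy output of :func:`zfp.expression.tissue_specific`.
    """
    group_of = {g.gene_id: g.group for g in catalogue}
    n_group = sum(1 for v in group_of.values() if v == group)
    if not 0 < n_group < len(group_of):
        raise ValueError(f"group {group!r} must be a proper subset of the catalogue")
    enriched = calls[(calls["tissue"] == tissue) & calls["enriched"]]
    enriched_genes = [g for g in enriched["gene_id"].unique() if g in group_of]
    k = sum(1 for g in enriched_genes if group_of[g] == group)
    return binomial_enrichment(
        k=k,
        n=len(enriched_genes),
        p0=n_group / len(group_of),
        group=group,
        tissue=tissue,
    )
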