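"""Cross-tissue expression profiling: TPM, filtering, TMM, clustering,
one-vs-rest tissue-specificity, and group/tissue summaries.

The pipeline mirrors a standard bulk RNA-seq workflow downstream of
quantification: gene-level counts and effective lengths come in, get
converted to transcripts-per-million (TPM), genes that are unexpressed
everywhere (TPM < 1 in all samples) or implausibly abundant (TPM > 10,000
in any sample) are discarded, and between-sample scale differences are
removed with trimmed-mean-of-M-values (TMM) factors.  Tissue-specific
genes are then called per tissue by a one-vs-rest negative-binomial Wald
test at FDR < 0.05 and log2 fold change > 1 (up in the focal tissue).

The differential test is intentionally self-contained: per-gene
method-of-moments dispersion shrunk toward a fitted mean-dispersion
trend, a Wald z on the log2 ratio of group means of size-factor-scaled
counts, and Benjamini-Hochberg correction within each one-vs-rest
comparison.  It is validated by its operating characteristics on
synthetic data (type-I control on null matrices, sensitivity on planted
effects) rather than by concordance with any particular external tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_FDR_MAX = 0.05
DEFAULT_LFC_MIN = 1.0
DEFAULT_TPM_LOW = 1.0
DEFAULT_TPM_HIGH = 10_000.0
#: Total trimmed fraction of M values (split evenly over both tails).
DEFAULT_TRIM_M = 0.30
#: Total trimmed fraction of A values.
DEFAULT_TRIM_A = 0.05


@dataclass
class CountMatrix:
    """Gene x sample integer counts with lengths and tissue labels."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    lengths: pd.Series  # gene -> effective length (bp)
    tissue_of: pd.Series  # sample -> tissue label

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing_len = set(self.counts.index) - set(self.lengths.index)
        if missing_len:
            raise ValueError(f"lengths missing for {len(missing_len)} genes")
        if (self.lengths.loc[self.counts.index] <= 0).any():
            raise ValueError("gene lengths must be positive")
        missing_tissue = set(self.counts.columns) - set(self.tissue_of.index)
        if missing_tissue:
            raise ValueError(f"tissue labels missing for samples: {sorted(missing_tissue)}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ExpressionMatrix:
    """Gene x sample abundances with a normalisation-state tag."""

    values: pd.DataFrame
    tissue_of: pd.Series
    state: str  # raw_tpm | filtered | tmm_normalized
    tmm_factors: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.state not in ("raw_tpm", "filtered", "tmm_normalized"):
            raise ValueError(f"unknown state {self.state!r}")


def tpm(cm: CountMatrix) -> ExpressionMatrix:
    """Transcripts per million: length-normalised rates rescaled to 1e6/sample.

    Raises a ValueError naming the sample if a column has zero total rate.
    """
    lengths = cm.lengths.loc[cm.counts.index].astype(float)
    rate = cm.counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    dead = denom[denom <= 0]
    if not dead.empty:
        raise ValueError(f"zero total rate in sample(s): {list(dead.index)}")
    values = rate.div(denom, axis=1) * 1e6
    return ExpressionMatrix(values=values, tissue_of=cm.tissue_of, state="raw_tpm")


def filter_matrix(
    x: ExpressionMatrix,
    low: float = DEFAULT_TPM_LOW,
    high: float = DEFAULT_TPM_HIGH,
) -> ExpressionMatrix:
    """Drop genes with TPM < *low* everywhere or TPM > *high* anywhere."""
    if x.state != "raw_tpm":
        raise ValueError(f"filter_matrix expects state raw_tpm, got {x.state}")
    max_tpm = x.values.max(axis=1)
    low_fail = max_tpm < low
    high_fail = (x.values > high).any(axis=1)
    keep = ~(low_fail | high_fail)
    logger.info(
        "filtered %d genes below %g everywhere, %d above %g somewhere; %d kept",
        int(low_fail.sum()), low, int(high_fail.sum()), high, int(keep.sum()),
    )
    return ExpressionMatrix(
        values=x.values.loc[keep], tissue_of=x.tissue_of, state="filtered"
    )


def _pick_reference(values: pd.DataFrame) -> str:
    """Sample whose upper quartile is closest to the mean upper quartile."""
    uq = values.quantile(0.75, axis=0)
    return (uq - uq.mean()).abs().idxmin()


def tmm_factors(
    x: ExpressionMatrix,
    ref: str | None = None,
    trim_m: float = DEFAULT_TRIM_M,
    trim_a: float = DEFAULT_TRIM_A,
    rescale: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    For each sample against the reference, per-gene M (log2 ratio of the
    matrix values) and A (mean log2 abundance) are computed over genes
    positive in both samples; the most extreme *trim_m* fraction of M and
    *trim_a* of A (totals, split evenly over the tails) are discarded; the
    factor is 2**(precision-weighted mean of the retained M).  With
    *rescale* (default) factors are divided by their geometric mean, so
    they multiply to one across samples.  Dividing a sample's values by
    its factor aligns it to the others.
    """
    if x.state != "filtered":
        raise ValueError(f"tmm_factors expects state filtered, got {x.state}")
    values = x.values
    if ref is None:
        ref = _pick_reference(values)
    elif ref not in values.columns:
        raise ValueError(f"reference sample {ref!r} not in matrix")
    xr = values[ref].to_numpy(dtype=float)
    n_ref = xr.sum()
    factors = {}
    for sample in values.columns:
        if sample == ref:
            factors[sample] = 1.0
            continue
        xs = values[sample].to_numpy(dtype=float)
        n_s = xs.sum()
        both = (xs > 0) & (xr > 0)
        s, r = xs[both], xr[both]
        m = np.log2(s / r)
        a = 0.5 * np.log2(s * r)
        keep = np.ones(len(m), dtype=bool)
        if len(m):
            m_lo, m_hi = np.quantile(m, [trim_m / 2, 1 - trim_m / 2])
            a_lo, a_hi = np.quantile(a, [trim_a / 2, 1 - trim_a / 2])
            keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if keep.sum() < 10:
            logger.warning(
                "TMM: only %d genes retained for sample %s; factor set to 1",
                int(keep.sum()), sample,
            )
            factors[sample] = 1.0
            continue
        # Inverse asymptotic variance of M under binomial sampling.
        w = (n_s - s[keep]) / (n_s * s[keep]) + (n_ref - r[keep]) / (n_ref * r[keep])
        with np.errstate(divide="ignore"):
            inv = np.where(w > 0, 1.0 / w, 0.0)
        if inv.sum() <= 0:
            inv = np.ones_like(inv)
        factors[sample] = float(2.0 ** (np.average(m[keep], weights=inv)))
    out = pd.Series(factors).reindex(values.columns)
    if rescale:
        out = out / np.exp(np.log(out).mean())
    return out


def normalize_tmm(x: ExpressionMatrix, **kwargs) -> ExpressionMatrix:
    """Divide each sample by its TMM factor; state becomes tmm_normalized."""
    factors = tmm_factors(x, **kwargs)
    return ExpressionMatrix(
        values=x.values.div(factors, axis=1),
        tissue_of=x.tissue_of,
        state="tmm_normalized",
        tmm_factors=factors,
    )


@dataclass
class Dendrogram:
    """Sample dendrogram: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

        return walk(tree) + ";"


def cluster_samples(x: ExpressionMatrix) -> Dendrogram:
    """Average-linkage clustering of samples on 1 - Pearson(log2(v+1)).

    Raises on fewer than two samples or on any constant sample vector
    (correlation distance is undefined there).
    """
    if x.state != "tmm_normalized":
        raise ValueError(f"cluster_samples expects state tmm_normalized, got {x.state}")
    if x.values.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    logv = np.log2(x.values.to_numpy(dtype=float) + 1.0)
    if np.any(logv.std(axis=0) == 0):
        raise ValueError("constant sample vector: correlation distance undefined")
    corr = np.corrcoef(logv.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(linkage=z, labels=list(x.values.columns))


def _size_factors(counts: np.ndarray, columns: pd.Index) -> np.ndarray:
    """Effective size factors: library size x TMM factor, geometric mean 1."""
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("sample with zero library size")
    cpm = pd.DataFrame(counts / lib * 1e6, columns=columns)
    keep = cpm.max(axis=1) > 0
    fake = ExpressionMatrix(
        values=cpm.loc[keep],
        tissue_of=pd.Series("x", index=columns),
        state="filtered",
    )
    f = tmm_factors(fake).to_numpy()
    s = lib * f
    return s / np.exp(np.log(s).mean())


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha ~ a0 + a1/mu over genes with usable estimates."""
    ok = (mu > 0) & (alpha > 0)
    if ok.sum() < 10:
        return np.full_like(mu, max(float(np.median(alpha[alpha > 0])) if (alpha > 0).any() else 0.01, 1e-6))
    x = 1.0 / mu[ok]
    design = np.column_stack([np.ones(ok.sum()), x])
    coef, *_ = np.linalg.lstsq(design, alpha[ok], rcond=None)
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu, 1e-8)
    return np.maximum(trend, 1e-6)


def tissue_specific(
    cm: CountMatrix,
    fdr_max: float = DEFAULT_FDR_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> pd.DataFrame:
    """One-vs-rest tissue-specificity calls for every tissue.

    For each tissue T, every gene is tested for differential expression
    between T's samples and all remaining samples with a negative-binomial
    Wald test on size-factor-scaled counts; p-values are BH-corrected
    across genes within the T-vs-rest comparison.  A gene is ``enriched``
    in T iff fdr < *fdr_max* and log2fc > *lfc_min* (up in T).

    Returns a tidy DataFrame (gene_id, tissue, log2fc, pvalue, fdr,
    enriched), one row per gene x tissue.
    """
    tissues = pd.unique(cm.tissue_of.loc[cm.samples])
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    counts = cm.counts.to_numpy(dtype=float)
    size = _size_factors(counts, cm.counts.columns)
    y = counts / size  # scaled counts, comparable across samples
    tissue_labels = cm.tissue_of.loc[cm.samples].to_numpy()

    pseudo = 0.5
    frames = []
    for tissue in tissues:
        in_t = tissue_labels == tissue
        n_a, n_b = int(in_t.sum()), int((~in_t).sum())
        if n_a == 0:
            raise ValueError(f"tissue {tissue!r} has no samples")
        ya, yb = y[:, in_t], y[:, ~in_t]
        mu_a, mu_b = ya.mean(axis=1), yb.mean(axis=1)

        # Method-of-moments dispersion pooled within the two groups,
        # shrunk 50/50 toward the fitted mean-dispersion trend.
        var_a = ya.var(axis=1, ddof=1) if n_a > 1 else np.zeros(len(mu_a))
        var_b = yb.var(axis=1, ddof=1) if n_b > 1 else np.zeros(len(mu_b))
        df_a, df_b = max(n_a - 1, 0), max(n_b - 1, 0)
        pooled_var = (df_a * var_a + df_b * var_b) / max(df_a + df_b, 1)
        mu_all = y.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_raw = (pooled_var - mu_all) / np.maximum(mu_all, 1e-8) ** 2
        alpha_raw = np.clip(np.nan_to_num(alpha_raw), 0.0, 10.0)
        trend = _fit_dispersion_trend(mu_all, alpha_raw)
        alpha = np.maximum(0.5 * alpha_raw + 0.5 * trend, 1e-8)

        lfc = np.log2((mu_a + pseudo) / (mu_b + pseudo))
        # Delta-method variance of each group's log2 mean: scaled count i
        # has variance mu/s_i + alpha*mu^2.
        sa, sb = size[in_t], size[~in_t]
        mu_a_f = np.maximum(mu_a, pseudo)
        mu_b_f = np.maximum(mu_b, pseudo)
        var_mean_a = (mu_a_f[:, None] / sa[None, :] + alpha[:, None] * mu_a_f[:, None] ** 2).sum(axis=1) / n_a**2
        var_mean_b = (mu_b_f[:, None] / sb[None, :] + alpha[:, None] * mu_b_f[:, None] ** 2).sum(axis=1) / n_b**2
        se_lfc = np.sqrt(var_mean_a / mu_a_f**2 + var_mean_b / mu_b_f**2) / np.log(2)
        z = lfc / np.maximum(se_lfc, 1e-12)
        pval = 2.0 * stats.norm.sf(np.abs(z))
        fdr = stats.false_discovery_control(pval, method="bh")
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": cm.genes,
                    "tissue": tissue,
                    "log2fc": lfc,
                    "pvalue": pval,
                    "fdr": fdr,
                    "enriched": (fdr < fdr_max) & (lfc > lfc_min),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def tissue_specific_summary(calls: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Enriched-gene count per tissue, plus genes enriched in >=1 tissue."""
    enriched = calls[calls["enriched"]]
    per_tissue = (
        enriched.groupby("tissue", sort=False)["gene_id"]
        .nunique()
        .rename("n_enriched")
        .reset_index()
        .sort_values("n_enriched", ascending=False, ignore_index=True)
    )
    return per_tissue, int(enriched["gene_id"].nunique())


def group_tissue_summary(
    x: ExpressionMatrix, catalogue: Sequence
) -> dict[str, pd.DataFrame]:
    """Expression summaries by ZFP group and by tissue, plus a z-scored heatmap.

    Returns three tables: ``by_group`` (per-gene mean expression with its
    group label, for ranking groups), ``by_tissue`` (per-tissue means over
    catalogue genes) and ``zscore`` (gene x tissue matrix of tissue means,
    row z-scored).  Catalogue genes absent from the matrix are excluded
    with a log message.
    """
    if x.state != "tmm_normalized":
        raise ValueError(f"group_tissue_summary expects tmm_normalized, got {x.state}")
    group_of = {g.gene_id: g.group for g in catalogue}
    present = [g for g in group_of if g in x.values.index]
    absent = len(group_of) - len(present)
    if absent:
        logger.info("%d catalogue genes absent from expression matrix", absent)
    sub = x.values.loc[present]

    by_group = pd.DataFrame(
        {
            "gene_id": present,
            "group": [group_of[g] for g in present],
            "mean_expression": sub.mean(axis=1).to_numpy(),
        }
    )
    tissue_means = sub.T.groupby(x.tissue_of.loc[sub.columns]).mean().T
    by_tissue = pd.DataFrame(
        {
            "tissue": tissue_means.columns,
            "mean_expression": tissue_means.mean(axis=0).to_numpy(),
        }
    )
    mean = tissue_means.mean(axis=1)
    sd = tissue_means.std(axis=1, ddof=0)
    zscore = tissue_means.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0)
    return {"by_group": by_group, "by_tissue": by_tissue, "zscore": zscore}
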