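"""TPM, filtering, TMM normalisation, sample clustering and summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_count_matrix
from test_clusters import make_gene
from zfp.expression import (
    ExpressionMatrix,
    cluster_samples,
    filter_matrix,
    group_tissue_summary,
    normalize_tmm,
    tmm_factors,
    tpm,
)
from zfp.simulate import SimConfig, simulate_counts


def as_filtered(values: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=values, tissue_of=pd.Series("t", index=values.columns), state="filtered"
    )


# ---------------------------------------------------------------- TPM

def test_single_gene_gets_the_whole_million():
    cm = make_count_matrix(pd.DataFrame({"s1": [7]}, index=["g1"]))
    assert tpm(cm).values.loc["g1", "s1"] == pytest.approx(1e6)


def test_length_normalisation_of_equal_counts():
    counts = pd.DataFrame({"s1": [100, 100]}, index=["short", "long"])
    lengths = pd.Series([1000.0, 2000.0], index=["short", "long"])
    cm = make_count_matrix(counts)
    cm.lengths = lengths
    vals = tpm(cm).values["s1"]
    assert vals["short"] == pytest.approx(666666.7, abs=0.1)
    assert vals["long"] == pytest.approx(333333.3, abs=0.1)


def test_tpm_columns_sum_to_one_million():
    sim = simulate_counts(SimConfig(seed=2, n_expr_genes=300))
    cm = make_count_matrix(sim.counts, tissue_of=sim.tissue_of)
    cm.lengths = sim.lengths.astype(float)
    sums = tpm(cm).values.sum(axis=0)
    assert np.allclose(sums, 1e6)


def test_zero_rate_sample_is_named_in_error():
    counts = pd.DataFrame({"ok": [5], "dead": [0]}, index=["g1"])
    with pytest.raises(ValueError, match="dead"):
        tpm(make_count_matrix(counts))


# ---------------------------------------------------------------- filtering

def test_filter_rules():
    values = pd.DataFrame(
        {
            "s1": [0.9, 12000.0, 0.5, 5.0],
            "s2": [0.8, 3.0, 3.0, 8.0],
        },
        index=["low_everywhere", "spike", "kept_mixed", "kept"],
    )
    x = ExpressionMatrix(values=values, tissue_of=pd.Series("t", index=["s1", "s2"]), state="raw_tpm")
    out = filter_matrix(x)
    assert list(out.values.index) == ["kept_mixed", "kept"]
    assert out.state == "filtered"


# ---------------------------------------------------------------- TMM

def naive_tmm(values: pd.DataFrame, ref: str, trim_m=0.30, trim_a=0.05):
    """Independent per-sample loop implementation of the TMM contract."""
    factors = {}
    xr = values[ref].to_numpy(float)
    n_ref = xr.sum()
    for sample in values.columns:
        if sample == ref:
            factors[sample] = 1.0
            continue
        xs = values[sample].to_numpy(float)
        n_s = xs.sum()
        ms, as_, ws = [], [], []
        for s, r in zip(xs, xr):
            if s > 0 and r > 0:
                ms.append(np.log2(s / r))
                as_.append(0.5 * np.log2(s * r))
                ws.append((n_s - s) / (n_s * s) + (n_ref - r) / (n_ref * r))
        ms, as_, ws = map(np.asarray, (ms, as_, ws))
        m_lo, m_hi = np.quantile(ms, [trim_m / 2, 1 - trim_m / 2])
        a_lo, a_hi = np.quantile(as_, [trim_a / 2, 1 - trim_a / 2])
        num = den = 0.0
        kept = 0
        for m, a, w in zip(ms, as_, ws):
            if m_lo <= m <= m_hi and a_lo <= a <= a_hi and w > 0:
                num += m / w
                den += 1.0 / w
                kept += 1
        factors[sample] = 2.0 ** (num / den) if kept >= 10 else 1.0
    return pd.Series(factors).reindex(values.columns)


def test_identical_samples_all_factors_one():
    values = pd.DataFrame(np.tile(np.arange(1.0, 41.0)[:, None], (1, 4)), columns=list("abcd"))
    assert tmm_factors(as_filtered(values)).tolist() == [1.0] * 4


def test_pure_scaling_yields_the_scale_factor():
    rng = np.random.default_rng(1)
    base = rng.lognormal(3, 1, 60)
    values = pd.DataFrame({"a": base, "b": 2 * base, "c": base})
    raw = tmm_factors(as_filtered(values), ref="a", rescale=False)
    assert raw["b"] == pytest.approx(2.0)
    assert raw["c"] == pytest.approx(1.0)


def test_scaling_one_sample_changes_only_its_unrescaled_factor():
    sim = simulate_counts(SimConfig(seed=9, n_expr_genes=400))
    x = filter_matrix(tpm(make_count_matrix(sim.counts, tissue_of=sim.tissue_of)))
    # TPM already normalises library scale, so scale the filtered values directly
    scaled = x.values.copy()
    scaled.iloc[:, 0] *= 3.0
    xs = ExpressionMatrix(values=scaled, tissue_of=x.tissue_of, state="filtered")
    ref = x.values.columns[-1]
    f0 = tmm_factors(x, ref=ref, rescale=False)
    f1 = tmm_factors(xs, ref=ref, rescale=False)
    # the scaled sample's precision weights shift with its totals, so the
    # factor tracks the scale only approximately; others are untouched exactly
    assert f1.iloc[0] == pytest.approx(3.0 * f0.iloc[0], rel=0.05)
    assert f1.iloc[1:].to_numpy() == pytest.approx(f0.iloc[1:].to_numpy(), rel=1e-12)


def test_matches_naive_oracle_on_negative_binomial_data():
    sim = simulate_counts(SimConfig(seed=4, n_expr_genes=500))
    x = filter_matrix(tpm(make_count_matrix(sim.counts, tissue_of=sim.tissue_of)))
    ref = x.values.columns[0]
    mine = tmm_factors(x, ref=ref, rescale=False)
    oracle = naive_tmm(x.values, ref=ref)
    assert mine.to_numpy() == pytest.approx(oracle.to_numpy(), abs=1e-8)


def test_geometric_mean_of_factors_is_one():
    sim = simulate_counts(SimConfig(seed=5, n_expr_genes=300))
    x = filter_matrix(tpm(make_count_matrix(sim.counts, tissue_of=sim.tissue_of)))
    f = tmm_factors(x)
    assert np.exp(np.log(f).mean()) == pytest.approx(1.0)


def test_too_few_genes_falls_back_to_unit_factor():
    values = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 7.0]})
    f = tmm_factors(as_filtered(values), ref="a")
    assert f.tolist() == [1.0, 1.0]


# ---------------------------------------------------------------- clustering

def normalized(values: pd.DataFrame, tissue_of=None) -> ExpressionMatrix:
    if tissue_of is None:
        tissue_of = pd.Series("t", index=values.columns)
    return ExpressionMatrix(values=values, tissue_of=tissue_of, state="tmm_normalized")


def test_duplicate_samples_merge_first():
    rng = np.random.default_rng(2)
    a = rng.lognormal(2, 1, 50)
    values = pd.DataFrame({"dup1": a, "dup2": a, "other": rng.lognormal(2, 1, 50)})
    dend = cluster_samples(normalized(values))
    first = dend.linkage[0]
    assert {dend.labels[int(first[0])], dend.labels[int(first[1])]} == {"dup1", "dup2"}
    assert first[2] == pytest.approx(0.0, abs=1e-12)


def test_replicates_form_tissue_clades():
    sim = simulate_counts(SimConfig(seed=6, n_expr_genes=800, n_planted=200, planted_lfc=4.0))
    x = normalize_tmm(filter_matrix(tpm(make_count_matrix(sim.counts, tissue_of=sim.tissue_of))))
    order = cluster_samples(x).leaf_order
    tissues = [s.rsplit("_", 1)[0] for s in order]
    # each tissue's replicates are contiguous in the leaf order
    seen = []
    for t in tissues:
        if not seen or seen[-1] != t:
            seen.append(t)
    assert len(seen) == len(set(tissues))


def test_sample_order_does_not_change_topology():
    sim = simulate_counts(SimConfig(seed=8, n_expr_genes=400, n_planted=100, planted_lfc=4.0))
    x = normalize_tmm(filter_matrix(tpm(make_count_matrix(sim.counts, tissue_of=sim.tissue_of))))
    perm = list(x.values.columns)[::-1]
    xp = ExpressionMatrix(values=x.values[perm], tissue_of=x.tissue_of, state="tmm_normalized")
    merges_a = {frozenset(c) for c in _clades(cluster_samples(x))}
    merges_b = {frozenset(c) for c in _clades(cluster_samples(xp))}
    assert merges_a == merges_b


def _clades(dend):
    from scipy.cluster.hierarchy import to_tree

    clades = []

    def walk(node):
        if node.is_leaf():
            return [dend.labels[node.id]]
        leaves = walk(node.get_left()) + walk(node.get_right())
        clades.append(leaves)
        return leaves

    walk(to_tree(dend.linkage))
    return clades


def test_constant_matrix_rejected():
    values = pd.DataFrame(np.ones((10, 3)), columns=list("abc"))
    with pytest.raises(ValueError, match="constant"):
        cluster_samples(normalized(values))


def test_newick_contains_all_samples():
    sim = simulate_counts(SimConfig(seed=2, n_expr_genes=200))
    x = normalize_tmm(filter_matrix(tpm(make_count_matrix(sim.counts, tissue_of=sim.tissue_of))))
    nwk = cluster_samples(x).to_newick()
    assert nwk.endswith(";")
    for s in x.values.columns:
        assert s in nwk


# ---------------------------------------------------------------- summaries

def test_group_summary_means_and_zscores():
    genes = [make_gene("K1", "1", 0, 10, "KRAB"), make_gene("Z1", "1", 20, 30)]
    rng = np.random.default_rng(3)
    tissue_of = pd.Series(["t1", "t1", "t2", "t2"], index=["a", "b", "c", "d"])
    values = pd.DataFrame(
        {
            "a": [1.0, 10.0], "b": [1.0, 12.0], "c": [1.0, 30.0], "d": [1.0, 28.0],
        },
        index=["K1", "Z1"],
    )
    x = ExpressionMatrix(values=values, tissue_of=tissue_of, state="tmm_normalized")
    out = group_tissue_summary(x, genes)
    by_group = out["by_group"].set_index("gene_id")
    assert by_group.loc["K1", "mean_expression"] == pytest.approx(1.0)
    z = out["zscore"]
    assert np.allclose(z.loc["Z1"].mean(), 0.0)
    assert np.allclose(z.loc["Z1"].std(ddof=0), 1.0)
    assert z.loc["K1"].isna().all()  # constant row has no z-score


def test_low_krab_expression_ranks_lowest():
    rng = np.random.default_rng(12)
    genes = [make_gene(f"K{i}", "1", i, i + 1, "KRAB") for i in range(10)]
    genes += [make_gene(f"Z{i}", "2", i, i + 1) for i in range(10)]
    samples = [f"s{i}" for i in range(6)]
    krab = rng.lognormal(np.log(5), 0.2, (10, 6))
    rest = rng.lognormal(np.log(10), 0.2, (10, 6))
    values = pd.DataFrame(
        np.vstack([krab, rest]), index=[g.gene_id for g in genes], columns=samples
    )
    x = ExpressionMatrix(
        values=values, tissue_of=pd.Series("t", index=samples), state="tmm_normalized"
    )
    ranking = (
        group_tissue_summary(x, genes)["by_group"]
        .groupby("group")["mean_expression"]
        .mean()
        .sort_values()
    )
    assert ranking.index[0] == "KRAB"
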