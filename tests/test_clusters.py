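"""Genomic cluster detection against a brute-force transitive-closure oracle."""

import numpy as np
import pytest

from conftest import make_isoform
from zfp.annotation import ZfpGene, build_catalogue, parse_domtblout, read_coordinates
from zfp.clusters import cluster_composition, detect_clusters


def make_gene(gene_id, chrom, start, end, group="ZF_ONLY"):
    effectors = () if group == "ZF_ONLY" else (group,)
    iso = make_isoform(f"{gene_id}.1", gene_id=gene_id, zf=3, effectors=effectors)
    return ZfpGene(
        gene_id=gene_id, canonical=iso, group=group,
        chrom=chrom, start=start, end=end, strand="+",
    )


def oracle_components(genes, max_gap):
    """Connected components of the pairwise interval-distance graph (union-find)."""
    parent = list(range(len(genes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            if a.chrom != b.chrom:
                continue
            dist = max(0, max(a.start, b.start) - min(a.end, b.end))
            if dist < max_gap:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(len(genes)):
        comps.setdefault(find(i), set()).add(genes[i].gene_id)
    return {frozenset(c) for c in comps.values()}


def random_catalogue(rng, n):
    genes = []
    for i in range(n):
        chrom = str(rng.integers(1, 4))
        start = int(rng.integers(0, 3_000_000))
        end = start + int(rng.integers(1_000, 50_000))
        genes.append(make_gene(f"G{i}", chrom, start, end))
    return genes


def test_close_genes_form_one_block():
    genes = [
        make_gene("A", "1", 0, 10_000),
        make_gene("B", "1", 110_000, 120_000),  # gap 100 kb
        make_gene("C", "1", 320_000, 330_000),  # gap 200 kb
    ]
    blocks = detect_clusters(genes)
    assert len(blocks) == 1
    assert blocks[0].members == ["A", "B", "C"]
    assert blocks[0].cluster_id == "C1C1"
    assert (blocks[0].start, blocks[0].end) == (0, 330_000)


def test_wide_gap_breaks_block_below_minimum():
    genes = [
        make_gene("A", "1", 0, 10_000),
        make_gene("B", "1", 110_000, 120_000),
        make_gene("C", "1", 420_001, 430_000),  # gap > 300 kb
    ]
    assert detect_clusters(genes) == []


def test_gap_rule_is_strict_less_than():
    genes = [
        make_gene("A", "1", 0, 10_000),
        make_gene("B", "1", 260_000, 270_000),  # gap exactly 250 kb
        make_gene("C", "1", 280_000, 290_000),
    ]
    assert detect_clusters(genes) == []  # A excluded, B+C below min_genes
    assert len(detect_clusters(genes, max_gap=250_001)) == 1


def test_matches_pairwise_closure_oracle():
    rng = np.random.default_rng(7)
    for _ in range(30):
        genes = random_catalogue(rng, int(rng.integers(5, 51)))
        max_gap = int(rng.integers(50_000, 400_000))
        blocks = detect_clusters(genes, max_gap=max_gap, min_genes=1)
        got = {frozenset(b.members) for b in blocks}
        assert got == oracle_components(genes, max_gap)


def test_permutation_invariance_and_disjoint_membership():
    rng = np.random.default_rng(11)
    genes = random_catalogue(rng, 40)
    blocks = detect_clusters(genes)
    shuffled = list(genes)
    rng.shuffle(shuffled)
    blocks2 = detect_clusters(shuffled)
    assert [b.members for b in blocks] == [b.members for b in blocks2]
    all_members = [g for b in blocks for g in b.members]
    assert len(all_members) == len(set(all_members))


def test_blocks_are_maximal():
    """No two returned blocks on one chromosome are within max_gap."""
    rng = np.random.default_rng(13)
    genes = random_catalogue(rng, 50)
    blocks = detect_clusters(genes, min_genes=1)
    by_chrom = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    for bs in by_chrom.values():
        bs.sort(key=lambda b: b.start)
        for a, b in zip(bs, bs[1:]):
            assert b.start - a.end >= 250_000


def test_increasing_gap_never_shrinks_a_gene_block():
    rng = np.random.default_rng(17)
    genes = random_catalogue(rng, 40)
    small = detect_clusters(genes, max_gap=100_000, min_genes=1)
    large = detect_clusters(genes, max_gap=300_000, min_genes=1)
    size_small = {g: b.n_total for b in small for g in b.members}
    size_large = {g: b.n_total for b in large for g in b.members}
    for g in size_small:
        assert size_large[g] >= size_small[g]


def test_genes_without_coordinates_are_skipped():
    iso = make_isoform("X.1", gene_id="X", zf=2)
    genes = [ZfpGene(gene_id="X", canonical=iso, group="ZF_ONLY")]
    assert detect_clusters(genes) == []


def test_planted_cluster_recovered_exactly(catalogue_sim):
    """The planted 21-gene block (16 KRAB) on chr29 comes back intact."""
    hits = parse_domtblout(catalogue_sim.domtbl_path)
    catalogue = build_catalogue(hits, read_coordinates(catalogue_sim.coords_path))
    blocks = detect_clusters(catalogue)
    assert len(blocks) == 1
    block = blocks[0]
    assert block.cluster_id == "C29C1"
    assert block.n_total == 21
    assert block.n_by_group["KRAB"] == 16
    planted = set(catalogue_sim.truth.loc[catalogue_sim.truth.cluster_id != "", "gene_id"])
    assert set(block.members) == planted


def test_composition_tables():
    genes = [make_gene(f"K{i}", "29", i * 100_000, i * 100_000 + 10_000, "KRAB") for i in range(16)]
    genes += [make_gene(f"Z{i}", "29", (16 + i) * 100_000, (16 + i) * 100_000 + 10_000) for i in range(5)]
    table, summary = cluster_composition(detect_clusters(genes))
    assert summary == {"n_clusters": 1, "n_genes_in_clusters": 21, "n_krab_in_clusters": 16}
    assert table.loc[0, "n_total"] == 21 and table.loc[0, "n_KRAB"] == 16


def test_empty_block_list_gives_zero_summary():
    table, summary = cluster_composition([])
    assert table.empty
    assert summary == {"n_clusters": 0, "n_genes_in_clusters": 0, "n_krab_in_clusters": 0}
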