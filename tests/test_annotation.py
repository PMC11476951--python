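"""Domain-scan parsing, canonical-isoform selection and group summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_isoform
from zfp.annotation import (
    DomtblParseError,
    classify_gene,
    parse_domtblout,
    round_half_up,
    select_canonical,
    summarize_groups,
)
from zfp.simulate import write_domtblout

_LINE = (
    "{iso} - 400 {query} PF00096.30 23 1e-09 25.0 0.1 1 1 "
    "1e-10 {ievalue} 25.0 0.1 1 23 100 122 100 122 0.95 some description\n"
)


def test_comment_only_file_yields_no_hits(tmp_path):
    path = tmp_path / "empty.domtblout"
    path.write_text("# target name ...\n#---\n# Program: hmmsearch\n")
    assert parse_domtblout(path) == []


def test_evalue_threshold_drops_weak_domains(tmp_path):
    path = tmp_path / "three.domtblout"
    path.write_text(
        _LINE.format(iso="A.1", query="zf-C2H2", ievalue="1e-08")
        + _LINE.format(iso="A.1", query="zf-C2H2", ievalue="0.2")
        + _LINE.format(iso="B.1", query="KRAB", ievalue="0.04")
    )
    hits = parse_domtblout(path, evalue_max=0.05)
    assert [(h.isoform_id, h.profile) for h in hits] == [("A.1", "ZF_C2H2"), ("B.1", "KRAB")]


def test_malformed_line_reports_line_number(tmp_path):
    path = tmp_path / "bad.domtblout"
    path.write_text("# header\nA.1 - 400 zf-C2H2 PF00096.30\n")
    with pytest.raises(DomtblParseError, match=r":2:"):
        parse_domtblout(path)


def test_missing_file_raises_io_error(tmp_path):
    with pytest.raises(FileNotFoundError):
        parse_domtblout(tmp_path / "nope.domtblout")


def test_write_parse_round_trip(catalogue_sim, tmp_path):
    """The generator's records survive write -> parse unchanged."""
    path = tmp_path / "rt.domtblout"
    hits = catalogue_sim.hits
    write_domtblout(hits, path)
    parsed = parse_domtblout(path, evalue_max=1e9)
    assert len(parsed) == len(hits)
    for a, b in zip(parsed, hits):
        assert a.isoform_id == b.isoform_id
        assert a.profile == b.profile
        assert (a.env_start, a.env_end) == (b.env_start, b.env_end)
        # E-values print at two significant figures, so 5% relative slack
        assert a.i_evalue == pytest.approx(b.i_evalue, rel=0.055)
        assert a.score == pytest.approx(b.score, abs=0.05)


def test_decoy_hits_fail_default_threshold(catalogue_sim):
    parsed = parse_domtblout(catalogue_sim.domtbl_path, evalue_max=0.05)
    assert len(parsed) == len(catalogue_sim.hits)


@pytest.mark.parametrize(
    "isoforms, expected",
    [
        # rule 1: effector present in some but not all -> effector-bearing wins
        ([make_isoform("A", zf=4, effectors=("KRAB",)), make_isoform("B", zf=5)], "A"),
        # rule 2: most zinc fingers wins among effector-bearing
        (
            [
                make_isoform("A", length=400, zf=4, effectors=("KRAB",)),
                make_isoform("B", length=380, zf=6, effectors=("KRAB",)),
            ],
            "B",
        ),
        # rule 3: equal architecture -> longest
        (
            [
                make_isoform("A", length=400, zf=4, effectors=("KRAB",)),
                make_isoform("B", length=450, zf=4, effectors=("KRAB",)),
            ],
            "B",
        ),
        # final tie-break: lexicographically smallest id
        ([make_isoform("B", zf=4), make_isoform("A", zf=4)], "A"),
        # an effector isoform with no fingers cannot be canonical
        ([make_isoform("A", zf=0, effectors=("KRAB",)), make_isoform("B", zf=5)], "B"),
    ],
)
def test_canonical_selection_rules(isoforms, expected):
    assert select_canonical(isoforms).isoform_id == expected


@st.composite
def isoform_sets(draw):
    n = draw(st.integers(1, 6))
    isoforms = []
    for i in range(n):
        effectors = tuple(
            draw(st.sets(st.sampled_from(["KRAB", "BTB", "SCAN", "SET"]), max_size=2))
        )
        isoforms.append(
            make_isoform(
                f"I{i}",
                length=draw(st.integers(100, 600)),
                zf=draw(st.integers(0, 8)),
                effectors=effectors,
            )
        )
    if not any(iso.zf_count for iso in isoforms):
        isoforms.append(make_isoform("Iz", zf=1))
    return isoforms


@given(isoforms=isoform_sets(), seed=st.integers(0, 2**16))
@settings(max_examples=200, deadline=None)
def test_canonical_selection_is_deterministic_and_order_free(isoforms, seed):
    import random

    chosen = select_canonical(isoforms)
    assert chosen.zf_count >= 1
    shuffled = list(isoforms)
    random.Random(seed).shuffle(shuffled)
    assert select_canonical(shuffled).isoform_id == chosen.isoform_id


def test_classify_gene_none_without_zinc_fingers():
    assert classify_gene([make_isoform("A", zf=0, effectors=("KRAB",))]) is None


def test_classify_gene_empty_list_rejected():
    with pytest.raises(ValueError):
        classify_gene([])


@pytest.mark.parametrize(
    "effectors, group",
    [
        (("KRAB",), "KRAB"),
        (("SCAN",), "SCAN"),  # SCAN at N-terminus plus a ZF array
        ((), "ZF_ONLY"),
        (("BTB", "KRAB"), "KRAB"),  # priority order on multi-effector genes
    ],
)
def test_group_assignment(effectors, group):
    gene = classify_gene([make_isoform("A", zf=6, effectors=effectors)])
    assert gene is not None and gene.group == group


def test_summarize_groups_partitions_and_percentages():
    genes = []
    for i, grp in enumerate(["KRAB", "BTB", "SET", "HOMEO", "ZF_ONLY"]):
        for j in range(2):
            effectors = () if grp == "ZF_ONLY" else (grp,)
            genes.append(
                classify_gene([make_isoform(f"I{i}{j}", gene_id=f"G{i}{j}", zf=3, effectors=effectors)])
            )
    table = summarize_groups(genes)
    assert table["n"].sum() == 10
    assert set(table["percent"]) == {20.0}
    assert abs(table["percent"].sum() - 100.0) < 0.3


def test_summarize_groups_empty_catalogue():
    assert summarize_groups([]).empty


def test_round_half_up_reporting_convention():
    assert round_half_up(12.25) == 12.3
    assert round_half_up(12.24) == 12.2
    assert round_half_up(100 * 39 / 301) == 13.0
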