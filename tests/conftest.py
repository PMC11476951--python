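import pandas as pd
import pytest

from zfp.annotation import DomainHit, IsoformAnnotation
from zfp.expression import CountMatrix
from zfp.simulate import SimConfig, simulate_catalogue


def make_isoform(
    isoform_id: str,
    gene_id: str = "G1",
    length: int = 400,
    zf: int = 4,
    effectors: tuple[str, ...] = (),
) -> IsoformAnnotation:
    """Construct an isoform with the given domain architecture."""
    hits = [
        DomainHit(isoform_id, eff, 5 + 60 * i, 45 + 60 * i, 1e-10, 50.0)
        for i, eff in enumerate(effectors)
    ]
    hits += [
        DomainHit(isoform_id, "ZF_C2H2", 100 + 24 * i, 122 + 24 * i, 1e-8, 25.0)
        for i in range(zf)
    ]
    return IsoformAnnotation(isoform_id=isoform_id, gene_id=gene_id, length=length, hits=hits)


def make_count_matrix(counts: pd.DataFrame, tissue_of=None, length: int = 1000) -> CountMatrix:
    lengths = pd.Series(length, index=counts.index, dtype=float)
    if tissue_of is None:
        tissue_of = pd.Series("t", index=counts.columns)
    return CountMatrix(counts=counts, lengths=lengths, tissue_of=tissue_of)


@pytest.fixture(scope="session")
def catalogue_sim(tmp_path_factory):
    """A default synthetic annotation input set (shared, read-only)."""
    out = tmp_path_factory.mktemp("sim_catalogue")
    return simulate_catalogue(SimConfig(seed=1), out)
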