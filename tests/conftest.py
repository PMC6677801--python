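import numpy as np
import pandas as pd
import pytest

from hapfunnel.pedigree import (
    CovariateTable,
    HaplotypeBlock,
    Pedigree,
    PedigreeMember,
    TransmissionTable,
)
from hapfunnel.simulate import worked_example


@pytest.fixture(scope="session")
def family():
    """17-member, three-generation family with 11 children."""
    members = [
        PedigreeMember("GF_P", None, None, 1),
        PedigreeMember("GM_P", None, None, 1),
        PedigreeMember("GF_M", None, None, 1),
        PedigreeMember("GM_M", None, None, 1),
        PedigreeMember("FATHER", "GF_P", "GM_P", 2),
        PedigreeMember("MOTHER", "GF_M", "GM_M", 2),
    ] + [PedigreeMember(f"C{i + 1:02d}", "FATHER", "MOTHER", 3) for i in range(11)]
    return Pedigree(members)


@pytest.fixture(scope="session")
def block():
    return HaplotypeBlock("blk1", "chr1", 0, 100_000)


@pytest.fixture(scope="session")
def informative_tx(family, block):
    """Alternating paternal / distinct maternal transmissions for one block."""
    pat = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 1]
    mat = [1, 0, 0, 1, 1, 0, 1, 0, 1, 0, 0]
    return TransmissionTable(
        {(c, block.block_id): (p, m) for c, p, m in zip(family.children, pat, mat)}
    )


@pytest.fixture(scope="session")
def covariates(family):
    n = len(family.children)
    return CovariateTable(
        pd.DataFrame(
            {
                "batch": ["A", "B"] * (n // 2) + ["A"] * (n % 2),
                "ebv_quartile": [(i % 4) + 1 for i in range(n)],
            },
            index=pd.Index(family.children, name="child"),
        )
    )


@pytest.fixture(scope="session")
def we_bundle(tmp_path_factory):
    """The worked-example study, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("worked_example") / "study"
    study, truth = worked_example(outdir)
    return outdir, study, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
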