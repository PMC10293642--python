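import pytest

import codonusage as cu
from codonusage.genetic_code import STANDARD_CODE


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture
def tiny_record():
    return cu.CdsRecord(transcript_id="t1", gene="G1", sequence="ATGAAATAA")


@pytest.fixture(scope="session")
def four_gene_set():
    """Synthetic four-gene study set with the deposited transcript lengths
    (11/1/4/6 transcripts, 846-2313 nt) and skewed synonymous usage."""
    spec = cu.four_gene_preset(seed=11, dirichlet_alpha=0.6)
    return cu.generate_gene_set(spec)


@pytest.fixture(scope="session")
def four_gene_report(four_gene_set, tmp_path_factory):
    out = tmp_path_factory.mktemp("report") / "run"
    written = cu.run_all(four_gene_set, cu.RunConfig(output_dir=out))
    return out, written
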