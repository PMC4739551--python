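import io

import pytest

from varscreen import fixtures as fx
from varscreen import reference_io as rio


@pytest.fixture(scope="session")
def fixture_spec():
    return fx.FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def run_dir(tmp_path_factory, fixture_spec):
    """A complete 2-patient synthetic run directory (built once per session)."""
    root = tmp_path_factory.mktemp("run")
    return fx.make_run_directory(str(root), fixture_spec)


@pytest.fixture(scope="session")
def genome_and_models(fixture_spec):
    genome, models, refflat, ids_tsv = fx.make_genome(fixture_spec)
    return genome, models, refflat, ids_tsv


def make_genome_text(seq: str, name: str = "chrT") -> rio.ReferenceGenome:
    return rio.load_reference(io.StringIO(f">{name}\n{seq}\n"))


@pytest.fixture()
def homopolymer_genome():
    # 1-based: position 100 = C, 101..103 = A, 104 = T
    seq = "G" * 99 + "C" + "AAA" + "T" + "G" * 46
    return make_genome_text(seq, name="chrH")
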