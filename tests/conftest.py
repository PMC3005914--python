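import numpy as np
import pytest

from nucvarseq import kmers, synthetic


@pytest.fixture(scope="session")
def index6():
    return kmers.build_index(6)


@pytest.fixture(scope="session")
def index3():
    return kmers.build_index(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seqs(rng, n, length):
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]


@pytest.fixture(scope="session")
def fixture_genome(tmp_path_factory):
    """A small written genome fixture shared by prep tests."""
    fx = synthetic.generate_genome_fixture(
        n_chrom=2, chrom_length=20_000, n_nucleosomes=120, n_genes=12, seed=7
    )
    d = tmp_path_factory.mktemp("fixture")
    paths = synthetic.write_fixture(fx, d)
    return fx, paths
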