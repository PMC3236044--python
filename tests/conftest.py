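import pytest

from annotqc.config import QCConfig
from annotqc.synth import GenomeSpec, generate, gold_standard


@pytest.fixture(scope="session")
def gold_record():
    return gold_standard()


@pytest.fixture(scope="session")
def gold_truth():
    return generate(GenomeSpec())[1]


@pytest.fixture()
def config():
    return QCConfig()


@pytest.fixture(scope="session")
def small_record():
    """A small genome for fast parse/serialize round-trip tests."""
    record, _ = generate(GenomeSpec(seed=11, length_bp=40_000, n_proteins=25,
                                    protein_len_dist=(120.0, 30.0, 40)))
    return record
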