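import pytest

from hp1kit import Genome


@pytest.fixture
def small_genome():
    return Genome({"chr2L": 100_000, "chr2R": 150_000})


@pytest.fixture
def tiny_genome():
    return Genome({"chrA": 1_000})
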