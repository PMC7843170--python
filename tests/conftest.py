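import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "mlcskit",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("mlcskit")

from mlcskit import Alphabet, BioSequence, SequenceSet


@pytest.fixture
def dna():
    return Alphabet.dna()


@pytest.fixture
def protein():
    return Alphabet.protein()


@pytest.fixture
def worked_pair():
    """The classic two-sequence instance whose three LCS are known exactly."""
    alpha = Alphabet.protein().extended("B")
    return SequenceSet(
        alpha, (BioSequence("s1", "ABCBDAB"), BioSequence("s2", "BDCABA"))
    )


@pytest.fixture
def fasta_file(tmp_path):
    def write(text, name="in.fasta"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return write
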