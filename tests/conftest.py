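import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20170)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(text, name="seqs.fa"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def gff_file(tmp_path):
    def _write(lines, name="genes.gff3"):
        path = tmp_path / name
        path.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")
        return path

    return _write
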