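import pytest

from chresonym.examples import inversus_example, macnae_example
from chresonym.record_io import write_dataset


@pytest.fixture
def macnae():
    return macnae_example()


@pytest.fixture
def inversus():
    return inversus_example()


@pytest.fixture
def macnae_dir(macnae, tmp_path):
    d = tmp_path / "macnae"
    write_dataset(macnae, d)
    return d
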