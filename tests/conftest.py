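import pytest

from baocea.params import build_reference_parameters
from baocea.synthetic import synthetic_life_table


@pytest.fixture(scope="session")
def ref_params():
    """Reference configuration: published inputs with the corrected death-HR row."""
    return build_reference_parameters()


@pytest.fixture(scope="session")
def life_table():
    """Synthetic U.S.-like Gompertz-Makeham life table (ages 0..110)."""
    return synthetic_life_table()
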