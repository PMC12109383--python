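import numpy as np
import pytest

from quenchlab.simulate import STUDY_LADDER_M
from quenchlab.titration import QuenchTable


@pytest.fixture
def ladder():
    """The 0-26.7 uM titration ladder (mol/L)."""
    return np.array(STUDY_LADDER_M)


@pytest.fixture
def exact_table(ladder):
    """Factory for noise-free Stern-Volmer tables F0/F = 1 + Ksv [Q]."""

    def make(ksv=5.0e4, f0=5000.0, temperature=298.0):
        f = f0 / (1.0 + ksv * ladder)
        return QuenchTable(temperature, ladder, f)

    return make


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A full synthetic study dataset on disk (seed 42, 1% noise)."""
    from quenchlab.study import write_study_dataset

    return write_study_dataset(tmp_path_factory.mktemp("study") / "data", seed=42)
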