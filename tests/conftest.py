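import numpy as np
import pytest

from mapocc.synthetic import make_disassembly_series, make_toy_model


@pytest.fixture(scope="session")
def toy_model():
    """Small shared toy model: 8 features x 12 atoms."""
    return make_toy_model(n_features=8, atoms_per_feature=12, seed=7)


@pytest.fixture(scope="session")
def series6():
    """Linear 6-class disassembly series with planted truth."""
    return make_disassembly_series(n_classes=6, seed=11, atoms_per_feature=12)


@pytest.fixture(scope="session")
def series_branch():
    """Two-branch 8-class series (diamond inclusion order)."""
    return make_disassembly_series(
        n_classes=8, branching=True, seed=13, atoms_per_feature=12
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
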