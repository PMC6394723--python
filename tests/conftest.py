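import numpy as np
import pytest

from mcptyper.primers import builtin_panel, builtin_primers


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


@pytest.fixture(scope="session")
def panel_by_group(panel):
    return {p.group: p for p in panel}


@pytest.fixture(scope="session")
def all_primers():
    return builtin_primers()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
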