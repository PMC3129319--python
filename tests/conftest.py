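import numpy as np
import pytest

from practident import IGT, NGT, build_case, disst_protocol, simulate


@pytest.fixture(scope="session")
def prot5():
    return disst_protocol(5.0)


@pytest.fixture(scope="session")
def prot10():
    return disst_protocol(10.0)


@pytest.fixture(scope="session")
def ngt_profiles(prot5):
    return simulate(NGT.kin, NGT.secretion, NGT.pd, prot5)


@pytest.fixture(scope="session")
def ngt_cases(prot5):
    """One ModelCase of each kind for the NGT participant, 5-min sampling."""
    return {kind: build_case(kind, NGT, prot5) for kind in
            ("nK_nL", "nT_VP", "SI_VG", "SI_pG", "five_param")}


@pytest.fixture(scope="session")
def igt():
    return IGT


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20110526)
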